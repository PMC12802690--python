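"""Differentially methylated region calling by correlation-adjusted meta-analysis.

Candidate regions are maximal chains of significant sites (dDMPs) in which
each consecutive pair lies within 500 bp; chains with at least three dDMPs
are tested.  The combined statistic is an inverse-variance meta-analysis of
the per-site slopes whose covariance Sigma = diag(se) . R . diag(se) uses the
correlation R of methylation residuals after covariate adjustment, so
correlated neighbouring probes do not overstate the evidence:

    B  = (1' Sigma^-1 b) / (1' Sigma^-1 1)
    SE = (1' Sigma^-1 1)^(-1/2),  z = B / SE,  two-sided normal p.

With R = I this reduces exactly to fixed-effect inverse-variance
meta-analysis.  Region p-values are Bonferroni-adjusted over the number of
candidates; regions with adjusted p < 0.05 are reported as dDMRs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BetaMatrix
from .linear_modelling import build_design

MAX_GAP = 500
MIN_DMPS = 3
RIDGE = 1e-6


def build_candidates(
    site_results: pd.DataFrame,
    annotation: pd.DataFrame,
    max_gap: int = MAX_GAP,
    min_dmps: int = MIN_DMPS,
) -> list[dict]:
    """Maximal <=``max_gap`` bp chains of dDMPs with >= ``min_dmps`` sites.

    The gap rule bounds *consecutive* distances, so a chain may span more
    than ``max_gap`` in total.
    """
    ann = annotation.set_index("site_id")
    dmps = site_results[site_results["dmp"]].copy()
    if dmps.empty:
        return []
    dmps["chromosome"] = dmps["site_id"].map(ann["chromosome"])
    dmps["position"] = dmps["site_id"].map(ann["position"])
    dmps = dmps.sort_values(["chromosome", "position"], kind="stable")

    candidates = []
    current: list[pd.Series] = []
    for _, row in dmps.iterrows():
        if current and (
            row["chromosome"] != current[-1]["chromosome"]
            or row["position"] - current[-1]["position"] > max_gap
        ):
            if len(current) >= min_dmps:
                candidates.append(_candidate(current))
            current = []
        current.append(row)
    if len(current) >= min_dmps:
        candidates.append(_candidate(current))
    return candidates


def _candidate(rows: list[pd.Series]) -> dict:
    return {
        "chromosome": rows[0]["chromosome"],
        "start": int(rows[0]["position"]),
        "end": int(rows[-1]["position"]),
        "site_ids": [r["site_id"] for r in rows],
        "n_dmps": len(rows),
    }


def region_statistic(
    effects: np.ndarray, ses: np.ndarray, R: np.ndarray
) -> tuple[float, float, float, float]:
    """Correlation-adjusted inverse-variance combination of site effects.

    Returns (combined_effect, combined_se, z, two-sided normal p).  ``R`` must
    be positive definite; a ridge of 1e-6 is added to its diagonal before
    factorisation, and failure after that is an error.
    """
    b = np.asarray(effects, float)
    s = np.asarray(ses, float)
    R = np.asarray(R, float)
    sigma = np.outer(s, s) * (R + RIDGE * np.eye(len(b)))
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "site covariance is not positive definite after ridge 1e-6"
        ) from err
    ones = np.ones(len(b))
    w = np.linalg.solve(sigma, ones)  # Sigma^-1 1
    denom = ones @ w
    combined = (w @ b) / denom
    combined_se = denom**-0.5
    z = combined / combined_se
    p = 2.0 * stats.norm.sf(abs(z))
    del L
    return float(combined), float(combined_se), float(z), float(p)


def residual_correlation(
    beta: BetaMatrix, sheet: pd.DataFrame, site_ids: list[str],
    covariates: tuple[str, ...] = ("sex", "batch"),
) -> np.ndarray:
    """Pearson correlation of per-site OLS residuals after full covariate
    adjustment (age + covariates)."""
    sheet = sheet.set_index("sample_id").loc[beta.sample_ids].reset_index()
    X = build_design(sheet, covariates).to_numpy(float)
    sub = beta.subset_sites(site_ids)
    resids = []
    for y in sub.values:
        keep = np.isfinite(y)
        r = np.full(y.shape, np.nan)
        coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        r[keep] = y[keep] - X[keep] @ coef
        resids.append(r)
    resid = np.asarray(resids)
    return pd.DataFrame(resid.T).corr().to_numpy()


def call_dmrs(
    site_results: pd.DataFrame,
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    annotation: pd.DataFrame,
    max_gap: int = MAX_GAP,
    min_dmps: int = MIN_DMPS,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = ("sex", "batch"),
) -> pd.DataFrame:
    """Build candidates, combine statistics and Bonferroni-adjust.

    Returns all candidate regions with columns (chromosome, start, end,
    site_ids, n_dmps, combined_effect, combined_se, z, p, p_adjusted,
    significant, mixed_direction, genes).  dDMRs are the rows with
    ``significant`` true (adjusted p < ``alpha``).
    """
    candidates = build_candidates(site_results, annotation, max_gap, min_dmps)
    if not candidates:
        return pd.DataFrame(
            columns=["chromosome", "start", "end", "site_ids", "n_dmps",
                     "combined_effect", "combined_se", "z", "p", "p_adjusted",
                     "significant", "mixed_direction", "genes"]
        )
    res_idx = site_results.set_index("site_id")
    ann_idx = annotation.set_index("site_id")
    rows = []
    for cand in candidates:
        sids = cand["site_ids"]
        eff = res_idx.loc[sids, "effect"].to_numpy(float)
        ses = res_idx.loc[sids, "se"].to_numpy(float)
        R = residual_correlation(beta, sheet, sids, covariates)
        B, se, z, p = region_statistic(eff, ses, R)
        genes = sorted({g for s in sids for g in ann_idx.loc[s, "gene_symbols"]})
        rows.append(
            {
                **cand,
                "site_ids": ";".join(sids),
                "combined_effect": B,
                "combined_se": se,
                "z": z,
                "p": p,
                "mixed_direction": bool((eff > 0).any() and (eff < 0).any()),
                "genes": ";".join(genes),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.minimum(1.0, out["p"] * len(out))
    out["significant"] = out["p_adjusted"] < alpha
    return out
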