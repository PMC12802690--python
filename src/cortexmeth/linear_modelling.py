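"""Per-site linear models of methylation against developmental age.

The core model is ordinary least squares of the methylation proportion on
age (pcw prenatally, years postnatally), controlling for sex and experimental
batch.  Sites passing the experiment-wide EPIC significance threshold
(p < 9e-8) are flagged as developmentally differentially methylated positions
(dDMPs).  Effects are reported in percentage points per week (proportion
slope x 100).  Extreme p-values are carried in log10 space alongside the
float p so that tails far below double precision remain comparable.

Also here: the genome-wide hypo/hyper direction binomial test, effect
magnitude and variance comparisons, the global (mean-methylation) trend,
the age x cell-fraction interaction model, a donor random-intercept mixed
model for cell-type effects, and the prenatal/postnatal cross-stage
comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io_formats import BetaMatrix

EWAS_ALPHA = 9e-8
LOG10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Small numeric helpers
# ---------------------------------------------------------------------------

def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (the reporting convention)."""
    return float(f"{x:.{sig}g}")


def percent(k: int, n: int, sig: int = 3) -> float:
    """Percentage k/n rounded to ``sig`` significant figures."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round_sig(100.0 * k / n, sig)


def _log10_p_from_t(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Two-sided log10 p for t statistics, stable for extreme tails."""
    return (np.log(2.0) + stats.t.logsf(np.abs(t), df)) / LOG10


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def build_design(
    sheet: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "batch"),
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Design matrix with intercept, age and indicator-coded covariates.

    Categorical covariates are coded as treatment contrasts (first level
    dropped).  Raises on rank deficiency, naming the collinear columns.
    """
    cols = {"const": np.ones(len(sheet)), "age": sheet["age_value"].to_numpy(float)}
    for cov in covariates:
        series = sheet[cov]
        if series.dtype.kind in "if":
            cols[cov] = series.to_numpy(float)
        else:
            levels = sorted(series.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (series.astype(str) == lev).astype(float)
    X = pd.DataFrame(cols, index=sheet.index)
    if extra is not None:
        X = pd.concat([X, extra], axis=1)
    _check_full_rank(X)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(float)
    rank = np.linalg.matrix_rank(A)
    if rank == A.shape[1]:
        return
    # identify columns lying in the span of the others
    bad = []
    for j, name in enumerate(X.columns):
        others = np.delete(A, j, axis=1)
        resid = A[:, j] - others @ np.linalg.lstsq(others, A[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(A[:, j])):
            bad.append(name)
    raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# Per-site OLS
# ---------------------------------------------------------------------------

def fit_site_linear(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "batch"),
    alpha: float = EWAS_ALPHA,
    term: str = "age",
    min_complete: int = 10,
) -> pd.DataFrame:
    """Per-site OLS of methylation on age + covariates; dDMP flags at ``alpha``.

    Missing values are handled as complete cases per site.  Returns one row
    per site with (effect [pp/week], se, t, p, log10_p, df, direction,
    n_used, dmp).
    """
    sheet = sheet.set_index("sample_id").loc[beta.sample_ids].reset_index()
    X_full = build_design(sheet, covariates)
    term_idx = list(X_full.columns).index(term)
    Xa = X_full.to_numpy(float)
    Y = beta.values

    out = np.full((beta.n_sites, 5), np.nan)  # slope, se, t, df, n_used
    masks = ~np.isfinite(Y)
    # group sites by missingness pattern so each group is one matrix solve
    pattern_ids = {}
    groups: dict[int, list[int]] = {}
    for i in range(beta.n_sites):
        key = masks[i].tobytes()
        gid = pattern_ids.setdefault(key, len(pattern_ids))
        groups.setdefault(gid, []).append(i)

    for rows in groups.values():
        keep = ~masks[rows[0]]
        n_used = int(keep.sum())
        if n_used < min_complete:
            raise ValueError(
                f"site {beta.site_ids[rows[0]]!r} has {n_used} complete cases "
                f"(need >= {min_complete})"
            )
        X = Xa[keep]
        _check_full_rank(pd.DataFrame(X, columns=X_full.columns))
        XtXi = np.linalg.inv(X.T @ X)
        H = XtXi @ X.T
        Yg = Y[np.ix_(rows, np.flatnonzero(keep))]
        B = Yg @ H.T
        resid = Yg - B @ X.T
        df = n_used - X.shape[1]
        sigma2 = (resid**2).sum(axis=1) / df
        se = np.sqrt(sigma2 * XtXi[term_idx, term_idx])
        out[rows, 0] = B[:, term_idx]
        out[rows, 1] = se
        out[rows, 2] = B[:, term_idx] / se
        out[rows, 3] = df
        out[rows, 4] = n_used

    log10_p = _log10_p_from_t(out[:, 2], out[:, 3])
    res = pd.DataFrame(
        {
            "site_id": beta.site_ids,
            "effect": out[:, 0] * 100.0,
            "se": out[:, 1] * 100.0,
            "t": out[:, 2],
            "log10_p": log10_p,
            "df": out[:, 3].astype(int),
            "n_used": out[:, 4].astype(int),
        }
    )
    with np.errstate(under="ignore"):
        res["p"] = np.power(10.0, log10_p)  # underflows to 0 beyond ~1e-323

    res["direction"] = np.where(res["effect"] > 0, "hyper", "hypo")
    res["dmp"] = log10_p < np.log10(alpha)
    return res


# ---------------------------------------------------------------------------
# Direction binomial test
# ---------------------------------------------------------------------------

def binomial_tail_log(k: int, n: int, p0: float, tail: str = "upper") -> float:
    """Natural-log one-tailed exact binomial tail, summed in log space."""
    if tail == "upper":
        ks = np.arange(k, n + 1)
    else:
        ks = np.arange(0, k + 1)
    return float(logsumexp(stats.binom.logpmf(ks, n, p0)))


def direction_binomial(n_total: int, n_success: int, p0: float = 0.5) -> dict:
    """One-tailed exact binomial test P(X >= n_success | n_total, p0).

    Used genome-wide with p0 = 0.5 to test for an excess of hypomethylated
    dDMPs.  Returns the tail p (log-space computation), its log10, and the
    success percentage at 3 significant figures.
    """
    if n_total < 1 or not 0 < p0 < 1 or n_success > n_total:
        raise ValueError("invalid binomial test inputs")
    logp = binomial_tail_log(n_success, n_total, p0, tail="upper")
    return {
        "n_total": n_total,
        "n_success": n_success,
        "p0": p0,
        "p_one_tailed": float(np.exp(logp)),
        "log10_p": logp / LOG10,
        "percent_success": percent(n_success, n_total),
    }


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def compare_effect_magnitude(effects_hyper, effects_hypo) -> dict:
    """Welch t-tests comparing dDMP effect sizes between directions.

    Tests both |effect| (magnitude) and the signed effects; returns group
    means alongside each statistic.
    """
    a = np.asarray(effects_hyper, float)
    b = np.asarray(effects_hypo, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both effect groups must be non-empty")
    t_abs, p_abs = stats.ttest_ind(np.abs(a), np.abs(b), equal_var=False)
    t_sgn, p_sgn = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_hyper": float(a.mean()),
        "mean_hypo": float(b.mean()),
        "mean_abs_hyper": float(np.abs(a).mean()),
        "mean_abs_hypo": float(np.abs(b).mean()),
        "t_abs": float(t_abs),
        "p_abs": float(p_abs),
        "t_signed": float(t_sgn),
        "p_signed": float(p_sgn),
    }


def global_trend(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    site_mask: np.ndarray | None = None,
    covariates: tuple[str, ...] = ("sex", "batch"),
) -> dict:
    """Slope of per-sample mean methylation (over e.g. autosomal sites) vs age."""
    values = beta.values if site_mask is None else beta.values[np.asarray(site_mask, bool)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sample_means = np.nanmean(values, axis=0)
    mean_beta = BetaMatrix(["global_mean"], list(beta.sample_ids), sample_means[None, :])
    row = fit_site_linear(mean_beta, sheet, covariates, min_complete=5).iloc[0]
    return {"effect": float(row["effect"]), "se": float(row["se"]),
            "t": float(row["t"]), "p": float(row["p"]), "log10_p": float(row["log10_p"])}


def variance_compare(
    beta_a: BetaMatrix, beta_b: BetaMatrix, site_ids: list[str] | None = None
) -> dict:
    """Per-site variance (percentage scale) in two groups plus a Welch t-test.

    Mirrors the fetal-vs-adult variance contrast: variances are computed on
    the % methylation scale, so a mean variance of 120 corresponds to a mean
    SD of about 11% methylation.
    """
    if site_ids is None:
        site_ids = [s for s in beta_a.site_ids if s in set(beta_b.site_ids)]
    sub_a = beta_a.subset_sites(site_ids)
    sub_b = beta_b.subset_sites(site_ids)
    if sub_a.n_samples < 2 or sub_b.n_samples < 2:
        raise ValueError("each group needs >= 2 samples to estimate variance")
    var_a = np.nanvar(sub_a.values * 100.0, axis=1, ddof=1)
    var_b = np.nanvar(sub_b.values * 100.0, axis=1, ddof=1)
    t, p = stats.ttest_ind(var_a, var_b, equal_var=False)
    table = pd.DataFrame({"site_id": site_ids, "variance_a": var_a, "variance_b": var_b})
    return {
        "table": table,
        "mean_variance_a": float(var_a.mean()),
        "mean_variance_b": float(var_b.mean()),
        "mean_sd_a": float(np.sqrt(var_a).mean()),
        "mean_sd_b": float(np.sqrt(var_b).mean()),
        "t": float(t),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# Age x cell-fraction interaction model
# ---------------------------------------------------------------------------

def fit_interaction(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    fraction_col: str = "fraction",
    covariates: tuple[str, ...] = ("sex", "batch"),
    alpha: float = EWAS_ALPHA,
) -> pd.DataFrame:
    """Age x cell-fraction interaction model across two nuclei fractions.

    Fits methylation ~ age + fraction + age:fraction + covariates per site;
    the interaction p comes from the age:fraction coefficient.  Stratified
    per-fraction age slopes are refitted on each fraction's samples.
    """
    sheet = sheet.set_index("sample_id").loc[beta.sample_ids].reset_index()
    levels = sorted(sheet[fraction_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"interaction model needs exactly 2 fractions, got {levels}")
    for lev in levels:
        if (sheet[fraction_col] == lev).sum() < 3:
            raise ValueError(f"fraction {lev!r} has < 3 samples")
    frac = (sheet[fraction_col].astype(str) == levels[1]).astype(float)
    extra = pd.DataFrame(
        {f"frac[{levels[1]}]": frac, "age_x_frac": frac * sheet["age_value"].to_numpy(float)},
        index=sheet.index,
    )
    # full model: reuse the per-site OLS machinery with the interaction term
    res_int = _fit_with_extra(beta, sheet, covariates, extra, term="age_x_frac")
    strat = {}
    for lev in levels:
        sel = sheet.loc[sheet[fraction_col] == lev, "sample_id"].tolist()
        sub = beta.subset_samples(sel)
        sub_sheet = sheet[sheet[fraction_col] == lev]
        strat[lev] = fit_site_linear(sub, sub_sheet, covariates, alpha=alpha, min_complete=3)

    out = pd.DataFrame({"site_id": beta.site_ids})
    out["interaction_effect"] = res_int["effect"]
    out["interaction_se"] = res_int["se"]
    out["interaction_p"] = res_int["p"]
    out["interaction_log10_p"] = res_int["log10_p"]
    out["significant"] = res_int["log10_p"] < np.log10(alpha)
    for lev in levels:
        out[f"effect[{lev}]"] = strat[lev]["effect"].to_numpy()
        out[f"p[{lev}]"] = strat[lev]["p"].to_numpy()
    return out


def _fit_with_extra(beta, sheet, covariates, extra, term):
    X = build_design(sheet, covariates, extra=extra)
    proxy = BetaMatrix(list(beta.site_ids), list(beta.sample_ids), beta.values)
    # temporary sheet carrying the extra columns is unnecessary: fit directly
    return _ols_table(proxy, X, term)


def _ols_table(beta: BetaMatrix, X: pd.DataFrame, term: str) -> pd.DataFrame:
    """OLS of each site on a prebuilt design matrix; report one coefficient."""
    term_idx = list(X.columns).index(term)
    Xa = X.to_numpy(float)
    rows = []
    for i, sid in enumerate(beta.site_ids):
        y = beta.values[i]
        keep = np.isfinite(y)
        Xk, yk = Xa[keep], y[keep]
        XtXi = np.linalg.inv(Xk.T @ Xk)
        b = XtXi @ Xk.T @ yk
        resid = yk - Xk @ b
        df = keep.sum() - Xk.shape[1]
        se = np.sqrt((resid**2).sum() / df * XtXi[term_idx, term_idx])
        t = b[term_idx] / se
        rows.append((sid, b[term_idx] * 100.0, se * 100.0, t, df))
    res = pd.DataFrame(rows, columns=["site_id", "effect", "se", "t", "df"])
    res["log10_p"] = _log10_p_from_t(res["t"].to_numpy(), res["df"].to_numpy())
    res["p"] = np.power(10.0, res["log10_p"])
    return res


# ---------------------------------------------------------------------------
# Mixed model with a donor random intercept
# ---------------------------------------------------------------------------

def fit_site_mixed(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    cell_col: str = "fraction",
    covariates: tuple[str, ...] = ("sex", "batch"),
    donor_col: str = "donor_id",
    alpha: float = EWAS_ALPHA,
) -> pd.DataFrame:
    """Cell-type effect per site from a donor random-intercept mixed model.

    Coefficients come from the REML fit; significance of the cell-type term
    from a likelihood-ratio comparison of nested models refitted by maximum
    likelihood.  If the random-effect variance is singular (or the fit
    fails), the site falls back to a fixed-effects OLS fit with an LRT on the
    OLS likelihoods, flagged in ``fallback_ols``.
    """
    import statsmodels.api as sm

    sheet = sheet.set_index("sample_id").loc[beta.sample_ids].reset_index()
    levels = sorted(sheet[cell_col].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("cell-type term needs >= 2 levels")
    cell_dummies = pd.DataFrame(
        {f"cell[{lev}]": (sheet[cell_col].astype(str) == lev).astype(float)
         for lev in levels[1:]},
        index=sheet.index,
    )
    X_red = build_design(sheet, covariates)
    X_full = pd.concat([X_red, cell_dummies], axis=1)
    _check_full_rank(X_full)
    groups = sheet[donor_col].to_numpy()
    k_cell = cell_dummies.shape[1]

    rows = []
    for i, sid in enumerate(beta.site_ids):
        y = beta.values[i]
        keep = np.isfinite(y)
        yk = y[keep]
        Xf, Xr, g = X_full[keep.tolist()], X_red[keep.tolist()], groups[keep]
        row = {"site_id": sid, "n_used": int(keep.sum()), "fallback_ols": False}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reml = sm.MixedLM(yk, Xf, groups=g).fit(reml=True)
                if reml.cov_re.values.max() < 1e-10:
                    raise np.linalg.LinAlgError("singular random-effect variance")
                ml_full = sm.MixedLM(yk, Xf, groups=g).fit(reml=False)
                ml_red = sm.MixedLM(yk, Xr, groups=g).fit(reml=False)
            lrt = 2.0 * (ml_full.llf - ml_red.llf)
            effects = reml.params[[c for c in Xf.columns if c.startswith("cell[")]]
        except (np.linalg.LinAlgError, ValueError):
            row["fallback_ols"] = True
            of = sm.OLS(yk, Xf).fit()
            orr = sm.OLS(yk, Xr).fit()
            lrt = 2.0 * (of.llf - orr.llf)
            effects = of.params[[c for c in Xf.columns if c.startswith("cell[")]]
        lrt = max(float(lrt), 0.0)
        log10_p = stats.chi2.logsf(lrt, k_cell) / LOG10
        row.update(
            {
                "effect": float(effects.iloc[0]) * 100.0,
                "lrt": lrt,
                "df_lrt": k_cell,
                "p": float(np.power(10.0, log10_p)),
                "log10_p": float(log10_p),
            }
        )
        row["significant"] = row["log10_p"] < np.log10(alpha)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-stage comparison
# ---------------------------------------------------------------------------

def crossstage_compare(
    prenatal: pd.DataFrame, postnatal: pd.DataFrame, alpha_post: float
) -> dict:
    """Compare age effects between prenatal and postnatal cohorts.

    Pearson correlation of effects over shared sites; sites passing
    ``alpha_post`` postnatally are classed 'consistent' or 'opposite' by sign
    agreement, others 'postnatal-null'.
    """
    merged = prenatal.merge(postnatal, on="site_id", suffixes=("_pre", "_post"))
    if merged.empty:
        raise ValueError("no shared sites between result tables")
    corr = float(np.corrcoef(merged["effect_pre"], merged["effect_post"])[0, 1])
    sig = merged["p_post"] < alpha_post
    same = np.sign(merged["effect_pre"]) == np.sign(merged["effect_post"])
    klass = np.where(~sig, "postnatal-null", np.where(same, "consistent", "opposite"))
    merged["class"] = klass
    n_sig = int(sig.sum())
    n_opp = int((klass == "opposite").sum())
    return {
        "correlation": corr,
        "table": merged[["site_id", "effect_pre", "effect_post", "class"]],
        "n_shared": len(merged),
        "n_significant_postnatal": n_sig,
        "n_opposite": n_opp,
        "percent_opposite": percent(n_opp, n_sig) if n_sig else float("nan"),
    }
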