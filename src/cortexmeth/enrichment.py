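"""Enrichment statistics for dDMPs across genomic categories.

Four families of tests, each reporting a log-odds "effect", an odds ratio
(exp(effect)), a p-value and a Bonferroni-corrected p:

* chromosome / CpG-island / genic feature enrichment: per-category 2x2
  chi-squared tests (no continuity correction) with Haldane-corrected log
  odds ratios when a cell is empty;
* per-feature direction tests: one-tailed exact binomials with success
  probability equal to the genome-wide hypermethylated proportion among
  dDMPs;
* open-chromatin peak enrichment: one joint logistic regression of dDMP
  status on the peak-membership indicators of *all* cell types, so each
  coefficient controls for every other cell type's peaks;
* gene-set enrichment: gene-level logistic regression of "contains a dDMP"
  on set membership, controlling for gene size (number of annotated sites),
  plus the tiered-bin variant in which dDMPs outside the current top-k bin
  are removed from the background entirely.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PeakSet
from .linear_modelling import LOG10, binomial_tail_log, percent

HALDANE = 0.5


# ---------------------------------------------------------------------------
# 2x2 machinery
# ---------------------------------------------------------------------------

def log_odds_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Log odds ratio and its SE for the table [[a, b], [c, d]].

    Rows are in/out of category, columns dmp/non-dmp.  A Haldane correction
    of 0.5 per cell is applied when any cell is zero.
    """
    cells = np.array([a, b, c, d], float)
    if (cells == 0).any():
        cells = cells + HALDANE
    a_, b_, c_, d_ = cells
    lor = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt((1.0 / cells).sum())
    return float(lor), float(se)


def chi_squared_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table."""
    table = np.array([[a, b], [c, d]], float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def feature_enrichment(
    site_results: pd.DataFrame, annotation: pd.DataFrame, grouping: str
) -> pd.DataFrame:
    """dDMP enrichment per category of ``grouping`` (chromosome, cgi_class or
    genic_class): chi-squared p, log OR, Bonferroni correction."""
    merged = site_results.merge(annotation[["site_id", grouping]], on="site_id")
    dmp = merged["dmp"].to_numpy(bool)
    rows = []
    for category, sub in merged.groupby(grouping):
        inside = merged[grouping] == category
        if inside.sum() == 0:
            continue
        a = int((inside & dmp).sum())
        b = int((inside & ~dmp).sum())
        c = int((~inside & dmp).sum())
        d = int((~inside & ~dmp).sum())
        lor, se = log_odds_2x2(a, b, c, d)
        chi2, p = chi_squared_2x2(a, b, c, d)
        rows.append(
            {
                "category_label": category,
                "n_in_category": a + b,
                "n_dmp_in_category": a,
                "percent_dmp": percent(a, a + b) if a + b else np.nan,
                "effect": lor,
                "odds_ratio": float(np.exp(lor)),
                "se": se,
                "chi2": chi2,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_corrected"] = np.minimum(1.0, out["p"] * len(out))
    return out


def direction_by_feature(
    site_results: pd.DataFrame, annotation: pd.DataFrame, grouping: str
) -> pd.DataFrame:
    """Per-category one-tailed binomial on the hyper/hypo split of dDMPs.

    Success = hypermethylated dDMP; p0 = hypermethylated proportion among
    all dDMPs genome-wide; the tail is taken in the direction of departure
    from p0 and computed exactly in log space.
    """
    dmps = site_results[site_results["dmp"]].merge(
        annotation[["site_id", grouping]], on="site_id"
    )
    if dmps.empty:
        raise ValueError("no dDMPs to test")
    p0 = float((dmps["direction"] == "hyper").mean())
    rows = []
    for category, sub in dmps.groupby(grouping):
        n = len(sub)
        k = int((sub["direction"] == "hyper").sum())
        if n == 0:
            continue
        tail = "upper" if k / n >= p0 else "lower"
        logp = binomial_tail_log(k, n, p0, tail=tail)
        rows.append(
            {
                "category_label": category,
                "n_total": n,
                "n_success": k,
                "percent_hyper": percent(k, n),
                "p0": p0,
                "tail": tail,
                "p_one_tailed": float(np.exp(logp)),
                "log10_p": logp / LOG10,
            }
        )
    out = pd.DataFrame(rows)
    out["p_corrected"] = np.minimum(1.0, out["p_one_tailed"] * len(out))
    return out


# ---------------------------------------------------------------------------
# Peak membership and joint logistic enrichment
# ---------------------------------------------------------------------------

def peak_membership(annotation: pd.DataFrame, peaks: PeakSet) -> np.ndarray:
    """Boolean membership of each annotated site in the peak set's union.

    Sites are 1-based positions; peaks are 0-based half-open, so site p is
    inside [start, end) iff p - 1 lies in it.
    """
    member = np.zeros(len(annotation), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in peaks.intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        run_end = np.maximum.accumulate(np.array([e for _, e in ivs]))
        sel = annotation["chromosome"].to_numpy() == chrom
        pos0 = annotation.loc[sel, "position"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos0.size, dtype=bool)
        hit[ok] = run_end[idx[ok]] > pos0[ok]
        member[sel] = hit
    return member


def peak_enrichment(
    site_results: pd.DataFrame, annotation: pd.DataFrame, peak_sets: list[PeakSet]
) -> pd.DataFrame:
    """Joint logistic regression of dDMP status on all cell-type peak
    indicators; each coefficient is that cell type's log-odds controlling
    for the others.  Complete separation yields a signed infinite-effect
    sentinel with a Fisher-exact fallback p."""
    import statsmodels.api as sm

    if len(peak_sets) < 2:
        raise ValueError("need at least 2 peak sets")
    ann = annotation.set_index("site_id").loc[site_results["site_id"]].reset_index()
    labels = [ps.cell_type_label for ps in peak_sets]
    M = np.column_stack([peak_membership(ann, ps) for ps in peak_sets]).astype(float)
    _check_membership_rank(M, labels)
    y = site_results["dmp"].to_numpy(float)
    X = sm.add_constant(pd.DataFrame(M, columns=labels))

    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.abs(fit.params).max() > 30:
            separated = True
    except Exception:
        separated = True
        fit = None

    rows = []
    for j, label in enumerate(labels):
        if not separated:
            eff = float(fit.params[label])
            se = float(fit.bse[label])
            p = float(fit.pvalues[label])
            sep_flag = False
        else:
            inp = M[:, j].astype(bool)
            a = int((inp & (y == 1)).sum())
            b = int((inp & (y == 0)).sum())
            c = int((~inp & (y == 1)).sum())
            d = int((~inp & (y == 0)).sum())
            _, p = stats.fisher_exact([[a, b], [c, d]])
            lor, se = log_odds_2x2(a, b, c, d)
            eff = float(np.sign(lor) * np.inf) if min(a, b, c, d) == 0 else lor
            sep_flag = True
        rows.append(
            {
                "category_label": label,
                "n_in_category": int(M[:, j].sum()),
                "n_dmp_in_category": int((M[:, j].astype(bool) & (y == 1)).sum()),
                "effect": eff,
                "odds_ratio": float(np.exp(eff)) if np.isfinite(eff) else float("inf"),
                "se": se,
                "p": p,
                "separated": sep_flag,
            }
        )
    out = pd.DataFrame(rows)
    out["p_corrected"] = np.minimum(1.0, out["p"] * len(out))
    return out


def _check_membership_rank(M: np.ndarray, labels: list[str]) -> None:
    for i in range(M.shape[1]):
        for j in range(i + 1, M.shape[1]):
            if np.array_equal(M[:, i], M[:, j]):
                raise ValueError(
                    f"peak sets {labels[i]!r} and {labels[j]!r} have identical "
                    "site membership (perfectly collinear)"
                )
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(M)), M])) < M.shape[1] + 1:
        raise ValueError(f"peak membership matrix is rank deficient across {labels}")


# ---------------------------------------------------------------------------
# Gene-level gene-set enrichment
# ---------------------------------------------------------------------------

def gene_level_table(site_results: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene table: has_dmp (>=1 dDMP site annotated) and n_probes.

    A probe annotated to several genes contributes to each of them; genes
    with no annotated probes are absent.
    """
    merged = site_results[["site_id", "dmp"]].merge(
        annotation[["site_id", "gene_symbols"]], on="site_id"
    )
    exploded = merged.explode("gene_symbols").dropna(subset=["gene_symbols"])
    exploded = exploded[exploded["gene_symbols"] != ""]
    table = (
        exploded.groupby("gene_symbols")
        .agg(has_dmp=("dmp", "any"), n_probes=("site_id", "nunique"))
        .reset_index()
        .rename(columns={"gene_symbols": "gene"})
    )
    return table


def geneset_enrichment(gene_table: pd.DataFrame, gene_set) -> dict:
    """Logistic regression has_dmp ~ in_set + n_probes over all genes.

    The coefficient of ``in_set`` is the enrichment log-odds; p is the
    two-sided Wald test.  Errors if the set shares no genes with the table.
    """
    import statsmodels.api as sm

    members = {g.upper() for g in gene_set.gene_symbols}
    in_set = gene_table["gene"].str.upper().isin(members).astype(float)
    if in_set.sum() == 0:
        raise ValueError(f"gene set {gene_set.set_name!r} has no overlap with the gene table")
    X = sm.add_constant(
        pd.DataFrame({"in_set": in_set, "n_probes": gene_table["n_probes"].astype(float)})
    )
    y = gene_table["has_dmp"].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    eff = float(fit.params["in_set"])
    n_set = int(in_set.sum())
    return {
        "category_label": gene_set.set_name,
        "n_in_category": n_set,
        "n_dmp_in_category": int(gene_table.loc[in_set.astype(bool), "has_dmp"].sum()),
        "percent_dmp_in_set": percent(
            int(gene_table.loc[in_set.astype(bool), "has_dmp"].sum()), n_set
        ),
        "background_percent": percent(int(y.sum()), len(y)),
        "effect": eff,
        "odds_ratio": float(np.exp(eff)),
        "se": float(fit.bse["in_set"]),
        "p": float(fit.pvalues["in_set"]),
    }


def tiered_enrichment(
    site_results: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_set,
    bin_sizes: list[int],
) -> pd.DataFrame:
    """Gene-set enrichment over bins of the top-k most significant dDMPs.

    dDMPs are ranked by p; for each bin size k only the top-k keep dDMP
    status while the *remaining dDMPs are removed from the analysis*, so the
    non-dDMP background is identical across bins.  Bin sizes above the
    number of dDMPs are clamped (with a warning).
    """
    dmps = site_results[site_results["dmp"]].sort_values("log10_p", kind="stable")
    n_dmps = len(dmps)
    rows = []
    for k in bin_sizes:
        if k > n_dmps:
            warnings.warn(f"bin size {k} exceeds {n_dmps} dDMPs; clamped")
            k = n_dmps
        top = set(dmps["site_id"].head(k))
        drop = set(dmps["site_id"]) - top
        sub = site_results[~site_results["site_id"].isin(drop)]
        table = gene_level_table(sub, annotation)
        res = geneset_enrichment(table, gene_set)
        res["bin_size"] = k
        rows.append(res)
    out = pd.DataFrame(rows)
    out["p_corrected"] = np.minimum(1.0, out["p"] * len(out))
    return out
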