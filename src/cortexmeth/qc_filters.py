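"""Site-level filters applied before trajectory modelling.

Three exclusions reduce false nonlinear calls: (i) leave-one-out Z-score
outlier samples (|Z| > 5) are set missing per site; (ii) non-variable sites,
whose middle-80% range (10th-90th percentile span) is below 5% methylation,
are dropped; (iii) constant sites, consistently above 90% or below 10%
methylation in every sample, are dropped.  All boundaries are strict, as
stated for each rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix

SD_FLOOR = 1e-6  # floor on the leave-one-out SD; never divide by zero


def loo_zscore_outliers(values: np.ndarray, z_thresh: float = 5.0) -> np.ndarray:
    """Flag samples whose value is a leave-one-out Z-score outlier.

    For each sample i, Z_i = (x_i - mean_{-i}) / sd_{-i} computed from the
    remaining samples; |Z_i| > z_thresh is flagged.  Missing values are never
    flagged and do not contribute to the leave-one-out statistics.
    """
    x = np.asarray(values, float)
    flags = np.zeros(x.shape, dtype=bool)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 5:
        raise ValueError(f"need >= 5 non-missing values, got {n}")
    s, ss = x[ok].sum(), (x[ok] ** 2).sum()
    m = n - 1
    for i in np.flatnonzero(ok):
        mean_i = (s - x[i]) / m
        var_i = ((ss - x[i] ** 2) - m * mean_i**2) / (m - 1)
        sd_i = max(np.sqrt(max(var_i, 0.0)), SD_FLOOR)
        flags[i] = abs(x[i] - mean_i) / sd_i > z_thresh
    return flags


def apply_outlier_filter(beta: BetaMatrix, z_thresh: float = 5.0) -> tuple[BetaMatrix, pd.DataFrame]:
    """Set leave-one-out outlier values missing, per site; the site is kept."""
    values = beta.values.copy()
    records = []
    for i, sid in enumerate(beta.site_ids):
        flags = loo_zscore_outliers(values[i], z_thresh=z_thresh)
        if flags.any():
            values[i, flags] = np.nan
        records.append(
            {"site_id": sid,
             "outlier_samples": ";".join(np.array(beta.sample_ids)[flags]),
             "n_outliers": int(flags.sum())}
        )
    return BetaMatrix(list(beta.site_ids), list(beta.sample_ids), values), pd.DataFrame(records)


def middle_range(values: np.ndarray, middle_fraction: float = 0.8) -> float:
    """Span of the central ``middle_fraction`` of values (percentile span,
    linear interpolation)."""
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    tail = 100.0 * (1.0 - middle_fraction) / 2.0
    lo, hi = np.percentile(x, [tail, 100.0 - tail])
    return float(hi - lo)


def filter_nonvariable(
    beta: BetaMatrix, middle_fraction: float = 0.8, min_range: float = 0.05
) -> pd.DataFrame:
    """Exclude sites whose middle-80% range is strictly below ``min_range``."""
    records = []
    for i, sid in enumerate(beta.site_ids):
        rng = middle_range(beta.values[i], middle_fraction)
        excluded = rng < min_range
        records.append(
            {"site_id": sid, "middle80_range": rng, "excluded": excluded,
             "reason": "nonvariable" if excluded else "none"}
        )
    return pd.DataFrame(records)


def filter_constant(beta: BetaMatrix, hi: float = 0.90, lo: float = 0.10) -> pd.DataFrame:
    """Exclude sites consistently > hi or consistently < lo in all samples."""
    records = []
    for i, sid in enumerate(beta.site_ids):
        x = beta.values[i]
        x = x[np.isfinite(x)]
        excluded = bool(x.size) and (np.all(x > hi) or np.all(x < lo))
        records.append(
            {"site_id": sid, "excluded": excluded,
             "reason": "constant" if excluded else "none"}
        )
    return pd.DataFrame(records)


def run_qc(
    beta: BetaMatrix,
    z_thresh: float = 5.0,
    middle_fraction: float = 0.8,
    min_range: float = 0.05,
    hi: float = 0.90,
    lo: float = 0.10,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Full pre-trajectory QC: outlier masking then site exclusion.

    Returns the masked matrix restricted to retained sites and a per-site
    FilterReport with columns (site_id, outlier_samples, excluded, reason,
    middle80_range).
    """
    masked, outliers = apply_outlier_filter(beta, z_thresh=z_thresh)
    nonvar = filter_nonvariable(masked, middle_fraction, min_range).set_index("site_id")
    const = filter_constant(masked, hi, lo).set_index("site_id")

    report = outliers.set_index("site_id")
    report["middle80_range"] = nonvar["middle80_range"]
    reason = np.where(nonvar["excluded"], "nonvariable",
                      np.where(const["excluded"], "constant", "none"))
    report["reason"] = reason
    report["excluded"] = reason != "none"
    report = report.reset_index()

    keep = report.loc[~report["excluded"], "site_id"].tolist()
    return masked.subset_sites(keep), report
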