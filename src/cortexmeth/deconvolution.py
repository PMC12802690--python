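"""Reference-based cell-composition estimation from bulk methylation.

A reference matrix of cell-type-discriminating sites is built from purified
samples: per cell type, one-vs-rest t-statistics rank the sites and the top
``num_probes`` by |t| ("any" selection: regardless of direction) are taken;
the reference entry is the within-type mean.  Bulk proportions are the
non-negative least-squares projection of each sample onto the reference
profiles (no sum-to-one constraint; the proportion sum is reported as a
diagnostic).  The quality of each deconvolution is scored by the root mean
square reconstruction error over the reference sites (the CETYGO-style
error): zero for an exact mixture and increasing with reference
misspecification, e.g. when the true cell type is missing from the panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .io_formats import BetaMatrix


def select_reference_probes(
    purified: BetaMatrix,
    cell_labels: pd.Series,
    num_probes: int = 100,
    probe_select: str = "any",
) -> pd.DataFrame:
    """Reference matrix (sites x cell types) from purified samples.

    ``cell_labels`` maps sample id -> cell type (>= 2 types, >= 2 samples
    each).  "any" selection takes, per cell type, the ``num_probes`` sites
    with the largest one-vs-rest |t|; ties break deterministically by
    site_id.  The reference holds within-type mean methylation at the union
    of the selections.
    """
    if probe_select != "any":
        raise ValueError(f"unsupported probe_select {probe_select!r}")
    labels = cell_labels.loc[purified.sample_ids]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    for ct in types:
        if (labels == ct).sum() < 2:
            raise ValueError(f"cell type {ct!r} has < 2 purified samples")

    values = purified.values
    site_ids = np.array(purified.site_ids)
    selected: dict[str, None] = {}
    for ct in types:
        inside = (labels == ct).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, _ = stats.ttest_ind(values[:, inside], values[:, ~inside], axis=1)
        t = np.nan_to_num(t, nan=0.0)
        order = np.lexsort((site_ids, -np.abs(t)))  # |t| desc, then site_id asc
        n_take = min(num_probes, len(site_ids))
        if n_take < num_probes:
            warnings.warn(
                f"only {n_take} candidate sites available (requested {num_probes})"
            )
        for idx in order[:n_take]:
            selected.setdefault(site_ids[idx], None)

    chosen = list(selected)
    sub = purified.subset_sites(chosen)
    ref = pd.DataFrame(index=chosen)
    for ct in types:
        inside = (labels == ct).to_numpy()
        ref[ct] = sub.values[:, inside].mean(axis=1)
    ref.index.name = "site_id"
    return ref


def estimate_proportions(bulk: BetaMatrix, reference: pd.DataFrame) -> pd.DataFrame:
    """Non-negative least-squares proportions per bulk sample.

    Requires >= 50% of reference sites present in the bulk matrix and a
    full-column-rank reference.  Returns one row per sample with the
    per-cell-type weights, their sum and the CETYGO reconstruction error.
    """
    shared = [s for s in reference.index if s in set(bulk.site_ids)]
    if len(shared) < 0.5 * len(reference):
        raise ValueError(
            f"only {len(shared)}/{len(reference)} reference sites present in bulk matrix"
        )
    X = reference.loc[shared].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("reference matrix is rank deficient")
    sub = bulk.subset_sites(shared)
    rows = []
    for j, sample in enumerate(sub.sample_ids):
        y = sub.values[:, j]
        keep = np.isfinite(y)
        w, _ = nnls(X[keep], y[keep])
        row = {"sample_id": sample}
        row.update(dict(zip(reference.columns, w)))
        row["proportion_sum"] = float(w.sum())
        row["cetygo"] = cetygo_score(y[keep], X[keep], w)
        rows.append(row)
    return pd.DataFrame(rows)


def cetygo_score(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> float:
    """Root mean square error between a bulk profile and its reconstruction."""
    resid = np.asarray(y, float) - np.asarray(X, float) @ np.asarray(w, float)
    return float(np.sqrt(np.mean(resid**2)))
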