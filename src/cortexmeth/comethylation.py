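"""Signed co-methylation network modules over nonlinear sites.

A simplified weighted-correlation-network procedure: signed adjacency at
soft-threshold power 12, topological overlap (TOM) similarity, average
linkage hierarchical clustering of 1 - TOM with a static height cut, and
size filtering.  Clusters below the minimum size are labelled "unassigned"
(the grey-module equivalent) and excluded from eigengene and hub
computation.  Module eigengenes are the first principal component of the
standardised member-site matrix, sign-oriented so that the mean member kME
is positive; hub sites are the members most correlated with their module
eigengene.

This is a deliberate simplification of dynamic-tree-cut module detection:
the cut height and minimum module size are exposed as parameters rather
than re-deriving the full procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import BetaMatrix

UNASSIGNED = "unassigned"
DEFAULT_POWER = 12
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.995


def signed_adjacency(values: np.ndarray, power: int = DEFAULT_POWER) -> np.ndarray:
    """a_ij = ((1 + cor(x_i, x_j)) / 2) ^ power over sites (rows)."""
    sds = np.nanstd(values, axis=1)
    if np.any(sds == 0):
        i = int(np.flatnonzero(sds == 0)[0])
        raise ValueError(f"zero-variance site at row {i}")
    cor = pd.DataFrame(values.T).corr().to_numpy()
    return ((1.0 + cor) / 2.0) ** power


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1,
    where l_ij sums a_iu a_uj over u distinct from i and j and k_i is the
    connectivity sum_{j != i} a_ij."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # includes u = i and u = j terms, both zero after the fill
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(beta: BetaMatrix, power: int = DEFAULT_POWER) -> np.ndarray:
    """TOM similarity matrix of the sites of ``beta``."""
    if beta.n_sites < 20 or beta.n_samples < 10:
        raise ValueError("network construction needs >= 20 sites and >= 10 samples")
    return topological_overlap(signed_adjacency(beta.values, power))


def detect_modules(
    tom: np.ndarray,
    site_ids: list[str],
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float | None = None,
) -> pd.DataFrame:
    """Average-linkage clustering of 1 - TOM with a static cut.

    With ``cut_height=None`` the cut is chosen from the dendrogram itself:
    candidate heights between successive merges are scanned and the one
    producing the most clusters of at least ``min_module_size`` wins (ties
    go to the highest cut, i.e. the most inclusive modules).  An explicit
    numeric height reproduces the classic static cut (e.g. 0.995).

    Clusters smaller than ``min_module_size`` become "unassigned"; the rest
    are labelled M1, M2, ... in decreasing size order.
    """
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    if cut_height is None:
        cut_height = _best_static_cut(Z, min_module_size)
    raw = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].sort_values(ascending=False)
    label_of = {cl: f"M{rank + 1}" for rank, cl in enumerate(big.index)}
    labels = [label_of.get(cl, UNASSIGNED) for cl in raw]
    return pd.DataFrame({"site_id": site_ids, "module": labels})


def _best_static_cut(Z: np.ndarray, min_module_size: int) -> float:
    """Static cut height maximising the number of size-qualified clusters."""
    heights = np.unique(Z[:, 2])
    candidates = np.concatenate([(heights[:-1] + heights[1:]) / 2.0,
                                 [heights[-1] + 1.0]])
    best_t, best_count = candidates[-1], -1
    for t in candidates:
        raw = fcluster(Z, t=t, criterion="distance")
        count = int((np.bincount(raw) >= min_module_size).sum())
        if count >= best_count:  # >= so ties pick the highest (latest) cut
            best_t, best_count = t, count
    return float(best_t)


def eigengene(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of the standardised site x sample matrix.

    Returns (per-sample eigengene scores, fraction of variance explained);
    the sign is oriented so the mean correlation with member sites is
    positive, and loadings are unit norm by construction of the SVD.
    """
    X = values - values.mean(axis=1, keepdims=True)
    sds = X.std(axis=1, ddof=0)
    sds[sds == 0] = 1.0
    X = X / sds[:, None]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = Vt[0]
    explained = float(S[0] ** 2 / (S**2).sum())
    kme = _row_correlations(values, scores)
    if np.nanmean(kme) < 0:
        scores = -scores
    return scores, explained


def _row_correlations(values: np.ndarray, vec: np.ndarray) -> np.ndarray:
    vc = vec - vec.mean()
    Xc = values - values.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (vc**2).sum())
    denom[denom == 0] = np.nan
    return (Xc @ vc) / denom


def module_eigengenes(
    beta: BetaMatrix, assignment: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eigengenes per module and kME of every assigned site.

    Returns (eigengene table: module x sample, kME table with columns
    site_id, module, kME).  Unassigned sites are excluded.
    """
    eg_rows, kme_rows = {}, []
    for module, sub in assignment[assignment["module"] != UNASSIGNED].groupby("module"):
        sids = sub["site_id"].tolist()
        values = beta.subset_sites(sids).values
        scores, _ = eigengene(values)
        eg_rows[module] = scores
        for sid, k in zip(sids, _row_correlations(values, scores)):
            kme_rows.append({"site_id": sid, "module": module, "kME": float(k)})
    eg = pd.DataFrame(eg_rows, index=beta.sample_ids).T
    eg.index.name = "module"
    return eg, pd.DataFrame(kme_rows)


def hub_sites(kme_table: pd.DataFrame, top_n: int = 1) -> pd.DataFrame:
    """Top ``top_n`` sites per module by kME (ties broken by site_id)."""
    out = (
        kme_table.sort_values(["module", "kME", "site_id"],
                              ascending=[True, False, True], kind="stable")
        .groupby("module")
        .head(top_n)
        .reset_index(drop=True)
    )
    return out


def pca_project(reference: BetaMatrix, query: BetaMatrix, k: int = 2) -> dict:
    """Project a query cohort into the reference cohort's PC space.

    PCA is fitted on the reference samples (sites standardised by reference
    mean/SD); query samples at the same sites are transformed with the
    reference loadings and centering.  Returns reference scores, query
    scores and the explained-variance fractions.
    """
    ref_sites = reference.site_ids
    q = query.subset_sites(ref_sites)
    Xr = reference.values
    mu = Xr.mean(axis=1, keepdims=True)
    sd = Xr.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Zr = (Xr - mu) / sd
    Zq = (q.values - mu) / sd
    U, S, Vt = np.linalg.svd(Zr, full_matrices=False)
    k = min(k, S.size)
    loadings = U[:, :k]  # sites x k, orthonormal
    scores_ref = Zr.T @ loadings
    scores_query = Zq.T @ loadings
    explained = (S[:k] ** 2) / (S**2).sum()
    cols = [f"PC{i + 1}" for i in range(k)]
    return {
        "reference_scores": pd.DataFrame(scores_ref, index=reference.sample_ids, columns=cols),
        "query_scores": pd.DataFrame(scores_query, index=q.sample_ids, columns=cols),
        "explained_variance": explained,
        "loadings": pd.DataFrame(loadings, index=ref_sites, columns=cols),
    }
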