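"""Grouping lactations by daily-yield pattern.

Lactation curves differ systematically in shape (peak timing, peak height,
persistency), and a small minority are atypical (delayed peak, monotone
increase).  To group lactations by *shape* rather than production level,
each lactation is Z-scored over its observed days, reduced to 24 decadal
means (DIM 31..270 in 10-day bins), projected onto the first five principal
components, and clustered by Ward agglomerative clustering on Euclidean
distances in PC space.  The number of clusters is chosen by the mean
silhouette coefficient.  Within each cluster, records deviating three or
more SD from the per-DIM cluster mean are removed as outliers.

The per-cluster mean Z-scored profile over DIM 1..305 feeds the edge rule
of the imputation module, and the cluster label is a fixed effect in the
downstream genetic models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .elc import N_DIM
from .preprocessing import LactationSeries

DECADAL_START = 31
DECADAL_END = 270
N_BINS = (DECADAL_END - DECADAL_START + 1) // 10  # 24


class DegenerateSeriesError(ValueError):
    """Raised when a lactation cannot be Z-scored (constant / too short)."""


@dataclass
class ClusterModel:
    k: int
    assignments: dict[tuple[str, int], int]  # (cow_id, parity) -> cluster 0..k-1
    normalized_profiles: np.ndarray  # k x 305 mean Z-scored yield per DIM
    silhouette_by_k: dict[int, float]
    pca_loadings: np.ndarray  # 24 x n_components
    pc_variance_explained: np.ndarray
    excluded: list[tuple[str, int]]

    def profile_for(self, lactation: LactationSeries) -> np.ndarray:
        return self.normalized_profiles[self.assignments[lactation.key]]


def zscore_normalize(values: np.ndarray) -> np.ndarray:
    """Z-score a lactation over its observed days (n-1 denominator).

    NaN slots (missing days) stay NaN.  Raises
    :class:`DegenerateSeriesError` for constant or nearly-empty series, in
    which case the lactation is flagged and excluded from clustering.
    """
    values = np.asarray(values, dtype=float)
    obs = values[~np.isnan(values)]
    if obs.size < 2:
        raise DegenerateSeriesError("need at least 2 observed values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise DegenerateSeriesError("constant series has zero SD")
    return (values - obs.mean()) / sd


def decadal_means(normalized: np.ndarray) -> np.ndarray:
    """24 ten-day bin means over DIM 31..270 (bin j covers DIM 31+10(j-1)..40+10(j-1)).

    A bin with no observed day yields NaN; the caller excludes such
    lactations from clustering.
    """
    normalized = np.asarray(normalized, dtype=float)
    if normalized.size != N_DIM:
        raise ValueError(f"expected a {N_DIM}-slot series")
    out = np.empty(N_BINS)
    for j in range(N_BINS):
        lo = DECADAL_START - 1 + 10 * j
        chunk = normalized[lo : lo + 10]
        obs = chunk[~np.isnan(chunk)]
        out[j] = obs.mean() if obs.size else np.nan
    return out


def fit_pca(matrix: np.ndarray, n_components: int = 5) -> tuple[np.ndarray, PCA]:
    """Project decadal-mean rows onto the leading principal components.

    Columns are centred internally (covariance PCA, no re-scaling: the rows
    were already Z-scored).  Returns (scores, fitted PCA object).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < n_components:
        raise ValueError("need at least as many rows as components")
    rank = np.linalg.matrix_rank(matrix - matrix.mean(axis=0))
    if rank < n_components:
        raise ValueError(f"matrix rank {rank} < {n_components} components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    return scores, pca


def ward_cluster(points: np.ndarray, k: int) -> np.ndarray:
    """Ward minimum-variance agglomerative clustering cut at k clusters.

    Merges minimise the increase in total within-cluster sum of squares
    (the Lance-Williams update on squared Euclidean distances).  Labels are
    0-based.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == n:
        return np.arange(n)
    merge_tree = linkage(points, method="ward")
    return fcluster(merge_tree, t=k, criterion="maxclust") - 1


def select_k_by_silhouette(
    points: np.ndarray, k_range=range(2, 11)
) -> tuple[int, dict[int, float]]:
    """Choose the cluster count maximising the mean silhouette coefficient.

    Returns (best k, full silhouette-by-k table). Euclidean distances in
    PC space; ties go to the smaller k.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    table: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = ward_cluster(points, k)
        table[k] = float(silhouette_score(points, labels, metric="euclidean"))
    if not table:
        raise ValueError("no feasible k in the requested range")
    best = max(table, key=lambda k: (table[k], -k))
    return best, table


def remove_within_cluster_outliers(
    lactations: list[LactationSeries],
    assignments: dict[tuple[str, int], int],
) -> pd.DataFrame:
    """Per cluster and per DIM, delete raw yields >= 3 SD from the mean.

    The mean and SD (n-1 denominator) are computed over observed values of
    the cluster members at that DIM; records with ``|y - mean| >= 3*SD``
    are set to missing in place ("three or more SD", so exactly 3 SD is
    removed).  Applied once, not iterated.  Returns the removal report.
    """
    groups: dict[int, list[LactationSeries]] = {}
    for lact in lactations:
        cl = assignments.get(lact.key)
        if cl is not None:
            groups.setdefault(cl, []).append(lact)

    removed = []
    for cl, members in sorted(groups.items()):
        ymat = np.vstack([m.yields for m in members])
        obs = np.vstack([m.observed_mask for m in members])
        vals = np.where(obs, ymat, np.nan)
        with np.errstate(invalid="ignore"):
            n_obs = obs.sum(axis=0)
            mean = np.nanmean(np.where(n_obs > 0, vals, np.nan), axis=0)
            sd = np.nanstd(vals, axis=0, ddof=1)
        for i, m in enumerate(members):
            bad = (
                m.observed_mask
                & (n_obs >= 2)
                & (sd > 0)
                & (np.abs(m.yields - mean) >= 3 * sd)
            )
            for dim0 in np.flatnonzero(bad):
                removed.append(
                    {
                        "cluster": cl,
                        "cow_id": m.cow_id,
                        "parity": m.parity,
                        "dim": dim0 + 1,
                        "yield_kg": m.yields[dim0],
                    }
                )
            m.yields[bad] = np.nan
            m.observed_mask[bad] = False
    return pd.DataFrame(removed, columns=["cluster", "cow_id", "parity", "dim", "yield_kg"])


def cluster_lactations(
    lactations: list[LactationSeries],
    k_range=range(2, 11),
    n_components: int = 5,
    k: int | None = None,
    remove_outliers: bool = True,
) -> ClusterModel:
    """Full clustering stage: Z-score, decadal means, PCA, Ward, silhouette.

    Lactations that cannot be Z-scored or that have an empty decadal bin
    are excluded (flagged in ``excluded``) but still receive a cluster
    label afterwards by nearest normalized profile, so the imputation edge
    rule has a profile for every lactation.  When ``remove_outliers`` the
    3-SD per-DIM rule is applied in place and the profiles are computed on
    the cleaned data.
    """
    feats, keys, zrows = [], [], {}
    excluded: list[tuple[str, int]] = []
    for lact in lactations:
        try:
            z = zscore_normalize(np.where(lact.observed_mask, lact.yields, np.nan))
        except DegenerateSeriesError:
            excluded.append(lact.key)
            continue
        bins = decadal_means(z)
        if np.any(np.isnan(bins)):
            excluded.append(lact.key)
            continue
        feats.append(bins)
        keys.append(lact.key)
        zrows[lact.key] = z
    if len(feats) < n_components + 1:
        raise ValueError("too few clusterable lactations")

    X = np.vstack(feats)
    scores, pca = fit_pca(X, n_components=n_components)
    if k is None:
        k, sil_table = select_k_by_silhouette(scores, k_range)
    else:
        _, sil_table = select_k_by_silhouette(scores, [k]) if 2 <= k <= len(keys) - 1 else (k, {})
    labels = ward_cluster(scores, k)
    assignments = {key: int(lab) for key, lab in zip(keys, labels)}

    if remove_outliers:
        remove_within_cluster_outliers(lactations, assignments)

    profiles = _normalized_profiles(lactations, assignments, k)

    # attach excluded lactations to the nearest profile so imputation works
    for lact in lactations:
        if lact.key in excluded:
            try:
                z = zscore_normalize(np.where(lact.observed_mask, lact.yields, np.nan))
            except DegenerateSeriesError:
                continue
            obs = ~np.isnan(z)
            dists = [
                np.nanmean((profiles[c, obs] - z[obs]) ** 2) for c in range(k)
            ]
            assignments[lact.key] = int(np.argmin(dists))

    for lact in lactations:
        if lact.key in assignments:
            lact.cluster_id = assignments[lact.key]

    return ClusterModel(
        k=k,
        assignments=assignments,
        normalized_profiles=profiles,
        silhouette_by_k=sil_table,
        pca_loadings=pca.components_.T,
        pc_variance_explained=pca.explained_variance_ratio_,
        excluded=excluded,
    )


def _normalized_profiles(
    lactations: list[LactationSeries],
    assignments: dict[tuple[str, int], int],
    k: int,
) -> np.ndarray:
    """Per-cluster per-DIM mean of the members' Z-scored yields (k x 305)."""
    sums = np.zeros((k, N_DIM))
    counts = np.zeros((k, N_DIM))
    for lact in lactations:
        cl = assignments.get(lact.key)
        if cl is None:
            continue
        try:
            z = zscore_normalize(np.where(lact.observed_mask, lact.yields, np.nan))
        except DegenerateSeriesError:
            continue
        obs = ~np.isnan(z)
        sums[cl, obs] += z[obs]
        counts[cl, obs] += 1
    with np.errstate(invalid="ignore"):
        profiles = sums / counts
    # fall back to the global mean profile where a cluster has no data at a DIM
    total = sums.sum(axis=0)
    tc = counts.sum(axis=0)
    global_profile = np.divide(total, tc, out=np.zeros(N_DIM), where=tc > 0)
    empty = counts == 0
    profiles[empty] = np.broadcast_to(global_profile, profiles.shape)[empty]
    return profiles


def assignments_frame(model: ClusterModel) -> pd.DataFrame:
    rows = [
        {"cow_id": c, "parity": p, "cluster": cl}
        for (c, p), cl in sorted(model.assignments.items())
    ]
    return pd.DataFrame(rows, columns=["cow_id", "parity", "cluster"])
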