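"""Trajectory clustering: Euclidean distances, Ward linkage, elbow
selection of k, and K-means assignment.

The cluster count is chosen from the within-cluster sum-of-squares
(SSE) curve — the K-means objective

    J(k) = sum_i sum_{x in C_i} ||x − mu_i||^2

evaluated at the fitted solution for each candidate k — by taking the
interior k maximising the discrete second difference
SSE(k−1) − 2·SSE(k) + SSE(k+1), the standard formalization of the
"elbow".  Ward's merge tree over the same Euclidean geometry is exposed
alongside for comparison; final labels come from K-means (k-means++
initialisation, best of ``n_init`` restarts) relabelled canonically by
descending cluster size so identities are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .errors import ConfigurationError, ValidationError
from .preprocess import ScoreMatrix

DEFAULT_SEED = 42
DEFAULT_N_INIT = 10
DEFAULT_K_RANGE = tuple(range(1, 9))


@dataclass
class ClusterModel:
    """Fitted cluster assignment for one cohort."""

    k: int
    labels: np.ndarray  # (n,) ints in [0, k)
    centroids: np.ndarray  # (k, 5)
    sse: float  # objective J at the fitted solution
    sse_curve: dict[int, float] | None = None
    linkage_matrix: np.ndarray | None = None  # Ward merge tree

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def distance_matrix(matrix: ScoreMatrix) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise Euclidean distances."""
    if matrix.n < 2:
        raise ValidationError("distance matrix requires at least 2 rows")
    return squareform(pdist(matrix.values, metric="euclidean"))


def ward_linkage(D: np.ndarray) -> np.ndarray:
    """Ward merge tree from a square (or condensed) distance matrix.

    Returns the standard (n−1) × 4 linkage matrix; merge heights are
    non-decreasing for Ward on Euclidean distances.
    """
    D = np.asarray(D, dtype=float)
    condensed = squareform(D, checks=True) if D.ndim == 2 else D
    return linkage(condensed, method="ward")


def cut_tree_labels(linkage_matrix: np.ndarray, k: int) -> np.ndarray:
    """Partition into k clusters by cutting the merge tree; canonical labels."""
    raw = fcluster(linkage_matrix, t=k, criterion="maxclust")
    return canonical_relabel(raw - 1)


def canonical_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by descending size, ties broken by lowest member index."""
    labels = np.asarray(labels)
    ids, counts = np.unique(labels, return_counts=True)
    first_member = np.array([np.argmax(labels == i) for i in ids])
    order = np.lexsort((first_member, -counts))
    mapping = {int(ids[old]): new for new, old in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels], dtype=int)


def _fit_kmeans_raw(values: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    km.fit(values)
    return km


def kmeans_fit(
    matrix: ScoreMatrix,
    k: int,
    seed: int = DEFAULT_SEED,
    n_init: int = DEFAULT_N_INIT,
    sse_curve: dict[int, float] | None = None,
    with_linkage: bool = True,
) -> ClusterModel:
    """Lloyd's algorithm with k-means++ init, best of ``n_init`` restarts."""
    n = matrix.n
    if not 1 <= k <= n:
        raise ConfigurationError(f"k={k} outside [1, n={n}]")
    km = _fit_kmeans_raw(matrix.values, k, seed, n_init)
    new_labels = canonical_relabel(km.labels_)
    # reorder centroids to match canonical labels
    centroids = np.empty_like(km.cluster_centers_)
    for old in range(k):
        new = new_labels[np.argmax(km.labels_ == old)]
        centroids[new] = km.cluster_centers_[old]
    lk = ward_linkage(distance_matrix(matrix)) if (with_linkage and n >= 2) else None
    return ClusterModel(
        k=k,
        labels=new_labels,
        centroids=centroids,
        sse=float(km.inertia_),
        sse_curve=sse_curve,
        linkage_matrix=lk,
    )


def elbow_select(
    matrix: ScoreMatrix,
    k_range=DEFAULT_K_RANGE,
    seed: int = DEFAULT_SEED,
    n_init: int = DEFAULT_N_INIT,
) -> tuple[int, dict[int, float]]:
    """Choose k by the maximum discrete second difference of the SSE curve.

    ``k_range`` must be a contiguous ascending run of at least three
    integers within [1, n−1] so interior second differences exist.
    """
    ks = [int(k) for k in k_range]
    if len(ks) < 3:
        raise ConfigurationError("k_range must contain at least 3 values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ConfigurationError("k_range must be contiguous ascending integers")
    if ks[0] < 1 or ks[-1] > matrix.n - 1:
        raise ConfigurationError(f"k_range must lie within [1, {matrix.n - 1}]")

    sse_curve: dict[int, float] = {}
    for k in ks:
        km = _fit_kmeans_raw(matrix.values, k, seed, n_init)
        sse_curve[k] = float(km.inertia_)

    best_k, best_curvature = None, -np.inf
    for k in ks[1:-1]:
        curvature = sse_curve[k - 1] - 2.0 * sse_curve[k] + sse_curve[k + 1]
        if curvature > best_curvature:
            best_k, best_curvature = k, curvature
    return best_k, sse_curve


def fit_trajectory_clusters(
    matrix: ScoreMatrix,
    k_range=DEFAULT_K_RANGE,
    seed: int = DEFAULT_SEED,
    n_init: int = DEFAULT_N_INIT,
) -> ClusterModel:
    """Full clustering stage: elbow selection then K-means at the chosen k."""
    k, sse_curve = elbow_select(matrix, k_range=k_range, seed=seed, n_init=n_init)
    return kmeans_fit(matrix, k, seed=seed, n_init=n_init, sse_curve=sse_curve)
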