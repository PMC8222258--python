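"""Soft clustering of five-condition expression trajectories.

The workflow mirrors the standard time-course recipe: genes are filtered by
raw-expression variance across the five conditions (sample variance, n-1
denominator, threshold 3 by default), each surviving trajectory is z-scored
per row, soft-clustered by fuzzy c-means with fuzziness m = 1.5, and the
soft clusters are aggregated into a small number of main clusters by
complete-linkage hierarchical clustering (on the soft-cluster centroids by
default, or on the standardized rows directly).

Fuzzy c-means minimises  J = sum_i sum_k u_ik^m ||x_i - v_k||^2  by
alternating the membership update u_ik = (1/d_ik^2)^(1/(m-1)) (normalised
per gene) and the weighted centroid update v_k = sum_i u_ik^m x_i /
sum_i u_ik^m.  Initialisation is seeded farthest-point sampling, so runs
are deterministic given the seed.  J is checked to be non-increasing on
every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist


def variance_filter(matrix: pd.DataFrame, threshold: float = 3.0
                    ) -> pd.DataFrame:
    """Keep genes whose sample variance across conditions is >= threshold."""
    keep = matrix.var(axis=1, ddof=1) >= threshold
    return matrix.loc[keep]


def standardize_rows(matrix: pd.DataFrame, return_params: bool = False):
    """Z-score each row to mean 0 and (sample) standard deviation 1.

    Constant rows have no scale and are rejected; the variance filter
    upstream removes them in the normal workflow.
    """
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"constant row {bad!r} cannot be standardized")
    z = matrix.sub(means, axis=0).div(sds, axis=0)
    if return_params:
        return z, means, sds
    return z


@dataclass
class SoftClusterResult:
    membership: pd.DataFrame      # genes x clusters, rows sum to 1
    centroids: pd.DataFrame       # clusters x conditions
    objective: list[float]        # J after each iteration
    hard_labels: pd.Series        # argmax membership per gene
    n_iter: int
    converged: bool


def _farthest_point_init(X: np.ndarray, c: int,
                         rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    chosen = [int(rng.integers(n))]
    d = np.linalg.norm(X - X[chosen[0]], axis=1)
    for _ in range(1, c):
        nxt = int(np.argmax(d))  # ties -> lowest index, deterministic
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(X - X[nxt], axis=1))
    return X[chosen].copy()


def fuzzy_cmeans(matrix: pd.DataFrame | np.ndarray,
                 n_clusters: int,
                 m: float = 1.5,
                 max_iterations: int = 300,
                 tol: float = 1e-6,
                 seed: int = 0) -> SoftClusterResult:
    """Fuzzy c-means on (standardized) trajectories.

    Convergence is declared when the largest membership change between
    iterations drops below ``tol``.  Points exactly coinciding with a
    centroid get membership 1 there (split evenly over coinciding
    centroids), the standard singularity handling.
    """
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    X = np.asarray(matrix, dtype=float)
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        columns = matrix.columns
    else:
        index = pd.RangeIndex(X.shape[0])
        columns = pd.RangeIndex(X.shape[1])
    n = X.shape[0]
    if n < n_clusters:
        raise ValueError("need at least as many rows as clusters")

    rng = np.random.default_rng(seed)
    V = _farthest_point_init(X, n_clusters, rng)
    exponent = 1.0 / (m - 1.0)
    U_prev = None
    objective: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        d2 = cdist(X, V, metric="sqeuclidean")
        U = np.zeros_like(d2)
        zero = d2 <= 1e-300
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore"):
            w = d2 ** (-exponent)
        U[~any_zero] = (w[~any_zero]
                        / w[~any_zero].sum(axis=1, keepdims=True))
        if any_zero.any():
            U[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1,
                                                              keepdims=True)
        Um = U ** m
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        J = float(np.sum(Um * cdist(X, V, metric="sqeuclidean")))
        if objective and J > objective[-1] + 1e-9 * max(1.0, objective[-1]):
            raise AssertionError(
                f"fuzzy c-means objective increased: {objective[-1]} -> {J}")
        objective.append(J)
        if U_prev is not None and np.abs(U - U_prev).max() < tol:
            converged = True
            break
        U_prev = U

    cluster_ids = pd.RangeIndex(n_clusters, name="cluster")
    membership = pd.DataFrame(U, index=index, columns=cluster_ids)
    centroids = pd.DataFrame(V, index=cluster_ids, columns=columns)
    hard = pd.Series(np.argmax(U, axis=1), index=index, name="cluster")
    return SoftClusterResult(membership=membership, centroids=centroids,
                             objective=objective, hard_labels=hard,
                             n_iter=n_iter, converged=converged)


def hierarchical_main_clusters(matrix: pd.DataFrame,
                               n_main: int,
                               linkage_method: str = "complete",
                               soft: SoftClusterResult | None = None
                               ) -> tuple[pd.Series, pd.DataFrame, np.ndarray]:
    """Aggregate trajectories into main clusters by complete linkage.

    With ``soft`` given, the agglomeration runs on the soft-cluster
    centroids and genes inherit the main cluster of their hard label;
    otherwise it runs on the rows of ``matrix`` directly.  Returns
    (per-gene labels starting at 1, per-cluster mean trajectories, the
    scipy linkage matrix).
    """
    if soft is not None:
        points = soft.centroids.to_numpy()
        if len(points) < n_main:
            raise ValueError("fewer soft clusters than requested main clusters")
        Z = linkage(points, method=linkage_method, metric="euclidean")
        centroid_main = fcluster(Z, t=n_main, criterion="maxclust")
        labels = soft.hard_labels.map(
            lambda k: int(centroid_main[k])).rename("main_cluster")
    else:
        if len(matrix) < n_main:
            raise ValueError("fewer rows than requested main clusters")
        Z = linkage(matrix.to_numpy(), method=linkage_method,
                    metric="euclidean")
        labels = pd.Series(fcluster(Z, t=n_main, criterion="maxclust"),
                           index=matrix.index, name="main_cluster")
    means = matrix.groupby(labels).mean()
    means.index.name = "main_cluster"
    return labels, means, Z
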