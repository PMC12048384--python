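"""k-means clustering of features by their mutual-information profiles.

Each retained feature is represented by its row of the MI matrix (its MI
against every other retained feature), so the clustering geometry is
entirely determined by pairwise MI.  Lloyd's algorithm is implemented
directly because the pipeline fixes details a library implementation does
not expose: initial centroids drawn uniformly from the data points
(without k-means++), nearest-centroid ties broken by the lowest cluster
id, and an emptied cluster reseeded with the point farthest from that
cluster's previous centroid.  Restarts are ranked by WCSS and the best
kept, and the within-cluster sum of squares is checked to be
non-increasing across every Lloyd iteration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import index_to_tripeptide
from .mi import MIMatrix


@dataclass
class ClusterModel:
    """Fitted k-means model: centroids, assignment and diagnostics."""

    centroids: np.ndarray
    assignment: np.ndarray
    wcss: float
    n_iterations: int
    restart_seed: int
    restart_wcss: list[float]

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "K": self.n_clusters,
            "wcss": self.wcss,
            "n_iterations": self.n_iterations,
            "restart_seed": self.restart_seed,
            "restart_wcss": self.restart_wcss,
        }, indent=2))


def _assign(points: np.ndarray, centroids: np.ndarray,
            point_sq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid assignment; argmin breaks ties at lowest id."""
    # ||x - mu||^2 = ||x||^2 - 2 x.mu + ||mu||^2, computed blockwise
    cross = points @ centroids.T
    cent_sq = (centroids ** 2).sum(axis=1)
    d2 = point_sq[:, None] - 2.0 * cross + cent_sq[None, :]
    np.clip(d2, 0.0, None, out=d2)
    labels = np.argmin(d2, axis=1)
    return labels, d2


def _update_centroids(points: np.ndarray, labels: np.ndarray,
                      K: int) -> tuple[np.ndarray, np.ndarray]:
    """Cluster means via a one-hot matrix product (no per-cluster loop)."""
    counts = np.bincount(labels, minlength=K)
    onehot = np.zeros((K, points.shape[0]), dtype=points.dtype)
    onehot[labels, np.arange(points.shape[0])] = 1.0
    centroids = onehot @ points
    centroids /= counts[:, None]
    return centroids, counts


def _lloyd(points: np.ndarray, K: int, max_iter: int, tol: float,
           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    N = points.shape[0]
    point_sq = (points.astype(np.float64) ** 2).sum(axis=1)
    total_sq = float(point_sq.sum())
    init = rng.choice(N, size=K, replace=False)
    centroids = points[init].copy()
    prev_wcss = math.inf
    labels = np.zeros(N, dtype=np.int64)
    for iteration in range(1, max_iter + 1):
        labels, d2 = _assign(points, centroids,
                             point_sq.astype(points.dtype))
        # reseed emptied clusters with the point farthest from the
        # cluster's previous centroid (deterministic; ties -> lowest
        # index).  Each reseed takes a distinct point, and only from a
        # cluster that keeps at least one member.
        counts = np.bincount(labels, minlength=K)
        for k in np.flatnonzero(counts == 0):
            movable = counts[labels] > 1
            if not movable.any():
                break
            dist = np.where(movable, d2[:, k], -np.inf)
            farthest = int(np.argmax(dist))
            counts[labels[farthest]] -= 1
            labels[farthest] = k
            counts[k] = 1
        new_centroids, counts = _update_centroids(points, labels, K)
        # WCSS identity for mean centroids:
        # sum_k sum_{x in S_k} ||x - mu_k||^2
        #   = sum ||x||^2 - sum_k n_k ||mu_k||^2
        cent_sq = (new_centroids.astype(np.float64) ** 2).sum(axis=1)
        wcss = total_sq - float((counts * cent_sq).sum())
        if wcss > prev_wcss + 1e-5 * max(1.0, abs(prev_wcss)):
            raise RuntimeError(
                f"WCSS increased ({prev_wcss} -> {wcss}) in Lloyd iteration")
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        prev_wcss = wcss
        if shift < tol:
            break
    return centroids, labels, iteration


def kmeans(points: np.ndarray, K: int, n_restarts: int = 10,
           max_iter: int = 300, tol: float = 1e-6,
           seed: int = 0) -> ClusterModel:
    """Best-of-restarts Lloyd k-means with Euclidean distance.

    ``K`` must not exceed the number of points.  Each restart draws K
    distinct data points as initial centroids; the restart with the
    lowest WCSS wins (ties -> earliest restart).
    """
    points = np.ascontiguousarray(points)
    N = points.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > N:
        raise ValueError(f"K={K} exceeds number of points N={N}")
    best = None
    restart_wcss: list[float] = []
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        centroids, labels, n_iter = _lloyd(points, K, max_iter, tol, rng)
        diff = points.astype(np.float64) - centroids[labels].astype(
            np.float64)
        wcss = float((diff ** 2).sum())
        restart_wcss.append(wcss)
        if best is None or wcss < best[0]:
            best = (wcss, centroids, labels, n_iter, restart)
    wcss, centroids, labels, n_iter, restart = best
    return ClusterModel(centroids=centroids.astype(np.float64),
                        assignment=labels, wcss=wcss,
                        n_iterations=n_iter, restart_seed=restart,
                        restart_wcss=restart_wcss)


@dataclass
class ClusterAssignment:
    """Partition of retained features into K clusters.

    ``cluster_ids[k]`` is the cluster of retained feature k;
    ``feature_indices[k]`` its original 1-based index.
    """

    cluster_ids: np.ndarray
    feature_indices: np.ndarray
    model: ClusterModel

    @property
    def n_clusters(self) -> int:
        return self.model.n_clusters

    def members(self, cluster: int) -> np.ndarray:
        """Retained-space positions of the features in ``cluster``."""
        return np.flatnonzero(self.cluster_ids == cluster)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tripeptide": [index_to_tripeptide(int(i))
                           for i in self.feature_indices],
            "feature_index": self.feature_indices,
            "cluster_id": self.cluster_ids,
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_n_clusters(n_retained: int) -> int:
    """Default K: max(2, round(sqrt(d_retained))), capped at d_retained."""
    return min(n_retained, max(2, round(math.sqrt(n_retained))))


def cluster_features(mi: MIMatrix, K: int, n_restarts: int = 10,
                     max_iter: int = 300, tol: float = 1e-6,
                     seed: int = 0) -> ClusterAssignment:
    """Cluster features on their MI-profile rows with k-means."""
    if K > mi.n_features:
        raise ValueError(
            f"K={K} exceeds retained feature count {mi.n_features}")
    points = mi.values.astype(np.float32)
    model = kmeans(points, K, n_restarts=n_restarts, max_iter=max_iter,
                   tol=tol, seed=seed)
    return ClusterAssignment(cluster_ids=model.assignment,
                             feature_indices=mi.feature_indices,
                             model=model)
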