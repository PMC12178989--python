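"""Comparator approaches: tracks-only, raw-feature clustering, centroid clustering.

Three reference pathways bracket the constrained method:

* tracks-only — score the tracker's labels directly (no post-processing);
* raw clustering — cluster the per-detection feature vectors with an
  off-the-shelf algorithm, ignoring tracks entirely;
* centroid clustering — collapse each track to the centroid of its members'
  features, cluster the centroids, and propagate the cluster labels back to
  the detections.

Distance-based algorithms are normally run on z-scored features (see
:func:`trackreid.features.zscore`); the DBSCAN comparator sweeps its
parameter grid and keeps the run whose cluster count lands closest to the
requested K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import DBSCAN, KMeans, SpectralClustering
from sklearn.mixture import GaussianMixture

from .core import TrackedDataset, ValidationError, as_label_vector

__all__ = [
    "CentroidDataset",
    "UnsupportedMethodError",
    "track_centroids",
    "cluster_baseline",
    "propagate_centroid_labels",
    "LINKAGE_METHODS",
    "DBSCAN_EPS_GRID",
    "DBSCAN_MINPTS_GRID",
]

LINKAGE_METHODS = ("average", "centroid", "complete", "median", "single", "ward", "weighted")
DBSCAN_EPS_GRID = tuple(np.arange(0.5, 4.0 + 1e-9, 0.5))
DBSCAN_MINPTS_GRID = tuple(range(1, 9))


class UnsupportedMethodError(ValidationError):
    """Requested clustering method has no available implementation."""


@dataclass
class CentroidDataset:
    """One row per track: its label and the mean feature vector of its members."""

    track_keys: list[int]
    centroids: np.ndarray


def track_centroids(
    dataset: TrackedDataset, labels: Sequence[int]
) -> CentroidDataset:
    """Arithmetic mean of each track's feature vectors, keyed by track label."""
    X = dataset.feature_matrix()
    labels = as_label_vector(labels, len(dataset))
    keys = sorted(int(k) for k in np.unique(labels))
    centroids = np.stack([X[labels == k].mean(axis=0) for k in keys])
    return CentroidDataset(track_keys=keys, centroids=centroids)


def cluster_baseline(
    method: str,
    data: np.ndarray,
    K: int,
    seed: int = 0,
) -> np.ndarray:
    """Run one off-the-shelf clustering algorithm on the rows of ``data``.

    Methods: ``kmeans``, the seven hierarchical linkages (``average``,
    ``centroid``, ``complete``, ``median``, ``single``, ``ward``,
    ``weighted``), ``gmm`` (diagonal covariances, 1000-iteration cap),
    ``spectral``, and ``dbscan`` — which sweeps eps in {0.5, 1.0, ..., 4.0}
    x MinPts in {1, ..., 8} and returns the run whose cluster count is
    closest to K (ties to smaller eps, then smaller MinPts; noise points
    become singleton clusters in the returned labels).  ``finch`` is
    recognised but unsupported without an external implementation.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValidationError("data must be a non-empty 2-D matrix")
    if K < 1:
        raise ValidationError(f"K must be >= 1, got {K}")
    n = data.shape[0]
    method = method.lower().replace("_", "-")
    if method == "finch":
        raise UnsupportedMethodError(
            "no FINCH implementation is available; install one and wrap it, "
            "or choose another method"
        )
    if method == "kmeans":
        K = min(K, n)
        return KMeans(n_clusters=K, random_state=seed, n_init=10).fit_predict(data)
    if method in LINKAGE_METHODS:
        if n == 1:
            return np.zeros(1, dtype=int)
        Z = linkage(data, method=method)
        return fcluster(Z, t=min(K, n), criterion="maxclust") - 1
    if method == "gmm":
        K = min(K, n)
        gm = GaussianMixture(
            n_components=K,
            covariance_type="diag",
            max_iter=1000,
            random_state=seed,
        )
        return gm.fit_predict(data)
    if method == "spectral":
        if K >= n:
            return np.arange(n, dtype=int)
        sc = SpectralClustering(
            n_clusters=K, random_state=seed, assign_labels="kmeans"
        )
        return sc.fit_predict(data)
    if method == "dbscan":
        return _dbscan_sweep(data, K)
    raise ValidationError(f"unknown clustering method {method!r}")


def _dbscan_sweep(data: np.ndarray, K: int) -> np.ndarray:
    best = None  # (|count-K|, eps, minpts, labels)
    for eps in DBSCAN_EPS_GRID:
        for minpts in DBSCAN_MINPTS_GRID:
            labels = DBSCAN(eps=eps, min_samples=minpts).fit_predict(data)
            n_clusters = int(np.unique(labels[labels >= 0]).size)
            key = (abs(n_clusters - K), eps, minpts)
            if best is None or key < best[0]:
                best = (key, labels)
    labels = best[1].copy()
    # noise points are not clusterable; give each its own singleton label
    next_label = labels.max() + 1 if labels.max() >= 0 else 0
    for i in np.flatnonzero(labels < 0):
        labels[i] = next_label
        next_label += 1
    return labels


def propagate_centroid_labels(
    centroid_labels: Sequence[int],
    track_labels: Sequence[int],
    track_keys: Sequence[int] | None = None,
) -> np.ndarray:
    """Give every detection the cluster label of its track's centroid.

    ``centroid_labels`` is ordered like ``track_keys`` (default: sorted
    distinct values of ``track_labels``, matching
    :func:`track_centroids`).
    """
    track_labels = as_label_vector(track_labels)
    if track_keys is None:
        track_keys = sorted(int(k) for k in np.unique(track_labels))
    centroid_labels = np.asarray(centroid_labels)
    if centroid_labels.shape[0] != len(track_keys):
        raise ValidationError(
            f"{len(track_keys)} tracks but {centroid_labels.shape[0]} centroid labels"
        )
    mapping = {int(k): int(c) for k, c in zip(track_keys, centroid_labels)}
    missing = set(int(t) for t in np.unique(track_labels)) - set(mapping)
    if missing:
        raise ValidationError(f"tracks without a centroid label: {sorted(missing)}")
    return np.array([mapping[int(t)] for t in track_labels], dtype=int)
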