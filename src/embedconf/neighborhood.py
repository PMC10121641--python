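"""K-nearest-neighbor indices, label-consistency confidence, and the NPR baseline.

The ground-truth confidence of a sample is the fraction of its K embedding-
space nearest neighbors (Euclidean, self excluded) that share its class
label; a sample is erroneously embedded when fewer than K/2 neighbors agree
(a tie at exactly K/2 counts as correctly embedded).  The neighborhood
preservation ratio (NPR) is the unsupervised baseline: the fraction of a
sample's K-neighbor set in the original space that survives into its
K-neighbor set in the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class NeighborhoodIndex:
    """Per-sample ordered K-nearest-neighbor indices in a named space."""

    space_id: str
    K: int
    neighbors: np.ndarray  # n x K, ascending Euclidean distance, self excluded


@dataclass
class GroundTruthConfidence:
    """Label-consistency confidence scores on the grid {0, 1/K, ..., 1}."""

    scores: np.ndarray
    erroneous: np.ndarray
    K: int


def knn_index(points, K: int, space_id: str = "embedding") -> NeighborhoodIndex:
    """Exact Euclidean K-NN with deterministic lower-index tie-breaking.

    Duplicated points are legitimate neighbors of each other; only a point's
    own index is excluded from its neighborhood.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite values")
    n = points.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be smaller than n={n}")
    d2 = cdist(points, points, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    # stable sort on distances ties at equal distance toward the lower index
    order = np.argsort(d2, axis=1, kind="stable")
    return NeighborhoodIndex(space_id=space_id, K=K, neighbors=order[:, :K])


def ground_truth_confidence(index: NeighborhoodIndex, labels) -> GroundTruthConfidence:
    """Fraction of same-label neighbors per sample, plus the erroneous flag."""
    labels = np.asarray(labels)
    n, K = index.neighbors.shape
    if labels.shape[0] != n:
        raise ValueError(
            f"label length {labels.shape[0]} does not match {n} samples"
        )
    same = labels[index.neighbors] == labels[:, None]
    counts = same.sum(axis=1)
    scores = counts / K
    erroneous = counts < K / 2  # "at least K/2 agreeing" counts as correct
    return GroundTruthConfidence(scores=scores, erroneous=erroneous, K=K)


def npr(index_original: NeighborhoodIndex,
        index_embedding: NeighborhoodIndex) -> np.ndarray:
    """Neighborhood preservation ratio: |N_original ∩ N_embedding| / K per sample."""
    if index_original.K != index_embedding.K:
        raise ValueError(
            f"K mismatch: {index_original.K} vs {index_embedding.K}"
        )
    a = index_original.neighbors
    b = index_embedding.neighbors
    if a.shape != b.shape:
        raise ValueError("neighbor indices cover different sample sets")
    K = index_original.K
    out = np.empty(a.shape[0], dtype=float)
    for i in range(a.shape[0]):
        out[i] = np.intersect1d(a[i], b[i], assume_unique=True).size / K
    return out


def rank_ascending(scores) -> np.ndarray:
    """Stable ascending ordering of scores; ties broken by sample index."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    return np.argsort(scores, kind="stable")


def rank_descending(scores) -> np.ndarray:
    """Stable descending ordering; the reversal of :func:`rank_ascending`."""
    return rank_ascending(scores)[::-1]
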