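"""Confidence-filtered clustering: eliminate, cluster, reassign, evaluate.

The experiment compares three conditions on the same data:

1. ``whole_no_confidence`` — cluster every sample, score against all labels;
2. ``confident_only`` — drop the lowest-confidence fraction (the elimination
   rate), cluster the remainder, score against the kept labels;
3. ``with_confidence_scores`` — reassign each eliminated sample to the
   Euclidean-nearest cluster center from condition 2 and score the full
   labeling against all labels.

Hyperparameters (K for K-means via the elbow of the within-cluster
sum-of-squares curve; epsilon/MinPts for DBSCAN via the sorted average
k-distance knee and MinPts = 2*d + round(n/1000)) are re-selected
independently within each condition, since removing unreliable samples is
precisely what makes those selections easier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN, KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from ._knee import find_knee
from .clustering_metrics import acc_hungarian, ari, nmi
from .neighborhood import rank_ascending

CONDITIONS = ("whole_no_confidence", "confident_only", "with_confidence_scores")


@dataclass
class EliminationPlan:
    """Which samples a given elimination rate removes, and at what threshold."""

    rate: float
    threshold: float
    kept_indices: np.ndarray
    removed_indices: np.ndarray


@dataclass
class ClusterResult:
    """Cluster labels plus the centers used for reassignment.

    For K-means the centers are the fitted centroids; DBSCAN has no native
    centers, so each non-noise cluster's member centroid stands in.  Noise
    points carry label -1 and contribute to no center.
    """

    labels: np.ndarray
    centers: np.ndarray
    center_labels: np.ndarray
    params: Dict


@dataclass
class ClusteringReport:
    """(ARI, NMI, ACC) per experimental condition for one algorithm and rate."""

    algorithm: str
    rate: float
    conditions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    params: Dict[str, Dict] = field(default_factory=dict)


def eliminate_low_confidence(scores, rate: float) -> EliminationPlan:
    """Remove the floor(rate*n) lowest-confidence samples (stable tie-break)."""
    scores = np.asarray(scores, dtype=float)
    if not 0 < rate < 1:
        raise ValueError("elimination rate must lie in (0, 1)")
    n = scores.shape[0]
    n_removed = int(math.floor(rate * n))
    order = rank_ascending(scores)
    removed = np.sort(order[:n_removed])
    kept = np.sort(order[n_removed:])
    threshold = float(scores[order[n_removed - 1]]) if n_removed else float("-inf")
    return EliminationPlan(rate=rate, threshold=threshold,
                           kept_indices=kept, removed_indices=removed)


def _wcss_curve(points, k_values, seed):
    inertias = []
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(points)
        inertias.append(km.inertia_)
    return np.asarray(inertias)


def select_k_elbow(points, k_range: Sequence[int] = range(2, 16),
                   seed: int = 0) -> int:
    """Elbow of the within-cluster sum-of-squares curve; silhouette fallback.

    The knee of the decreasing convex WCSS-vs-K curve picks K.  If the curve
    has no knee (nearly straight), the K maximizing the mean silhouette over
    the same range is returned instead.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    k_values = [k for k in k_range if 2 <= k <= n - 1]
    if not k_values:
        raise ValueError(f"k_range contains no feasible K for n={n}")
    if np.allclose(points, points[0]):
        raise ValueError("all points identical; no cluster structure to select K")
    # anchor the curve at k=1 so a knee at the low end of k_range is visible
    curve_ks = k_values if k_values[0] == 1 else [1] + k_values
    inertias = _wcss_curve(points, curve_ks, seed)
    knee = find_knee(np.asarray(curve_ks, dtype=float), inertias,
                     curve="convex", direction="decreasing")
    if knee is not None and int(round(knee[0])) in k_values:
        return int(round(knee[0]))
    best_k, best_sil = k_values[0], -np.inf
    for k in k_values:
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed) \
            .fit_predict(points)
        sil = silhouette_score(points, labels)
        if sil > best_sil:
            best_k, best_sil = k, sil
    return best_k


def minpts_rule(d: int, n: int) -> int:
    """MinPts = 2*d + round(n/1000), rounding half up."""
    return 2 * d + int(math.floor(n / 1000 + 0.5))


def select_dbscan_params(points, k_for_eps: Optional[int] = None) -> Tuple[float, int]:
    """(epsilon, MinPts) from the k-distance knee and the MinPts rule.

    Epsilon is the value at the point of maximum curvature of the ascending
    sorted curve of each point's average distance to its k nearest neighbors;
    k defaults to MinPts.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    min_pts = minpts_rule(d, n)
    k = min_pts if k_for_eps is None else k_for_eps
    if k >= n:
        raise ValueError(f"k_for_eps={k} must be smaller than n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dists, _ = nn.kneighbors(points)
    avg = dists[:, 1:].mean(axis=1)  # drop the self-distance column
    curve = np.sort(avg)
    knee = find_knee(np.arange(n, dtype=float), curve,
                     curve="convex", direction="increasing")
    if knee is None:
        raise ValueError(
            "no knee found in the k-distance curve; supply epsilon manually"
        )
    return float(knee[1]), min_pts


def cluster_kmeans(points, K: int, seed: int = 0) -> ClusterResult:
    """Seeded K-means; deterministic for a fixed seed."""
    points = np.asarray(points, dtype=float)
    if K > points.shape[0]:
        raise ValueError(f"K={K} exceeds n={points.shape[0]}")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(points)
    return ClusterResult(labels=km.labels_.astype(int),
                         centers=km.cluster_centers_,
                         center_labels=np.arange(K),
                         params={"K": K, "seed": seed})


def cluster_dbscan(points, eps: float, min_pts: int) -> ClusterResult:
    """DBSCAN with member-centroid centers; noise labeled -1."""
    points = np.asarray(points, dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(points)
    cluster_ids = np.unique(labels[labels >= 0])
    centers = np.array([points[labels == c].mean(axis=0) for c in cluster_ids]) \
        if cluster_ids.size else np.empty((0, points.shape[1]))
    return ClusterResult(labels=labels.astype(int), centers=centers,
                         center_labels=cluster_ids,
                         params={"eps": float(eps), "min_pts": int(min_pts)})


def reassign_removed(result: ClusterResult, removed_points) -> np.ndarray:
    """Label each removed point by its Euclidean-nearest cluster center.

    Ties go to the lowest-index center; the kept samples' labels are not
    touched (assembly happens in the caller).
    """
    removed_points = np.atleast_2d(np.asarray(removed_points, dtype=float))
    if result.centers.shape[0] == 0:
        raise ValueError("no cluster centers available (all points noise?)")
    nearest = np.argmin(cdist(removed_points, result.centers), axis=1)
    return result.center_labels[nearest]


def _score(true_labels, pred_labels) -> Dict[str, float]:
    return {
        "ari": ari(true_labels, pred_labels),
        "nmi": nmi(true_labels, pred_labels),
        "acc": acc_hungarian(true_labels, pred_labels),
    }


def _fit_condition(points, algorithm, seed, k_range):
    if algorithm == "kmeans":
        K = select_k_elbow(points, k_range=k_range, seed=seed)
        return cluster_kmeans(points, K, seed=seed)
    if algorithm == "dbscan":
        eps, min_pts = select_dbscan_params(points)
        return cluster_dbscan(points, eps, min_pts)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def run_confidence_clustering(points, scores, true_labels, algorithm: str,
                              rate: float, seed: int = 0,
                              k_range: Sequence[int] = range(2, 16)) -> ClusteringReport:
    """Run the three-condition confidence-filtered clustering experiment.

    DBSCAN noise points keep -1 as their own pseudo-label when scoring
    conditions 1-2, so unclustered samples count against agreement rather
    than silently inflating it.
    """
    points = np.asarray(points, dtype=float)
    scores = np.asarray(scores, dtype=float)
    true_labels = np.asarray(true_labels)
    if not (points.shape[0] == scores.shape[0] == true_labels.shape[0]):
        raise ValueError("points, scores and labels must be aligned")

    report = ClusteringReport(algorithm=algorithm, rate=rate)

    whole = _fit_condition(points, algorithm, seed, k_range)
    report.conditions["whole_no_confidence"] = _score(true_labels, whole.labels)
    report.params["whole_no_confidence"] = whole.params

    plan = eliminate_low_confidence(scores, rate)
    kept = plan.kept_indices
    removed = plan.removed_indices
    confident = _fit_condition(points[kept], algorithm, seed, k_range)
    report.conditions["confident_only"] = _score(true_labels[kept], confident.labels)
    report.params["confident_only"] = dict(confident.params,
                                           threshold=plan.threshold)

    full_labels = np.empty(points.shape[0], dtype=int)
    full_labels[kept] = confident.labels
    full_labels[removed] = reassign_removed(confident, points[removed])
    report.conditions["with_confidence_scores"] = _score(true_labels, full_labels)
    report.params["with_confidence_scores"] = dict(confident.params,
                                                   threshold=plan.threshold)
    return report
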