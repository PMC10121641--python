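"""External clustering-agreement indices: ARI, NMI, Hungarian-matched accuracy.

ARI and NMI delegate to scikit-learn (NMI normalized by the arithmetic mean
of the two partition entropies, the library default).  Clustering accuracy
pads the contingency table square with zero rows/columns and solves the
optimal one-to-one cluster-to-class assignment, so the matched diagonal mass
divided by n is the best achievable labeling accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix


def _check(true_labels, pred_labels):
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape or true_labels.ndim != 1:
        raise ValueError(
            f"label vectors differ in shape: {true_labels.shape} vs "
            f"{pred_labels.shape}"
        )
    if true_labels.size < 2:
        raise ValueError("need at least 2 samples")
    return true_labels, pred_labels


def ari(true_labels, pred_labels) -> float:
    """Adjusted Rand index (pair-counting, chance-corrected; in [-1, 1])."""
    t, p = _check(true_labels, pred_labels)
    return float(adjusted_rand_score(t, p))


def nmi(true_labels, pred_labels) -> float:
    """Normalized mutual information (arithmetic-mean normalization; in [0, 1])."""
    t, p = _check(true_labels, pred_labels)
    return float(normalized_mutual_info_score(t, p, average_method="arithmetic"))


def contingency(true_labels, pred_labels) -> np.ndarray:
    """r x c contingency table between the two partitions."""
    t, p = _check(true_labels, pred_labels)
    return np.asarray(contingency_matrix(t, p))


def acc_hungarian(true_labels, pred_labels) -> float:
    """Clustering accuracy after optimal cluster-to-class matching (in [0, 1])."""
    table = contingency(true_labels, pred_labels)
    size = max(table.shape)
    padded = np.zeros((size, size), dtype=float)
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(padded, maximize=True)
    return float(padded[rows, cols].sum() / table.sum())
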