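"""Registry of 28 distance/similarity measures used as confidence features.

Every measure is implemented vectorized over arbitrary leading axes: the
callables accept arrays of shape ``(..., d)`` and reduce the trailing axis,
so the same code path serves scalar pairs, neighbor blocks ``(K, d)`` and
whole-dataset blocks ``(n, K, d)``.

scRNA-seq expression vectors are sparse, so several measures have terms with
zero denominators.  The convention used throughout: a term whose numerator
and denominator are both zero contributes 0; otherwise the denominator's
magnitude is floored at ``EPS = 1e-10``.  Measures from the Shannon-entropy
family operate on probability vectors and their inputs are first passed
through :func:`to_probability` (epsilon-smoothed, natural log).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

EPS = 1e-10

#: The seven jointly best-performing measures used as the default feature set.
SELECTED_MEASURES: Tuple[str, ...] = (
    "braycurtis",
    "correlation",
    "cosine",
    "dice",
    "kullback_leibler",
    "pearson",
    "wiad",
)


def to_probability(x, epsilon: float = 1e-10, axis: int = -1) -> np.ndarray:
    """Map a non-negative vector to a strictly positive probability vector.

    Negative entries are clipped to 0 first (2-D embedding coordinates may be
    negative).  An all-zero vector maps to the uniform distribution.  After
    normalization every entry is smoothed to at least ``epsilon/(1+n*epsilon)``
    so that logarithms are finite; the output sums to 1 along ``axis``.
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, None)
    total = x.sum(axis=axis, keepdims=True)
    n = x.shape[axis]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, x / np.where(total == 0, 1.0, total), 1.0 / n)
    return (p + epsilon) / (1.0 + n * epsilon)


def _ratio(num, den):
    """Elementwise num/den with the package-wide zero-denominator convention."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    sign = np.where(den < 0, -1.0, 1.0)
    floored = sign * np.maximum(np.abs(den), EPS)
    return np.where((num == 0) & (den == 0), 0.0, num / floored)


# -- similarity cores ---------------------------------------------------------

def _unit(v):
    """Scale each vector to unit norm; zero vectors stay zero."""
    n = np.sqrt(np.sum(v * v, axis=-1, keepdims=True))
    return v / np.where(n == 0, 1.0, n)


def _cosine_similarity(x, y):
    nx = np.sqrt(np.sum(x * x, axis=-1))
    ny = np.sqrt(np.sum(y * y, axis=-1))
    # normalizing first keeps the similarity scale-invariant for tiny norms
    sim = np.sum(_unit(x) * _unit(y), axis=-1)
    # two zero vectors are identical; one zero vector is maximally dissimilar
    return np.where((nx == 0) & (ny == 0), 1.0, sim)


def _pearson_r(x, y):
    xc = x - np.mean(x, axis=-1, keepdims=True)
    yc = y - np.mean(y, axis=-1, keepdims=True)
    nx = np.sqrt(np.sum(xc * xc, axis=-1))
    ny = np.sqrt(np.sum(yc * yc, axis=-1))
    r = np.sum(_unit(xc) * _unit(yc), axis=-1)
    # two constant vectors correlate perfectly; one constant vector: r = 0
    r = np.where((nx == 0) | (ny == 0), 0.0, r)
    r = np.where((nx == 0) & (ny == 0), 1.0, r)
    return np.clip(r, -1.0, 1.0)


# -- the 28 measures ----------------------------------------------------------

def _euclidean(x, y):
    d = x - y
    return np.sqrt(np.sum(d * d, axis=-1))


def _squared_euclidean(x, y):
    d = x - y
    return np.sum(d * d, axis=-1)


def _manhattan(x, y):
    return np.sum(np.abs(x - y), axis=-1)


def _chebyshev(x, y):
    return np.max(np.abs(x - y), axis=-1)


def _canberra(x, y):
    return np.sum(_ratio(np.abs(x - y), np.abs(x) + np.abs(y)), axis=-1)


def _lorentzian(x, y):
    return np.sum(np.log1p(np.abs(x - y)), axis=-1)


def _average_distance(x, y):
    return 0.5 * (_manhattan(x, y) + _chebyshev(x, y))


def _average_euclidean(x, y):
    d = x - y
    return np.sqrt(np.sum(d * d, axis=-1) / x.shape[-1])


def _mean_censored_euclidean(x, y):
    d = x - y
    num = np.sum(d * d, axis=-1)
    nonzero = np.sum((x + y) != 0, axis=-1).astype(float)
    return np.sqrt(_ratio(num, nonzero))


def _chi_squared(x, y):
    d = x - y
    return np.sum(_ratio(d * d, x + y), axis=-1)


def _clark(x, y):
    t = _ratio(x - y, np.abs(x) + np.abs(y))
    return np.sqrt(np.sum(t * t, axis=-1))


def _divergence(x, y):
    d = x - y
    s = x + y
    return 2.0 * np.sum(_ratio(d * d, s * s), axis=-1)


def _braycurtis(x, y):
    return _ratio(np.sum(np.abs(x - y), axis=-1), np.sum(np.abs(x + y), axis=-1))


def _motyka(x, y):
    """Motyka distance, shifted by -1/2 so that d(x, x) = 0.

    The classic form Sum max(x_i, y_i) / Sum (x_i + y_i) equals 1/2 for
    identical vectors; the constant offset is removed so the registry-wide
    identity d(x, x) = 0 holds.  Rankings are unaffected.
    """
    num = np.sum(np.maximum(x, y), axis=-1)
    den = np.sum(x + y, axis=-1)
    val = np.where((num == 0) & (den == 0), 0.5, _ratio(num, den))
    return val - 0.5


def _hassanat(x, y):
    mn = np.minimum(x, y)
    mx = np.maximum(x, y)
    c = np.where(mn < 0, -mn, 0.0)
    return np.sum(1.0 - (1.0 + mn + c) / (1.0 + mx + c), axis=-1)


def _vicis_symmetric(x, y):
    d = x - y
    mn = np.minimum(x, y)
    return np.sum(_ratio(d * d, mn * mn), axis=-1)


def _cosine(x, y):
    return 1.0 - _cosine_similarity(x, y)


def _chord(x, y):
    # sqrt(2 - 2*cos(x, y)), computed as the Euclidean distance between the
    # unit-normalized vectors so that d(x, x) is exactly 0
    d = _unit(x) - _unit(y)
    return np.sqrt(np.sum(d * d, axis=-1))


def _dice(x, y):
    d = x - y
    return _ratio(np.sum(d * d, axis=-1),
                  np.sum(x * x, axis=-1) + np.sum(y * y, axis=-1))


def _jaccard(x, y):
    d = x - y
    den = (np.sum(x * x, axis=-1) + np.sum(y * y, axis=-1)
           - np.sum(x * y, axis=-1))
    return _ratio(np.sum(d * d, axis=-1), den)


def _correlation(x, y):
    return 1.0 - _pearson_r(x, y)


def _squared_pearson(x, y):
    r = _pearson_r(x, y)
    return 1.0 - r * r


def _squared_chord(x, y):
    # |.| before sqrt: embedding coordinates may be negative
    d = np.sqrt(np.abs(x)) - np.sqrt(np.abs(y))
    return np.sum(d * d, axis=-1)


def _wiad(x, y):
    """Whittaker's index of association: half L1 between sum-normalized vectors."""
    xn = _ratio(x, np.sum(x, axis=-1, keepdims=True))
    yn = _ratio(y, np.sum(y, axis=-1, keepdims=True))
    return 0.5 * np.sum(np.abs(xn - yn), axis=-1)


def _kullback_leibler(p, q):
    return np.sum(p * np.log(p / q), axis=-1)


def _jeffreys(p, q):
    return np.sum((p - q) * np.log(p / q), axis=-1)


def _jensen_difference(p, q):
    m = 0.5 * (p + q)
    return np.sum(0.5 * (p * np.log(p) + q * np.log(q)) - m * np.log(m), axis=-1)


@dataclass(frozen=True)
class MeasureSpec:
    """A registered distance measure and its dispatch metadata."""

    id: str
    family: str
    requires_probability: bool
    symmetric: bool
    func: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.requires_probability:
            x = to_probability(x)
            y = to_probability(y)
        return self.func(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


def _spec(id, family, func, requires_probability=False, symmetric=True):
    return MeasureSpec(id, family, requires_probability, symmetric, func)


REGISTRY: Dict[str, MeasureSpec] = {
    s.id: s
    for s in (
        _spec("manhattan", "L1", _manhattan),
        _spec("canberra", "L1", _canberra),
        _spec("lorentzian", "L1", _lorentzian),
        _spec("braycurtis", "L1", _braycurtis),
        _spec("wiad", "L1", _wiad),
        _spec("euclidean", "L2/squared-L2", _euclidean),
        _spec("squared_euclidean", "L2/squared-L2", _squared_euclidean),
        _spec("average_euclidean", "L2/squared-L2", _average_euclidean),
        _spec("mean_censored_euclidean", "L2/squared-L2", _mean_censored_euclidean),
        _spec("chebyshev", "L2/squared-L2", _chebyshev),
        _spec("chi_squared", "L2/squared-L2", _chi_squared),
        _spec("clark", "L2/squared-L2", _clark),
        _spec("divergence", "L2/squared-L2", _divergence),
        _spec("squared_chord", "L2/squared-L2", _squared_chord),
        _spec("cosine", "inner-product/correlation", _cosine),
        _spec("chord", "inner-product/correlation", _chord),
        _spec("correlation", "inner-product/correlation", _correlation),
        # pearson and correlation are the same quantity (1 - r); both ids are
        # registered so the seven-measure feature list keeps seven blocks
        _spec("pearson", "inner-product/correlation", _correlation),
        _spec("squared_pearson", "inner-product/correlation", _squared_pearson),
        _spec("dice", "inner-product/correlation", _dice),
        _spec("jaccard", "inner-product/correlation", _jaccard),
        _spec("kullback_leibler", "Shannon-entropy", _kullback_leibler,
              requires_probability=True, symmetric=False),
        _spec("jeffreys", "Shannon-entropy", _jeffreys, requires_probability=True),
        _spec("jensen_difference", "Shannon-entropy", _jensen_difference,
              requires_probability=True),
        _spec("motyka", "intersection", _motyka),
        _spec("average_distance", "combination", _average_distance),
        _spec("hassanat", "vicissitude", _hassanat),
        _spec("vicis_symmetric", "vicissitude", _vicis_symmetric),
    )
}

assert len(REGISTRY) == 28


def measure_ids() -> Tuple[str, ...]:
    """All registered measure ids, in registry order."""
    return tuple(REGISTRY)


def get_measure(measure_id: str) -> MeasureSpec:
    try:
        return REGISTRY[measure_id]
    except KeyError:
        raise ValueError(
            f"unknown distance measure {measure_id!r}; "
            f"known: {', '.join(REGISTRY)}"
        ) from None


def distance(measure_id: str, x: Sequence[float], y: Sequence[float]) -> float:
    """Distance between two vectors under a registered measure."""
    spec = get_measure(measure_id)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"length mismatch: x has shape {x.shape}, y has shape {y.shape}"
        )
    if x.size < 1:
        raise ValueError("vectors must have length >= 1")
    return float(spec(x, y))


def pairwise_to_neighbors(measure_id: str, x: Sequence[float],
                          neighbors: np.ndarray) -> np.ndarray:
    """Distances from ``x`` to each row of a K x d neighbor matrix, in order."""
    spec = get_measure(measure_id)
    x = np.asarray(x, dtype=float)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    if neighbors.shape[1] != x.shape[0]:
        raise ValueError(
            f"length mismatch: x has {x.shape[0]} entries, "
            f"neighbor rows have {neighbors.shape[1]}"
        )
    return np.asarray(spec(x[None, :], neighbors), dtype=float)
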