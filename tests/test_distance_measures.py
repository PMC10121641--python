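"""Distance-measure registry: formulas, identities, symmetry, oracle parity."""

import math

import numpy as np
import pytest

from embedconf.distance_measures import (REGISTRY, SELECTED_MEASURES,
                                         distance, get_measure, measure_ids,
                                         pairwise_to_neighbors, to_probability)

EPS = 1e-10


# --- independent scalar-loop reference implementations -----------------------
# Written directly from the pinned formulas, one term at a time, as the
# oracle against the vectorized registry.

def _term(num, den):
    if num == 0 and den == 0:
        return 0.0
    sign = -1.0 if den < 0 else 1.0
    return num / (sign * max(abs(den), EPS))


def _probs(x):
    x = [max(v, 0.0) for v in x]
    s = sum(x)
    n = len(x)
    p = [v / s for v in x] if s > 0 else [1.0 / n] * n
    return [(v + EPS) / (1.0 + n * EPS) for v in p]


def _r(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    xc = [v - mx for v in x]
    yc = [v - my for v in y]
    nx = math.sqrt(sum(v * v for v in xc))
    ny = math.sqrt(sum(v * v for v in yc))
    if nx < EPS and ny < EPS:
        return 1.0
    return max(-1.0, min(1.0, sum(a * b for a, b in zip(xc, yc)) / max(nx * ny, EPS)))


def _cos_sim(x, y):
    nx = math.sqrt(sum(v * v for v in x))
    ny = math.sqrt(sum(v * v for v in y))
    if nx == 0 and ny == 0:
        return 1.0
    return sum(a * b for a, b in zip(x, y)) / max(nx * ny, EPS)


def _hassanat_term(a, b):
    mn, mx = min(a, b), max(a, b)
    c = -mn if mn < 0 else 0.0
    return 1.0 - (1.0 + mn + c) / (1.0 + mx + c)


SCALAR_REFERENCE = {
    "euclidean": lambda x, y: math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y))),
    "squared_euclidean": lambda x, y: sum((a - b) ** 2 for a, b in zip(x, y)),
    "manhattan": lambda x, y: sum(abs(a - b) for a, b in zip(x, y)),
    "chebyshev": lambda x, y: max(abs(a - b) for a, b in zip(x, y)),
    "canberra": lambda x, y: sum(_term(abs(a - b), abs(a) + abs(b))
                                 for a, b in zip(x, y)),
    "lorentzian": lambda x, y: sum(math.log(1 + abs(a - b)) for a, b in zip(x, y)),
    "average_distance": lambda x, y: 0.5 * (
        sum(abs(a - b) for a, b in zip(x, y))
        + max(abs(a - b) for a, b in zip(x, y))),
    "average_euclidean": lambda x, y: math.sqrt(
        sum((a - b) ** 2 for a, b in zip(x, y)) / len(x)),
    "mean_censored_euclidean": lambda x, y: math.sqrt(_term(
        sum((a - b) ** 2 for a, b in zip(x, y)),
        float(sum(1 for a, b in zip(x, y) if a + b != 0)))),
    "chi_squared": lambda x, y: sum(_term((a - b) ** 2, a + b)
                                    for a, b in zip(x, y)),
    "clark": lambda x, y: math.sqrt(sum(_term(a - b, abs(a) + abs(b)) ** 2
                                        for a, b in zip(x, y))),
    "divergence": lambda x, y: 2 * sum(_term((a - b) ** 2, (a + b) ** 2)
                                       for a, b in zip(x, y)),
    "braycurtis": lambda x, y: _term(sum(abs(a - b) for a, b in zip(x, y)),
                                     sum(abs(a + b) for a, b in zip(x, y))),
    "motyka": lambda x, y: (0.5 if sum(max(a, b) for a, b in zip(x, y)) == 0
                            and sum(a + b for a, b in zip(x, y)) == 0
                            else _term(sum(max(a, b) for a, b in zip(x, y)),
                                       sum(a + b for a, b in zip(x, y)))) - 0.5,
    "hassanat": lambda x, y: sum(_hassanat_term(a, b) for a, b in zip(x, y)),
    "vicis_symmetric": lambda x, y: sum(_term((a - b) ** 2, min(a, b) ** 2)
                                        for a, b in zip(x, y)),
    "cosine": lambda x, y: 1.0 - _cos_sim(x, y),
    "chord": lambda x, y: math.sqrt(sum(
        (a / max(math.sqrt(sum(v * v for v in x)), EPS)
         - b / max(math.sqrt(sum(v * v for v in y)), EPS)) ** 2
        for a, b in zip(x, y))),
    "dice": lambda x, y: _term(sum((a - b) ** 2 for a, b in zip(x, y)),
                               sum(a * a for a in x) + sum(b * b for b in y)),
    "jaccard": lambda x, y: _term(
        sum((a - b) ** 2 for a, b in zip(x, y)),
        sum(a * a for a in x) + sum(b * b for b in y)
        - sum(a * b for a, b in zip(x, y))),
    "correlation": lambda x, y: 1.0 - _r(x, y),
    "pearson": lambda x, y: 1.0 - _r(x, y),
    "squared_pearson": lambda x, y: 1.0 - _r(x, y) ** 2,
    "squared_chord": lambda x, y: sum(
        (math.sqrt(abs(a)) - math.sqrt(abs(b))) ** 2 for a, b in zip(x, y)),
    "wiad": lambda x, y: 0.5 * sum(
        abs(_term(a, sum(x)) - _term(b, sum(y))) for a, b in zip(x, y)),
    "kullback_leibler": lambda x, y: sum(
        p * math.log(p / q) for p, q in zip(_probs(x), _probs(y))),
    "jeffreys": lambda x, y: sum(
        (p - q) * math.log(p / q) for p, q in zip(_probs(x), _probs(y))),
    "jensen_difference": lambda x, y: sum(
        0.5 * (p * math.log(p) + q * math.log(q))
        - 0.5 * (p + q) * math.log(0.5 * (p + q))
        for p, q in zip(_probs(x), _probs(y))),
}


def test_registry_has_28_measures_with_the_seven_selected():
    assert len(REGISTRY) == 28
    assert set(SELECTED_MEASURES) <= set(measure_ids())
    assert len(SELECTED_MEASURES) == 7


@pytest.mark.parametrize("measure", sorted(REGISTRY))
def test_identity_is_zero(measure):
    rng = np.random.default_rng(42)
    for _ in range(5):
        x = rng.random(15) * 10
        assert abs(distance(measure, x, x)) < 1e-12


@pytest.mark.parametrize("measure", sorted(REGISTRY))
def test_vectorized_matches_scalar_loop(measure):
    """Every registry measure agrees with an independent scalar-loop oracle."""
    rng = np.random.default_rng(7)
    ref = SCALAR_REFERENCE[measure]
    for _ in range(100):
        x = rng.random(12) * 5
        y = rng.random(12) * 5
        if rng.random() < 0.3:  # sparsity typical of scRNA-seq vectors
            x[rng.random(12) < 0.5] = 0.0
            y[rng.random(12) < 0.5] = 0.0
        # rel tolerance matters for vicis_symmetric, whose floored-denominator
        # terms reach 1e12 on sparse vectors
        assert distance(measure, x, y) == pytest.approx(
            ref(list(x), list(y)), rel=1e-9, abs=1e-9)


def test_symmetric_measures_are_symmetric():
    rng = np.random.default_rng(3)
    for spec in REGISTRY.values():
        if not spec.symmetric:
            continue
        for _ in range(100):
            x = rng.random(10) * 4
            y = rng.random(10) * 4
            assert distance(spec.id, x, y) == pytest.approx(
                distance(spec.id, y, x), abs=1e-9)


def test_kullback_leibler_is_asymmetric():
    p = [0.8, 0.1, 0.1]
    q = [0.1, 0.1, 0.8]
    r = [0.5, 0.4, 0.1]
    assert not REGISTRY["kullback_leibler"].symmetric
    assert distance("kullback_leibler", p, r) != pytest.approx(
        distance("kullback_leibler", r, p), abs=1e-6)
    assert distance("kullback_leibler", p, p) == pytest.approx(0, abs=1e-12)


def test_correlation_equals_pearson():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        x = rng.random(8)
        y = rng.random(8)
        assert distance("correlation", x, y) == distance("pearson", x, y)


def test_nonnegativity_on_nonnegative_inputs():
    rng = np.random.default_rng(5)
    correlation_family = {"correlation", "pearson", "squared_pearson"}
    for spec in REGISTRY.values():
        for _ in range(20):
            x = rng.random(10) * 3
            y = rng.random(10) * 3
            d = distance(spec.id, x, y)
            if spec.id in correlation_family:
                assert -1e-12 <= d <= 2 + 1e-12
            else:
                assert d >= -1e-12


@pytest.mark.parametrize("measure,x,y,expected", [
    ("braycurtis", [1, 0], [0, 1], 1.0),
    ("wiad", [1, 1], [2, 0], 0.5),
    ("chebyshev", [0, 3], [4, 0], 4.0),
    ("manhattan", [0, 3], [4, 0], 7.0),
    ("average_distance", [0, 3], [4, 0], 5.5),
])
def test_hand_computed_values(measure, x, y, expected):
    assert distance(measure, x, y) == pytest.approx(expected, abs=1e-12)


def test_cosine_identity_any_nonzero_vector():
    assert distance("cosine", [3.0, 4.0], [3.0, 4.0]) == pytest.approx(0, abs=1e-12)


class TestToProbability:
    def test_simple_normalization(self):
        assert to_probability([2, 2]) == pytest.approx([0.5, 0.5], abs=1e-8)

    def test_all_zero_gives_uniform(self):
        assert to_probability([0, 0, 0]) == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_sums_to_one_and_strictly_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = to_probability(rng.random(20) * rng.choice([0, 1], 20))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p > 0)

    def test_negative_entries_clipped(self):
        p = to_probability([-1.0, 1.0, 1.0])
        assert p[0] == pytest.approx(0.0, abs=1e-9)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestPairwiseToNeighbors:
    def test_euclidean_unit_shift(self):
        x = np.array([1.0, 2.0, 3.0])
        nbrs = np.stack([x, x + np.array([1.0, 0, 0])])
        assert pairwise_to_neighbors("euclidean", x, nbrs) == pytest.approx([0, 1])

    def test_k_rows_in_k_values_out(self):
        rng = np.random.default_rng(1)
        nbrs = rng.random((20, 6))
        out = pairwise_to_neighbors("braycurtis", rng.random(6), nbrs)
        assert out.shape == (20,)

    def test_matches_row_loop(self):
        rng = np.random.default_rng(2)
        x = rng.random(9)
        nbrs = rng.random((8, 9))
        for measure in ("cosine", "kullback_leibler", "canberra"):
            out = pairwise_to_neighbors(measure, x, nbrs)
            looped = [distance(measure, x, row) for row in nbrs]
            assert out == pytest.approx(looped, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_to_neighbors("euclidean", [1, 2, 3], np.ones((4, 2)))


def test_unknown_measure_raises():
    with pytest.raises(ValueError, match="unknown distance measure"):
        get_measure("mahalanobis")
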