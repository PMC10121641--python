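"""Synthetic class-structured scRNA-seq-like data with known embedding errors.

The count generator draws per-gene baseline means log-normally, multiplies
in log-normal class effects (effect size = ``class_separation``), and
samples negative-binomial counts around the class means, giving the
sparsity and overdispersion typical of droplet scRNA-seq.  Errors are
injected into the 2-D embedding by swapping the coordinates of cross-class
pairs: a swapped sample lands inside another class's territory, which
guarantees a label-inconsistent neighborhood while leaving the embedding's
overall geometry untouched.  The generator does not attempt platform
effects or gene-gene correlation structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .io_preprocess import Embedding, ExpressionMatrix, cpm_log_normalize, tsne_embed


@dataclass
class FixtureSpec:
    """Generator parameters for one synthetic dataset."""

    n_cells: int = 1000
    n_genes: int = 200
    n_classes: int = 5
    class_separation: float = 1.0
    overdispersion: float = 0.5
    error_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_fraction < 0.5:
            raise ValueError("error_fraction must lie in [0, 0.5)")


@dataclass
class Fixture:
    """A full synthetic dataset: counts, labels, embedding, true error flags."""

    counts: ExpressionMatrix
    labels: np.ndarray
    embedding: Embedding
    true_error_flags: np.ndarray
    provenance: FixtureSpec


def _class_sizes(n: int, c: int) -> np.ndarray:
    sizes = np.full(c, n // c)
    sizes[: n % c] += 1
    return sizes


def generate_counts(spec: FixtureSpec, min_class_size: int = 21
                    ) -> Tuple[ExpressionMatrix, np.ndarray]:
    """Overdispersed, sparse class-structured counts; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec.n_cells, spec.n_classes)
    if sizes.min() < min_class_size:
        raise ValueError(
            f"smallest class has {sizes.min()} cells; need >= {min_class_size} "
            "for well-defined K-neighborhoods"
        )
    labels = np.repeat(np.arange(spec.n_classes), sizes)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    class_effect = np.exp(spec.class_separation
                          * rng.standard_normal((spec.n_classes, spec.n_genes)))
    mu = base[None, :] * class_effect  # class x gene mean expression
    theta = spec.overdispersion
    cell_mu = mu[labels]
    counts = rng.negative_binomial(theta, theta / (theta + cell_mu))
    matrix = ExpressionMatrix(
        counts.astype(float),
        cell_ids=[f"cell{i}" for i in range(spec.n_cells)],
        gene_ids=[f"gene{j}" for j in range(spec.n_genes)],
    )
    return matrix, labels


def embed_with_errors(counts: ExpressionMatrix, labels, error_fraction: float,
                      seed: int = 0, perplexity: float = 30.0
                      ) -> Tuple[Embedding, np.ndarray]:
    """t-SNE embedding with floor(error_fraction*n) coordinate-swap errors.

    Swapped partners always come from different classes.  An odd error count
    is completed by copying (not swapping) one extra sample's coordinates
    onto a cross-class location, so the flagged count is exact.
    """
    labels = np.asarray(labels)
    n = counts.n_cells
    if not 0 <= error_fraction < 0.5:
        raise ValueError("error_fraction must lie in [0, 0.5)")
    normalized = cpm_log_normalize(counts)
    emb = tsne_embed(normalized, perplexity=perplexity, seed=seed)
    coords = emb.coords.copy()
    flags = np.zeros(n, dtype=bool)
    m = int(math.floor(error_fraction * n))
    if m:
        rng = np.random.default_rng(seed)
        pool = list(rng.permutation(n))
        pairs = []
        while len(pairs) * 2 + 1 < m:
            if len(pool) < 2:
                raise ValueError("not enough cross-class pairs to inject errors")
            a = pool.pop()
            partner = next((j for j in pool if labels[j] != labels[a]), None)
            if partner is None:
                raise ValueError("not enough cross-class pairs to inject errors")
            pool.remove(partner)
            pairs.append((a, partner))
        for a, b in pairs:
            coords[[a, b]] = coords[[b, a]]
            flags[a] = flags[b] = True
        if m % 2:  # copy one more sample onto a cross-class position
            a = next(i for i in pool if not flags[i])
            donor = next(j for j in range(n)
                         if labels[j] != labels[a] and not flags[j])
            coords[a] = coords[donor] + rng.normal(scale=1e-3, size=2)
            flags[a] = True
    return Embedding(coords, list(emb.cell_ids)), flags


def default_regression_fixture(seed: int = 0) -> Fixture:
    """The pinned fixture for confidence-model evaluation.

    1000 cells, 200 genes, 5 balanced classes, 10% injected embedding errors.
    """
    spec = FixtureSpec(n_cells=1000, n_genes=200, n_classes=5,
                       error_fraction=0.1, seed=seed)
    counts, labels = generate_counts(spec)
    embedding, flags = embed_with_errors(counts, labels, spec.error_fraction,
                                         seed=seed)
    return Fixture(counts=counts, labels=labels, embedding=embedding,
                   true_error_flags=flags, provenance=spec)


def clustering_noise_fixture(n: int = 600, d: int = 10, n_classes: int = 4,
                             noise_fraction: float = 0.2,
                             separation: float = 4.0, seed: int = 0
                             ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian class blobs with confidence-correlated positional noise.

    A ``noise_fraction`` of points is corrupted in the two ways badly placed
    samples appear in real embeddings: half are displaced into the
    inter-cluster transition region between the first two classes (60-100%
    of the way toward that pair's midpoint), half are flung away from all
    clusters by a diffuse isotropic offset.  Confidence scores are
    constructed to correlate with the corruption: corrupted points draw
    U(0.05, 0.45), clean points U(0.55, 1.0).

    Returns ``(points, labels, scores, noise_flags)``.
    """
    rng = np.random.default_rng(seed)
    sizes = _class_sizes(n, n_classes)
    labels = np.repeat(np.arange(n_classes), sizes)
    centers = separation * rng.standard_normal((n_classes, d))
    points = centers[labels] + rng.standard_normal((n, d))
    n_noise = int(math.floor(noise_fraction * n))
    noisy = rng.choice(n, size=n_noise, replace=False)
    flags = np.zeros(n, dtype=bool)
    flags[noisy] = True
    transition = 0.5 * (centers[0] + centers[min(1, n_classes - 1)])
    scatter_scale = 0.6 * separation * math.sqrt(2.0)
    for j, i in enumerate(noisy):
        if j % 2 == 0:  # stranded between clusters
            frac = rng.uniform(0.6, 1.0)
            points[i] = points[i] + frac * (transition - centers[labels[i]])
        else:  # flung away from every cluster
            points[i] = points[i] + scatter_scale * rng.standard_normal(d)
    scores = rng.uniform(0.55, 1.0, size=n)
    scores[flags] = rng.uniform(0.05, 0.45, size=n_noise)
    return points, labels, scores, flags
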