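"""Neighborhood distance features for the confidence regressor.

For every sample the K nearest neighbors are found once, by Euclidean
distance in the 2-D embedding (the space whose quality is being assessed).
Each distance measure is then evaluated from the sample to those same K
neighbors in both coordinate systems: the embedding itself and the original
(normalized expression) space.  A correctly embedded sample sits among
expression-similar cells, so its original-space block stays small; a
mis-embedded sample's embedding neighbors are expression-distant, which is
exactly the signal the regressor learns.  Measures never re-rank the
neighborhood — the Euclidean sort fixes it.

Column layout is (measure, space, rank) with space ordered
original-then-embedding and ranks 1..K, e.g. ``cosine/original/1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .distance_measures import SELECTED_MEASURES, get_measure
from .io_preprocess import Embedding, ExpressionMatrix
from .neighborhood import knn_index

_SPACES = ("original", "embedding")


@dataclass
class FeatureMatrix:
    """An n x (|measures| * 2 * K) feature matrix with a stable column layout."""

    values: np.ndarray
    layout: List[str]
    measures: Tuple[str, ...]
    K: int

    def __post_init__(self):
        if self.values.shape[1] != len(self.layout):
            raise ValueError("layout length does not match column count")

    def rows(self, indices) -> "FeatureMatrix":
        """A row-subset view with the same column layout."""
        return FeatureMatrix(values=self.values[np.asarray(indices)],
                             layout=list(self.layout),
                             measures=self.measures, K=self.K)

    def require_same_layout(self, other: "FeatureMatrix") -> None:
        if self.layout != other.layout:
            for mine, theirs in zip(self.layout, other.layout):
                if mine != theirs:
                    raise ValueError(
                        f"feature layout mismatch at column {mine!r} vs {theirs!r}"
                    )
            raise ValueError(
                f"feature layout mismatch: {len(self.layout)} vs "
                f"{len(other.layout)} columns"
            )


def feature_layout(measures: Sequence[str], K: int) -> List[str]:
    """Ordered column descriptors ``measure/space/rank`` (ranks are 1-based)."""
    return [
        f"{m}/{space}/{rank}"
        for m in measures
        for space in _SPACES
        for rank in range(1, K + 1)
    ]


def extract_features(data_original, embedding,
                     measures: Sequence[str] = SELECTED_MEASURES,
                     K: int = 20) -> FeatureMatrix:
    """Build the regressor's feature matrix from both spaces' neighbor distances.

    ``data_original`` is the normalized cells x genes matrix (or any n x d
    array); ``embedding`` the aligned 2-D embedding.  Entropy-family measures
    receive inputs through the probability transform, which also clips the
    embedding's negative coordinates.
    """
    X = data_original.values if isinstance(data_original, ExpressionMatrix) \
        else np.asarray(data_original, dtype=float)
    E = embedding.coords if isinstance(embedding, Embedding) \
        else np.asarray(embedding, dtype=float)
    if X.shape[0] != E.shape[0]:
        raise ValueError(
            f"sample mismatch: {X.shape[0]} expression rows vs "
            f"{E.shape[0]} embedded points"
        )
    specs = [get_measure(m) for m in measures]  # fail fast on unknown ids
    nbrs = knn_index(E, K, space_id="embedding").neighbors

    blocks = []
    for spec in specs:
        for coords in (X, E):
            # (n, 1, d) against (n, K, d) -> (n, K) distances in rank order
            block = spec(coords[:, None, :], coords[nbrs])
            blocks.append(np.asarray(block, dtype=float))
    values = np.concatenate(blocks, axis=1)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values produced")
    return FeatureMatrix(values=values,
                         layout=feature_layout(measures, K),
                         measures=tuple(measures), K=K)


def write_features(fm: FeatureMatrix, path, header_comment=None) -> None:
    """Write the feature matrix as CSV with the layout as header."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(",".join(fm.layout) + "\n")
        np.savetxt(fh, fm.values, delimiter=",")


def read_features(path) -> FeatureMatrix:
    """Read a feature CSV written by :func:`write_features`."""
    import pandas as pd

    frame = pd.read_csv(path, comment="#")
    layout = list(frame.columns)
    measures = []
    K = 0
    for col in layout:
        measure, _, rank = col.split("/")
        if measure not in measures:
            measures.append(measure)
        K = max(K, int(rank))
    fm = FeatureMatrix(values=frame.to_numpy(dtype=float), layout=layout,
                       measures=tuple(measures), K=K)
    if layout != feature_layout(fm.measures, K):
        raise ValueError(f"{path} does not hold a canonical feature layout")
    return fm
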