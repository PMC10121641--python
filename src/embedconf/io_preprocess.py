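"""Reading/writing expression matrices, CPM-log normalization, seeded PCA/t-SNE.

The canonical in-memory layout is cells x genes.  Dense CSV/TSV files carry
gene ids in the header row and cell ids in the first column; MatrixMarket
files need sidecar text files with the row (cell) and column (gene) ids.
Normalization is counts-per-million followed by log2(x + 1), the standard
preprocessing for the droplet/plate scRNA-seq datasets this package targets;
no gene filtering or batch correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """A cells x genes numeric matrix with aligned cell and gene ids."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D")
        n, g = self.values.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cell ids / {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        if not self.normalized and np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at cell {self.cell_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """A 2-D embedding of cells, aligned with its source matrix."""

    coords: np.ndarray
    cell_ids: list

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding must have exactly 2 columns")
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("embedding rows and cell ids differ in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite coordinates")


@dataclass
class SplitSpec:
    """A reproducible train/test partition of sample indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float
    seed: int


_SEPARATORS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "mtx"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_expression(path, format: Optional[str] = None, *,
                    genes_as_rows: bool = False,
                    cell_ids_path=None, gene_ids_path=None,
                    normalized: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from dense CSV/TSV or sparse MatrixMarket.

    Dense files: header row = gene ids, first column = cell ids.  MTX files
    need sidecar id files (one id per line); defaults are ``<stem>_rows.txt``
    and ``<stem>_cols.txt`` next to the matrix.  Set ``genes_as_rows`` when
    the file ships in genes x cells orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in _SEPARATORS:
        try:
            frame = pd.read_csv(path, sep=_SEPARATORS[fmt], index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc
        values = frame.to_numpy(dtype=float)
        row_ids = [str(i) for i in frame.index]
        col_ids = [str(c) for c in frame.columns]
    elif fmt == "mtx":
        matrix = scipy.io.mmread(path)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        values = np.asarray(matrix, dtype=float)
        rows_file = Path(cell_ids_path) if cell_ids_path else path.with_name(path.stem + "_rows.txt")
        cols_file = Path(gene_ids_path) if gene_ids_path else path.with_name(path.stem + "_cols.txt")
        for f in (rows_file, cols_file):
            if not f.exists():
                raise FileNotFoundError(f"missing MTX id sidecar file {f}")
        row_ids = rows_file.read_text().split()
        col_ids = cols_file.read_text().split()
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if genes_as_rows:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids, normalized=normalized)


def write_expression(m: ExpressionMatrix, path, format: Optional[str] = None) -> None:
    """Write a matrix as dense CSV/TSV or MatrixMarket with id sidecars."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in _SEPARATORS:
        frame = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids)
        frame.to_csv(path, sep=_SEPARATORS[fmt])
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        path.with_name(path.stem + "_rows.txt").write_text("\n".join(m.cell_ids) + "\n")
        path.with_name(path.stem + "_cols.txt").write_text("\n".join(m.gene_ids) + "\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_labels(path) -> pd.Series:
    """Read a per-cell label CSV (columns: cell_id,label) to a Series."""
    frame = pd.read_csv(path, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"label file {path} needs cell_id,label columns")
    return pd.Series(frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0], name="label")


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"cell_id": labels.index, "label": labels.to_numpy()}).to_csv(path, index=False)


def read_embedding(path) -> Embedding:
    """Read a 2-D embedding TSV (columns: cell_id, x, y)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    if frame.shape[1] < 3:
        raise ValueError(f"embedding file {path} needs cell_id,x,y columns")
    return Embedding(frame.iloc[:, 1:3].to_numpy(dtype=float),
                     [str(c) for c in frame.iloc[:, 0]])


def write_embedding(emb: Embedding, path, header_comment: Optional[str] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("cell_id\tx\ty\n")
        for cid, (x, y) in zip(emb.cell_ids, emb.coords):
            fh.write(f"{cid}\t{float(x)!r}\t{float(y)!r}\n")


def cpm_log_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million scaling followed by log2(x + 1), per cell.

    Each cell's counts are scaled to sum to 1e6, then log2(x + 1) is applied
    elementwise.  Cells with zero total count cannot be scaled and raise an
    error naming them.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    totals = m.values.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        offenders = [m.cell_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"cells with zero total count: {offenders}")
    cpm = m.values / totals[:, None] * 1e6
    return ExpressionMatrix(np.log2(cpm + 1.0), list(m.cell_ids), list(m.gene_ids),
                            normalized=True)


def _as_array(m) -> np.ndarray:
    if isinstance(m, ExpressionMatrix):
        return m.values
    if isinstance(m, Embedding):
        return m.coords
    return np.asarray(m, dtype=float)


def pca_reduce(m, n_components: int = 30, seed: int = 0,
               return_explained_variance: bool = False):
    """Project to the top principal components (scores, variance-ordered)."""
    X = _as_array(m)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)={min(X.shape)}"
        )
    model = PCA(n_components=n_components, random_state=seed)
    scores = model.fit_transform(X)
    if return_explained_variance:
        return scores, model.explained_variance_
    return scores


def tsne_embed(m, perplexity: float = 30.0, n_components: int = 2,
               seed: int = 0) -> Embedding:
    """Seeded t-SNE embedding (delegated to scikit-learn's implementation).

    All parameters other than perplexity, the number of components and the
    seed stay at the delegate's defaults.
    """
    X = _as_array(m)
    n = X.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity={perplexity} must be < n_samples={n}")
    coords = TSNE(n_components=n_components, perplexity=perplexity,
                  random_state=seed, init="pca").fit_transform(X)
    if isinstance(m, ExpressionMatrix):
        cell_ids = list(m.cell_ids)
    else:
        cell_ids = [str(i) for i in range(n)]
    return Embedding(coords, cell_ids)


def train_test_split(n: int, ratio: float = 0.2, seed: int = 0) -> SplitSpec:
    """Disjoint, exhaustive, seed-reproducible split with |test| = round(ratio*n)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_test = int(math.floor(n * ratio + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitSpec(train_indices=np.sort(perm[n_test:]),
                     test_indices=np.sort(perm[:n_test]),
                     ratio=ratio, seed=seed)
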