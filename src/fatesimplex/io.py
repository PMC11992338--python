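"""Data model, validation and readers/writers for external formats.

The on-disk formats are the plain-text conventions of the single-cell world:

* count matrices as MatrixMarket ``.mtx`` with sibling ``features.tsv`` /
  ``barcodes.tsv`` (CellRanger layout: features on rows, cells on columns,
  1-based indices), or as a dense CSV with feature ids in the first column
  and barcodes in the header row;
* cell annotations as a two-column TSV/CSV (barcode, cluster label);
* cell-cell transition graphs as a square ``.mtx`` whose row/column order
  follows the barcode order of the paired count matrix.

All text I/O is UTF-8.  Cluster labels are opaque strings compared exactly;
no case or whitespace normalization is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "ValidationError",
    "FormatError",
    "DegenerateDataWarning",
    "ExpressionMatrix",
    "CellAnnotation",
    "TransitionGraph",
    "SimplexSpec",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_transition_graph",
    "write_transition_graph",
    "align",
]


class ValidationError(ValueError):
    """Raised when an in-memory object violates its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk file cannot be interpreted."""


class DegenerateDataWarning(UserWarning):
    """Emitted when a degenerate input triggers a documented fallback rule."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


def _check_values(values, what: str) -> None:
    data = values.data if sp.issparse(values) else np.asarray(values)
    if data.size and not np.all(np.isfinite(data)):
        raise ValidationError(f"{what} contains NaN or Inf entries")
    if data.size and data.min() < 0:
        raise ValidationError(f"{what} contains negative entries")


@dataclass
class ExpressionMatrix:
    """A feature-by-cell count (or normalized expression) matrix.

    Parameters
    ----------
    values
        Non-negative matrix of shape (G features, C cells); dense ndarray or
        scipy sparse.  Sparse inputs are stored as CSR.
    feature_ids, barcodes
        Unique identifiers for the G rows and C columns.
    modality
        ``"rna"`` or ``"atac"``; both run through the same pipeline.
    """

    values: Union[np.ndarray, sp.spmatrix]
    feature_ids: list[str]
    barcodes: list[str]
    modality: str = "rna"

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float)
        if self.modality not in ("rna", "atac"):
            raise ValidationError(f"modality must be 'rna' or 'atac', got {self.modality!r}")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        g, c = self.values.shape
        if len(self.feature_ids) != g:
            raise ValidationError(f"{len(self.feature_ids)} feature ids for {g} rows")
        if len(self.barcodes) != c:
            raise ValidationError(f"{len(self.barcodes)} barcodes for {c} columns")
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.barcodes, "barcode")
        _check_values(self.values, "expression matrix")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def subset_cells(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        vals = self.values[:, idx]
        return ExpressionMatrix(vals, list(self.feature_ids),
                                [self.barcodes[i] for i in idx], self.modality)

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise ValidationError(f"features not in matrix: {missing[:5]}")
        idx = np.asarray([pos[f] for f in ids], dtype=int)
        return ExpressionMatrix(self.values[idx, :], list(ids),
                                list(self.barcodes), self.modality)


@dataclass
class CellAnnotation:
    """Barcode -> cluster-label assignment; one row per barcode."""

    barcodes: list[str]
    clusters: list[str]

    def __post_init__(self) -> None:
        self.barcodes = [str(b) for b in self.barcodes]
        self.clusters = [str(c) for c in self.clusters]
        if len(self.barcodes) != len(self.clusters):
            raise ValidationError("barcodes and clusters differ in length")
        if not self.barcodes:
            raise ValidationError("annotation is empty")
        _check_unique(self.barcodes, "barcode")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def labels(self) -> list[str]:
        """Distinct cluster labels, sorted."""
        return sorted(set(self.clusters))

    def cluster_of(self) -> dict[str, str]:
        return dict(zip(self.barcodes, self.clusters))

    def indices_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.clusters, dtype=object) == label)

    def subset(self, barcodes: Sequence[str]) -> "CellAnnotation":
        lookup = self.cluster_of()
        missing = [b for b in barcodes if b not in lookup]
        if missing:
            raise ValidationError(f"barcodes not annotated: {missing[:5]}")
        return CellAnnotation(list(barcodes), [lookup[b] for b in barcodes])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"barcode": self.barcodes, "cluster": self.clusters})


@dataclass
class TransitionGraph:
    """Cell-cell transition weights; rows are source cells, columns targets."""

    weights: sp.spmatrix
    barcodes: list[str]

    def __post_init__(self) -> None:
        if not sp.issparse(self.weights):
            self.weights = sp.csr_matrix(np.asarray(self.weights, dtype=float))
        else:
            self.weights = sp.csr_matrix(self.weights)
        self.barcodes = [str(b) for b in self.barcodes]
        n, m = self.weights.shape
        if n != m:
            raise ValidationError(f"transition graph must be square, got {n}x{m}")
        if len(self.barcodes) != n:
            raise ValidationError(f"{len(self.barcodes)} barcodes for a {n}x{n} graph")
        _check_unique(self.barcodes, "barcode")
        _check_values(self.weights, "transition graph")

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    def subset(self, indices: Sequence[int]) -> "TransitionGraph":
        idx = np.asarray(indices, dtype=int)
        w = self.weights[idx, :][:, idx]
        return TransitionGraph(w, [self.barcodes[i] for i in idx])


@dataclass
class SimplexSpec:
    """The chosen terminal fates anchoring the simplex vertices (2-4 labels)."""

    terminal_labels: list[str]
    vertex_colors: Optional[list[str]] = field(default=None)

    def __post_init__(self) -> None:
        self.terminal_labels = [str(t) for t in self.terminal_labels]
        n = len(self.terminal_labels)
        if not 2 <= n <= 4:
            raise ValidationError(
                f"a simplex needs 2-4 terminal fates, got {n}")
        if len(set(self.terminal_labels)) != n:
            raise ValidationError("terminal labels must be distinct")
        if self.vertex_colors is not None and len(self.vertex_colors) != n:
            raise ValidationError("vertex_colors length must equal the number of terminals")

    @property
    def n_vertices(self) -> int:
        return len(self.terminal_labels)

    def validate_against(self, annotation: CellAnnotation) -> None:
        present = set(annotation.clusters)
        missing = [t for t in self.terminal_labels if t not in present]
        if missing:
            raise ValidationError(f"terminal labels absent from annotation: {missing}")


# ---------------------------------------------------------------------------
# readers / writers


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def _mtx_siblings(path: Path) -> tuple[Path, Path, Path]:
    if path.is_dir():
        return path / "matrix.mtx", path / "features.tsv", path / "barcodes.tsv"
    return path, path.parent / "features.tsv", path.parent / "barcodes.tsv"


def read_matrix(path: PathLike, format: Optional[str] = None,
                modality: str = "rna") -> ExpressionMatrix:
    """Read a feature-by-cell matrix from ``.mtx`` (+ sibling TSVs) or CSV.

    ``format`` is inferred from the path when omitted: a directory or a
    ``.mtx`` file selects MatrixMarket, a ``.csv`` file the dense layout.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.is_dir() or path.suffix.lower() == ".mtx" else "csv"
    if format == "mtx":
        mtx, feat, barc = _mtx_siblings(path)
        for p in (mtx, feat, barc):
            if not p.exists():
                raise FormatError(f"missing MatrixMarket component: {p}")
        values = sp.csr_matrix(scipy.io.mmread(mtx))
        features = pd.read_csv(feat, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()
        barcodes = pd.read_csv(barc, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()
        if values.shape != (len(features), len(barcodes)):
            raise FormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(features)} features x {len(barcodes)} barcodes")
        return ExpressionMatrix(values, features, barcodes, modality)
    if format == "csv":
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(df.to_numpy(dtype=float),
                                [str(i) for i in df.index],
                                [str(c) for c in df.columns], modality)
    raise FormatError(f"unknown matrix format: {format!r}")


def write_matrix(matrix: ExpressionMatrix, path: PathLike,
                 format: Optional[str] = None) -> Path:
    """Write a matrix as MatrixMarket (into a directory) or dense CSV."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "mtx"
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        vals = matrix.values if sp.issparse(matrix.values) else sp.coo_matrix(matrix.values)
        scipy.io.mmwrite(path / "matrix.mtx", vals, precision=17)
        (path / "features.tsv").write_text(
            "".join(f + "\n" for f in matrix.feature_ids), encoding="utf-8")
        (path / "barcodes.tsv").write_text(
            "".join(b + "\n" for b in matrix.barcodes), encoding="utf-8")
        return path / "matrix.mtx"
    if format == "csv":
        df = pd.DataFrame(matrix.to_dense(), index=matrix.feature_ids,
                          columns=matrix.barcodes)
        df.to_csv(path)
        return path
    raise FormatError(f"unknown matrix format: {format!r}")


_HEADER_TOKENS = {"barcode", "barcodes", "cell", "cell_id", "cellid"}


def read_annotation(path: PathLike) -> CellAnnotation:
    """Read a two-column (barcode, cluster) TSV/CSV; an optional header row
    whose first field looks like ``barcode``/``cell`` is skipped."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=_infer_sep(path), header=None, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"annotation file is empty: {path}") from None
    if df.empty:
        raise FormatError(f"annotation file is empty: {path}")
    if df.shape[1] < 2:
        raise FormatError(f"annotation needs two columns (barcode, cluster): {path}")
    if str(df.iloc[0, 0]).strip().lower() in _HEADER_TOKENS:
        df = df.iloc[1:]
    if df.empty:
        raise FormatError(f"annotation file has a header but no rows: {path}")
    return CellAnnotation(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist())


def write_annotation(annotation: CellAnnotation, path: PathLike) -> Path:
    path = Path(path)
    annotation.to_frame().to_csv(path, sep=_infer_sep(path), header=False,
                                 index=False)
    return path


def read_transition_graph(path: PathLike, barcodes: Sequence[str]) -> TransitionGraph:
    """Read a square transition-weight ``.mtx`` aligned to ``barcodes``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    w = sp.csr_matrix(scipy.io.mmread(path))
    n, m = w.shape
    if n != m:
        raise FormatError(f"transition graph must be square, got {n}x{m}")
    if n != len(barcodes):
        raise FormatError(
            f"transition graph is {n}x{n} but {len(barcodes)} barcodes were given")
    return TransitionGraph(w, list(barcodes))


def write_transition_graph(graph: TransitionGraph, path: PathLike) -> Path:
    path = Path(path)
    scipy.io.mmwrite(path, sp.coo_matrix(graph.weights), precision=17)
    return path


def align(matrix: ExpressionMatrix, annotation: CellAnnotation,
          graph: Optional[TransitionGraph] = None
          ) -> tuple[ExpressionMatrix, CellAnnotation, Optional[TransitionGraph]]:
    """Restrict all objects to the barcode intersection, in matrix order.

    Upstream velocity tools routinely filter cells, so the three inputs are
    intersected rather than required to match exactly; the number of cells
    dropped from each side is logged.
    """
    common = set(matrix.barcodes) & set(annotation.barcodes)
    if graph is not None:
        common &= set(graph.barcodes)
    if not common:
        raise ValidationError("no barcodes shared between inputs")
    order = [b for b in matrix.barcodes if b in common]

    for name, have in (("matrix", matrix.barcodes),
                       ("annotation", annotation.barcodes),
                       ("graph", graph.barcodes if graph is not None else None)):
        if have is not None and len(have) != len(order):
            logger.warning("align: dropping %d cells from %s",
                           len(have) - len(order), name)

    mpos = {b: i for i, b in enumerate(matrix.barcodes)}
    out_matrix = matrix.subset_cells([mpos[b] for b in order])
    out_annot = annotation.subset(order)
    out_graph = None
    if graph is not None:
        gpos = {b: i for i, b in enumerate(graph.barcodes)}
        out_graph = graph.subset([gpos[b] for b in order])
    return out_matrix, out_annot, out_graph
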