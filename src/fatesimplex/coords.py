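"""Barycentric simplex coordinates for cell-fate commitment.

The chain that places each cell inside the simplex, with C cells, N chosen
terminal fates (2 <= N <= 4) and a shared feature subspace of size G':

1. centroids      V[i, n]  = mean over terminal-n cells of feature i
2. distances      D[c, n]  = || E[:, c] - V[:, n] ||_2
3. row unit-sum   D[c, n] <- D[c, n] / sum_s D[c, s]
4. kernel         S[c, n]  = exp(-D[c, n] / sigma)          (sigma = 0.08)
5. range scaling  S[c, n] <- (S[c, n] - min_c S) / (max_c S - min_c S)
                  taken column-wise
6. L1 rows        B[c, n]  = S[c, n] / sum_s S[c, s]

B is row-stochastic: entry (c, n) is the cell's affinity for fate n, and the
row is the barycentric coordinate plotted inside the simplex.  The kernel
exponent is first-power in the row-normalized distance; the bandwidth sigma
is a single scalar, well-posed because step 3 puts every cell's distances on
a fixed unit-sum scale.

Degenerate cases keep the pipeline total, loudly: a constant similarity
column range-scales to 0.5, and a cell scoring the column minimum for every
vertex gets the uniform coordinate 1/N; both emit warnings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (CellAnnotation, DegenerateDataWarning, ExpressionMatrix,
                 SimplexSpec, TransitionGraph, ValidationError, PathLike, align)
from .features import (CellEmbedding, MarkerTable, normalize_counts,
                       pca_embed, wilcoxon_markers)

__all__ = [
    "CentroidMatrix",
    "DistanceMatrix",
    "SimilarityMatrix",
    "BarycentricCoordinates",
    "SimplexResult",
    "DEFAULT_SIGMA",
    "simplex_vertices",
    "compute_centroids",
    "compute_distances",
    "row_normalize_distances",
    "gaussian_similarity",
    "range_scale",
    "l1_normalize",
    "barycentric_to_cartesian",
    "compute_simplex",
]

DEFAULT_SIGMA = 0.08

MatrixLike = Union[ExpressionMatrix, CellEmbedding]


@dataclass
class CentroidMatrix:
    """Terminal-fate centroids: column n is the mean of cluster-n cells."""

    values: np.ndarray  # features x N
    terminal_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.terminal_labels):
            raise ValidationError("one centroid column per terminal label required")


@dataclass
class DistanceMatrix:
    """Cell-to-centroid Euclidean distances (C x N, non-negative)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("distances contain NaN or Inf")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("distances must be non-negative")


@dataclass
class SimilarityMatrix:
    """Kernel similarities in (0, 1] (C x N); range-scaled variants in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("similarities contain NaN or Inf")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("similarities must lie in [0, 1]")


@dataclass
class BarycentricCoordinates:
    """Row-stochastic C x N simplex coordinates; row c sums to 1."""

    values: np.ndarray
    terminal_labels: list[str]
    barcodes: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.terminal_labels):
            raise ValidationError("one coordinate column per terminal label required")
        if self.barcodes is not None and len(self.barcodes) != self.values.shape[0]:
            raise ValidationError("one barcode per coordinate row required")
        if self.values.size:
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ValidationError("barycentric entries must lie in [0, 1]")
            rows = self.values.sum(axis=1)
            if np.abs(rows - 1.0).max() > 1e-9:
                raise ValidationError("barycentric rows must sum to 1")

    @property
    def n_vertices(self) -> int:
        return len(self.terminal_labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.terminal_labels)
        if self.barcodes is not None:
            df.insert(0, "barcode", self.barcodes)
        return df

    def to_tsv(self, path: PathLike, cartesian: bool = True) -> Path:
        df = self.to_frame()
        if cartesian:
            xyz = barycentric_to_cartesian(self)
            for j, name in enumerate(("x", "y", "z")[: xyz.shape[1]]):
                df[name] = xyz[:, j]
        path = Path(path)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        return path


def _dense(matrix: MatrixLike) -> np.ndarray:
    vals = matrix.values
    if sp.issparse(vals):
        return np.asarray(vals.todense(), dtype=float)
    return np.asarray(vals, dtype=float)


def compute_centroids(matrix: MatrixLike, annotation: CellAnnotation,
                      spec: SimplexSpec) -> CentroidMatrix:
    """Mean feature vector of each terminal cluster (the simplex vertices)."""
    if list(matrix.barcodes) != list(annotation.barcodes):
        raise ValidationError("matrix and annotation are not aligned; call align() first")
    x = _dense(matrix)
    cols = []
    for t in spec.terminal_labels:
        idx = annotation.indices_of(t)
        if idx.size == 0:
            raise ValidationError(f"terminal cluster {t!r} has no cells")
        # average in barcode-sorted order so the centroid is bit-identical
        # under any permutation of the cells
        idx = idx[np.argsort([annotation.barcodes[i] for i in idx], kind="stable")]
        cols.append(x[:, idx].mean(axis=1))
    return CentroidMatrix(np.column_stack(cols), list(spec.terminal_labels))


def compute_distances(matrix: MatrixLike, centroids: CentroidMatrix) -> DistanceMatrix:
    """Euclidean distance from every cell to every terminal centroid."""
    x = _dense(matrix)
    if x.shape[0] != centroids.values.shape[0]:
        raise ValidationError(
            f"matrix has {x.shape[0]} features but centroids have "
            f"{centroids.values.shape[0]}")
    diff = x[:, :, np.newaxis] - centroids.values[:, np.newaxis, :]
    d = np.sqrt((diff ** 2).sum(axis=0))  # cells x N
    return DistanceMatrix(d)


def row_normalize_distances(distances: DistanceMatrix) -> DistanceMatrix:
    """Scale each cell's distances to unit sum."""
    d = distances.values
    rowsum = d.sum(axis=1)
    if np.any(rowsum == 0):
        bad = int(np.flatnonzero(rowsum == 0)[0])
        raise ValidationError(
            f"cell {bad} is at zero distance from every centroid — the "
            "terminal centroids coincide (degenerate simplex)")
    return DistanceMatrix(d / rowsum[:, np.newaxis])


def gaussian_similarity(distances: DistanceMatrix,
                        sigma: float = DEFAULT_SIGMA) -> SimilarityMatrix:
    """Convert row-normalized distances to similarities, exp(-d / sigma)."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    return SimilarityMatrix(np.exp(-distances.values / sigma))


def range_scale(similarity: SimilarityMatrix) -> SimilarityMatrix:
    """Affinely map each vertex's similarity column onto [0, 1].

    A constant column carries no ranking information; it maps to 0.5
    everywhere with a warning.
    """
    s = similarity.values
    lo = s.min(axis=0)
    hi = s.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} similarity columns are constant; "
                      "mapping them to 0.5", DegenerateDataWarning, stacklevel=2)
    safe = np.where(const, 1.0, span)
    scaled = (s - lo[np.newaxis, :]) / safe[np.newaxis, :]
    scaled[:, const] = 0.5
    return SimilarityMatrix(scaled)


def l1_normalize(similarity: SimilarityMatrix,
                 terminal_labels: Optional[Sequence[str]] = None,
                 barcodes: Optional[Sequence[str]] = None) -> BarycentricCoordinates:
    """L1-normalize each cell's scaled similarities into a unit-sum row.

    A cell at the column minimum for every vertex has an all-zero row; it is
    assigned the uniform coordinate 1/N with a warning.
    """
    s = similarity.values
    n = s.shape[1]
    rowsum = s.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero scaled similarity "
                      f"to every vertex; assigning uniform 1/{n}",
                      DegenerateDataWarning, stacklevel=2)
    out = np.empty_like(s)
    out[~zero] = s[~zero] / rowsum[~zero, np.newaxis]
    out[zero] = 1.0 / n
    labels = list(terminal_labels) if terminal_labels is not None else [
        f"vertex{i + 1}" for i in range(n)]
    return BarycentricCoordinates(out, labels,
                                  list(barcodes) if barcodes is not None else None)


_SQ3 = np.sqrt(3.0)
_VERTICES = {
    2: np.array([[0.0], [1.0]]),
    3: np.array([[0.0, 0.0], [1.0, 0.0], [0.5, _SQ3 / 2]]),
    4: np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, _SQ3 / 2, 0.0],
                 [0.5, _SQ3 / 6, np.sqrt(6.0) / 3]]),
}


def simplex_vertices(n: int) -> np.ndarray:
    """Cartesian vertex coordinates of the unit segment / equilateral
    triangle / regular tetrahedron used for plotting (N x (N-1))."""
    if n not in _VERTICES:
        raise ValidationError(f"simplexes support 2-4 vertices, got {n}")
    return _VERTICES[n].copy()


def barycentric_to_cartesian(coords: BarycentricCoordinates) -> np.ndarray:
    """Project barycentric rows to C x (N-1) Cartesian plotting coordinates."""
    n = coords.n_vertices
    b = coords.values
    rows = b.sum(axis=1)
    if b.size and np.abs(rows - 1.0).max() > 1e-6:
        raise ValidationError("barycentric rows must sum to 1 before projection")
    return b @ simplex_vertices(n)


@dataclass
class SimplexResult:
    """Everything the end-to-end computation produces."""

    coordinates: BarycentricCoordinates
    cartesian: np.ndarray
    spec: SimplexSpec
    markers: Optional[MarkerTable] = None
    potential: Optional["FatePotential"] = None  # noqa: F821
    field: Optional["VelocityField"] = None  # noqa: F821


def compute_simplex(matrix: ExpressionMatrix, annotation: CellAnnotation,
                    spec: SimplexSpec,
                    graph: Optional[TransitionGraph] = None,
                    method: str = "markers",
                    top_k: int = 30,
                    sigma: float = DEFAULT_SIGMA,
                    n_components: int = 10,
                    resolution: int = 10,
                    normalize: bool = True,
                    log_transform: bool = True) -> SimplexResult:
    """Run the full pipeline: normalize, select the feature subspace,
    place every cell in the simplex and (optionally) aggregate velocity.

    Internally the terminal labels are processed in sorted order and the
    output columns permuted back to the requested order, so reordering
    ``spec.terminal_labels`` permutes the result columns bit-exactly.
    """
    if method not in ("markers", "pca"):
        raise ValidationError(f"method must be 'markers' or 'pca', got {method!r}")
    spec.validate_against(annotation)
    matrix, annotation, graph = align(matrix, annotation, graph)

    if normalize:
        matrix = normalize_counts(matrix, log_transform=log_transform)

    canonical = SimplexSpec(sorted(spec.terminal_labels))
    markers: Optional[MarkerTable] = None
    if method == "markers":
        markers = wilcoxon_markers(matrix, annotation, canonical, top_k=top_k)
        union = markers.feature_union
        if not union:
            raise ValidationError(
                "no positive-fold-change markers found for any terminal; "
                "cannot build a feature subspace")
        space: MatrixLike = matrix.subset_features(union)
    else:
        space = pca_embed(matrix, n_components)

    centroids = compute_centroids(space, annotation, canonical)
    d = compute_distances(space, centroids)
    d = row_normalize_distances(d)
    s = gaussian_similarity(d, sigma=sigma)
    s = range_scale(s)
    bary = l1_normalize(s, canonical.terminal_labels, annotation.barcodes)

    # permute columns from canonical (sorted) order to the requested order
    perm = [canonical.terminal_labels.index(t) for t in spec.terminal_labels]
    coordinates = BarycentricCoordinates(bary.values[:, perm],
                                         list(spec.terminal_labels),
                                         list(annotation.barcodes))
    cartesian = barycentric_to_cartesian(coordinates)

    potential = field = None
    if graph is not None:
        from .velocity import fate_potential, grid_bin, FatePotential
        pot_canonical = fate_potential(graph, annotation, canonical)
        potential = FatePotential(pot_canonical.values[:, perm],
                                  list(spec.terminal_labels))
        field = grid_bin(cartesian, potential, resolution=resolution)

    if markers is not None:
        markers = MarkerTable({t: markers.tables[t] for t in spec.terminal_labels},
                              markers.top_k)
    return SimplexResult(coordinates=coordinates, cartesian=cartesian,
                         spec=spec, markers=markers, potential=potential,
                         field=field)
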