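"""Fate potential from a cell-cell transition graph, and its grid summary.

The transition graph (rows = source cells, columns = targets) comes from an
upstream RNA-velocity tool; this module never infers velocity itself.  A
cell's *fate potential* toward terminal cluster n is the mean outgoing edge
weight into that cluster, counting absent edges as zero and excluding the
self-edge:

    P[c, n] = sum_{j in cluster n, j != c} W[c, j] / |cluster n \\ {c}|

Averaging over the whole target cluster (not just connected neighbors)
keeps the statistic deterministic under kNN sparsification and monotone in
connectivity.  For display, cells are binned on their Cartesian simplex
coordinates into square (ternary) or cube (quaternary) grids laid over the
bounding box of the vertex polytope — so bin boundaries do not depend on
the data — and each occupied bin's mean potential is L1-normalized across
the N fates into arrow weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (CellAnnotation, DegenerateDataWarning, SimplexSpec,
                 TransitionGraph, ValidationError, PathLike)
from .coords import simplex_vertices

__all__ = ["FatePotential", "GridCell", "VelocityField", "fate_potential",
           "grid_bin", "arrows"]


@dataclass
class FatePotential:
    """Per-cell mean transition weight into each terminal cluster (C x N)."""

    values: np.ndarray
    terminal_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.terminal_labels):
            raise ValidationError("one potential column per terminal label required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("fate potential contains NaN or Inf")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("fate potential must be non-negative")


@dataclass
class GridCell:
    """One occupied bin of the velocity grid."""

    index: tuple[int, ...]
    centroid: np.ndarray          # (N-1)-dim Cartesian point
    weights: np.ndarray           # N fate weights, sum 1
    n_cells: int


@dataclass
class VelocityField:
    """Grid-aggregated arrow weights over the simplex."""

    grids: list[GridCell]
    terminal_labels: list[str]
    resolution: int

    def __post_init__(self) -> None:
        for g in self.grids:
            if g.n_cells < 1:
                raise ValidationError("every reported grid must contain a cell")
            if abs(float(g.weights.sum()) - 1.0) > 1e-9:
                raise ValidationError("grid weights must sum to 1")

    @property
    def n_cells_total(self) -> int:
        return sum(g.n_cells for g in self.grids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.grids:
            row: dict = {"grid": "-".join(map(str, g.index)), "n_cells": g.n_cells}
            for j, name in enumerate(("x", "y", "z")[: g.centroid.size]):
                row[f"centroid_{name}"] = g.centroid[j]
            for j, t in enumerate(self.terminal_labels):
                row[f"weight_{t}"] = g.weights[j]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: PathLike) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")
        return path


def fate_potential(graph: TransitionGraph, annotation: CellAnnotation,
                   spec: SimplexSpec) -> FatePotential:
    """Mean outgoing transition weight from each cell into each terminal
    cluster; absent edges count as zero and self-edges are excluded."""
    if list(graph.barcodes) != list(annotation.barcodes):
        raise ValidationError("graph and annotation are not aligned; call align() first")
    spec.validate_against(annotation)
    w = sp.csr_matrix(graph.weights)
    c = w.shape[0]
    diag = w.diagonal()
    cols = []
    for t in spec.terminal_labels:
        idx = annotation.indices_of(t)
        size = idx.size
        member = np.zeros(c, dtype=bool)
        member[idx] = True
        if size == 1:
            # the sole member's own column would average over an empty set
            raise ValidationError(
                f"terminal cluster {t!r} has a single cell; its fate "
                "potential is undefined after self-exclusion")
        total = np.asarray(w[:, idx].sum(axis=1)).ravel()
        total[member] -= diag[member]  # drop self-edges for in-cluster cells
        denom = np.where(member, size - 1, size).astype(float)
        cols.append(total / denom)
    return FatePotential(np.column_stack(cols), list(spec.terminal_labels))


def grid_bin(cartesian: np.ndarray, potential: FatePotential,
             resolution: int = 10) -> VelocityField:
    """Bin cells into ``resolution``^(N-1) axis-aligned bins over the vertex
    polytope's bounding box and aggregate fate potentials per bin.

    Bins are half-open ``[lo, hi)`` with the final bin closed.  Each
    occupied bin's weight vector is the mean of its member cells'
    potentials, L1-normalized across the N fates; a bin whose cells all
    have zero potential gets uniform weights with a warning.
    """
    if resolution < 1:
        raise ValidationError("resolution must be at least 1")
    cartesian = np.asarray(cartesian, dtype=float)
    n = potential.values.shape[1]
    if cartesian.shape[0] != potential.values.shape[0]:
        raise ValidationError("coordinates and potentials disagree on cell count")
    vertices = simplex_vertices(n)
    if cartesian.shape[1] != vertices.shape[1]:
        raise ValidationError(
            f"expected {vertices.shape[1]}-dimensional coordinates for a "
            f"{n}-vertex simplex")
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    tol = 1e-9
    if cartesian.size and ((cartesian < lo - tol).any() or (cartesian > hi + tol).any()):
        raise ValidationError("coordinates fall outside the simplex bounding box")

    frac = (cartesian - lo) / (hi - lo)
    idx = np.clip(np.floor(frac * resolution).astype(int), 0, resolution - 1)

    bins: dict[tuple[int, ...], list[int]] = {}
    for c in range(cartesian.shape[0]):
        bins.setdefault(tuple(idx[c]), []).append(c)

    grids: list[GridCell] = []
    n_degenerate = 0
    for key in sorted(bins):
        members = np.asarray(bins[key], dtype=int)
        mean_pot = potential.values[members].mean(axis=0)
        total = float(mean_pot.sum())
        if total == 0:
            n_degenerate += 1
            weights = np.full(n, 1.0 / n)
        else:
            weights = mean_pot / total
        grids.append(GridCell(index=key,
                              centroid=cartesian[members].mean(axis=0),
                              weights=weights, n_cells=int(members.size)))
    if n_degenerate:
        warnings.warn(f"{n_degenerate} grids have zero total potential; "
                      f"assigning uniform 1/{n} weights",
                      DegenerateDataWarning, stacklevel=2)
    return VelocityField(grids=grids, terminal_labels=list(potential.terminal_labels),
                         resolution=resolution)


def arrows(field: VelocityField, vertex_coords: Optional[np.ndarray] = None,
           max_len: float = 0.15) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Arrow geometry: per occupied grid and per vertex with non-zero
    weight, ``(origin, unit direction toward the vertex, weight * max_len)``.

    A vertex coincident with the grid centroid has no direction and is
    skipped.  Per grid, arrow lengths sum to ``max_len`` (up to skipped
    zero-weight vertices).
    """
    if max_len <= 0:
        raise ValidationError("max_len must be positive")
    n = len(field.terminal_labels)
    if vertex_coords is None:
        vertex_coords = simplex_vertices(n)
    vertex_coords = np.asarray(vertex_coords, dtype=float)
    out: list[tuple[np.ndarray, np.ndarray, float]] = []
    for g in field.grids:
        for j in range(n):
            wj = float(g.weights[j])
            if wj == 0:
                continue
            vec = vertex_coords[j] - g.centroid
            norm = float(np.linalg.norm(vec))
            if norm == 0:
                continue
            out.append((g.centroid.copy(), vec / norm, wj * max_len))
    return out
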