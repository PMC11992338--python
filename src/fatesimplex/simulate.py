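"""Synthetic single-cell fixtures with known ground truth.

The generator emulates the canonical differentiation setup: a few
terminally differentiated clusters, each over-expressing its own block of
marker features, plus a multipotent progenitor population whose expected
expression is a convex mixture of the terminal mean profiles — the
synthetic analogue of a transitional stem-cell cluster sitting in the
middle of the simplex.  Counts are integer-valued (Poisson or
gamma-Poisson/negative-binomial) so fixtures exercise the sparse-integer
code paths of real droplet data.

The transition graph gives every progenitor outgoing edges to a random
subset of each terminal cluster, with total edge mass per cluster
proportional to the progenitor mixture weight; terminal cells have no
outgoing edges.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .io import (CellAnnotation, ExpressionMatrix, TransitionGraph,
                 ValidationError, PathLike, write_annotation, write_matrix,
                 write_transition_graph)

__all__ = ["FixtureSpec", "generate", "write_fixture"]

PROGENITOR_LABEL = "Progenitor"


@dataclass
class FixtureSpec:
    """Parameters of the synthetic world.

    Defaults describe a modest but clearly structured dataset: 3 terminal
    fates x 100 cells plus 100 progenitors with a uniform mixture, 200
    features of which each fate marks 10, Poisson noise around a base rate
    of 1.0 with a +5.0 uplift on a fate's own marker block.
    """

    n_terminal_clusters: int = 3
    cells_per_cluster: int = 100
    n_progenitors: int = 100
    n_features: int = 200
    markers_per_cluster: int = 10
    marker_effect: float = 5.0
    base_rate: float = 1.0
    noise_model: str = "poisson"          # or "negative_binomial"
    dispersion: float = 2.0               # NB shape; larger = closer to Poisson
    progenitor_mixture: Optional[list[float]] = None
    edges_per_cluster: int = 20           # targets per progenitor per terminal
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_terminal_clusters <= 4:
            raise ValidationError("n_terminal_clusters must be 2-4")
        if self.cells_per_cluster < 1 or self.n_features < 1:
            raise ValidationError("cells_per_cluster and n_features must be positive")
        if self.n_progenitors < 0:
            raise ValidationError("n_progenitors must be non-negative")
        if self.markers_per_cluster < 1:
            raise ValidationError("markers_per_cluster must be positive")
        if self.markers_per_cluster * self.n_terminal_clusters > self.n_features:
            raise ValidationError("marker blocks exceed the number of features")
        if self.marker_effect < 0 or self.base_rate < 0:
            raise ValidationError("rates must be non-negative")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValidationError("noise_model must be poisson or negative_binomial")
        if self.progenitor_mixture is None:
            self.progenitor_mixture = [1.0 / self.n_terminal_clusters] * self.n_terminal_clusters
        mix = np.asarray(self.progenitor_mixture, dtype=float)
        if mix.size != self.n_terminal_clusters:
            raise ValidationError("progenitor_mixture needs one weight per terminal")
        if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must be non-negative and sum to 1")

    @property
    def terminal_labels(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_terminal_clusters)]


def _sample_counts(rng: np.random.Generator, mean: np.ndarray,
                   spec: FixtureSpec) -> np.ndarray:
    if spec.noise_model == "poisson":
        return rng.poisson(mean)
    lam = rng.gamma(shape=spec.dispersion,
                    scale=np.maximum(mean, 1e-12) / spec.dispersion)
    return rng.poisson(lam)


def generate(spec: FixtureSpec) -> tuple[ExpressionMatrix, CellAnnotation,
                                         TransitionGraph, dict]:
    """Draw a fixture dataset; returns (matrix, annotation, graph, truth).

    ``truth`` records the marker blocks, cluster mean profiles and the
    progenitor mixture, for assertions against recovered structure.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_terminal_clusters
    m = spec.markers_per_cluster
    g = spec.n_features

    means = np.full((k, g), spec.base_rate)
    marker_blocks: dict[str, list[int]] = {}
    for i, label in enumerate(spec.terminal_labels):
        block = list(range(i * m, (i + 1) * m))
        marker_blocks[label] = block
        means[i, block] += spec.marker_effect
    mix = np.asarray(spec.progenitor_mixture, dtype=float)
    prog_mean = mix @ means

    columns = []
    barcodes = []
    clusters = []
    cell = 0
    for i, label in enumerate(spec.terminal_labels):
        for _ in range(spec.cells_per_cluster):
            columns.append(_sample_counts(rng, means[i], spec))
            barcodes.append(f"cell{cell:05d}")
            clusters.append(label)
            cell += 1
    for _ in range(spec.n_progenitors):
        columns.append(_sample_counts(rng, prog_mean, spec))
        barcodes.append(f"cell{cell:05d}")
        clusters.append(PROGENITOR_LABEL)
        cell += 1

    counts = np.column_stack(columns).astype(float)  # features x cells
    feature_ids = [f"gene{i:05d}" for i in range(g)]
    matrix = ExpressionMatrix(sp.csr_matrix(counts), feature_ids, barcodes)
    annotation = CellAnnotation(barcodes, clusters)

    c = len(barcodes)
    rows, cols, vals = [], [], []
    prog_offset = k * spec.cells_per_cluster
    for p in range(spec.n_progenitors):
        src = prog_offset + p
        for i in range(k):
            if mix[i] == 0:
                continue
            start = i * spec.cells_per_cluster
            n_targets = min(spec.edges_per_cluster, spec.cells_per_cluster)
            targets = rng.choice(spec.cells_per_cluster, size=n_targets,
                                 replace=False) + start
            for t in targets:
                rows.append(src)
                cols.append(int(t))
                vals.append(mix[i] / n_targets)
    graph = TransitionGraph(
        sp.csr_matrix((vals, (rows, cols)), shape=(c, c)), barcodes)

    truth = {
        "terminal_labels": spec.terminal_labels,
        "progenitor_label": PROGENITOR_LABEL,
        "marker_blocks": {lab: [feature_ids[i] for i in block]
                          for lab, block in marker_blocks.items()},
        "cluster_means": {lab: means[i].tolist()
                          for i, lab in enumerate(spec.terminal_labels)},
        "progenitor_mixture": mix.tolist(),
    }
    return matrix, annotation, graph, truth


def write_fixture(spec: FixtureSpec, out_dir: PathLike) -> Path:
    """Generate a fixture and write it in the formats the readers consume:
    MatrixMarket matrix + sibling TSVs, annotation CSV, transition ``.mtx``
    and the ground truth as JSON.  One command regenerates everything."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, annotation, graph, truth = generate(spec)
    write_matrix(matrix, out_dir / "matrix", format="mtx")
    write_annotation(annotation, out_dir / "annotation.csv")
    write_transition_graph(graph, out_dir / "transition.mtx")
    (out_dir / "ground_truth.json").write_text(
        json.dumps({"spec": asdict(spec), "truth": truth}, indent=2),
        encoding="utf-8")
    return out_dir
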