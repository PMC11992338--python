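"""Segment (N=2), ternary (N=3) and quaternary (N=4) simplex plots.

Rendering is split into two layers.  ``build_geometry`` produces a
:class:`PlotGeometry` — point coordinates, colors, vertex positions and
arrow segments — that tests assert on directly; the ``plot_*`` functions
hand that geometry to matplotlib and write PNG/SVG/PDF.  Pixel output is
never part of the contract.

Cluster colors are assigned deterministically from sorted label order; by
default non-terminal cells are drawn gray so the chosen fates stand out,
and both arrows and vertices share each fate's color.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

import matplotlib
import matplotlib.pyplot as plt

from .io import CellAnnotation, SimplexSpec, ValidationError, PathLike
from .coords import BarycentricCoordinates, barycentric_to_cartesian, simplex_vertices
from .velocity import VelocityField, arrows as velocity_arrows

__all__ = ["PlotConfig", "PlotGeometry", "Arrow", "cluster_palette",
           "build_geometry", "plot_ternary", "plot_quaternary", "plot_binary",
           "plot_simplex"]

GRAY = "#b8b8b8"
_PALETTE = ["#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
            "#a65628", "#f781bf", "#17becf", "#bcbd22", "#8c564b"]


@dataclass
class PlotConfig:
    """Styling knobs shared by all simplex plots."""

    point_size: float = 8.0
    vertex_colors: Optional[list[str]] = None
    arrow_max_len: float = 0.15
    title: str = ""
    output_format: str = "png"
    dpi: int = 150
    jitter_seed: int = 0          # vertical jitter of the N=2 segment plot
    color_all_clusters: bool = False

    def __post_init__(self) -> None:
        if self.point_size <= 0:
            raise ValidationError("point_size must be positive")
        if self.arrow_max_len <= 0:
            raise ValidationError("arrow_max_len must be positive")
        if self.output_format not in ("png", "svg", "pdf"):
            raise ValidationError("output_format must be png, svg or pdf")
        if self.dpi < 1:
            raise ValidationError("dpi must be positive")


@dataclass(frozen=True)
class Arrow:
    origin: tuple
    direction: tuple
    length: float
    color: str


@dataclass
class PlotGeometry:
    """Backend-independent plot data; all geometry tests target this."""

    points: np.ndarray            # C x (N-1) Cartesian positions
    point_colors: list[str]
    point_clusters: list[str]
    vertices: np.ndarray          # N x (N-1)
    vertex_labels: list[str]
    vertex_colors: list[str]
    arrows: list[Arrow] = dc_field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        names = ("x", "y", "z")[: self.points.shape[1]]
        df = pd.DataFrame(self.points, columns=list(names))
        df["cluster"] = self.point_clusters
        df["color"] = self.point_colors
        return df


def cluster_palette(labels: Sequence[str]) -> dict[str, str]:
    """Deterministic label -> color map by sorted label order."""
    ordered = sorted(set(labels))
    return {lab: _PALETTE[i % len(_PALETTE)] for i, lab in enumerate(ordered)}


def build_geometry(coords: BarycentricCoordinates, annotation: CellAnnotation,
                   field: Optional[VelocityField] = None,
                   config: Optional[PlotConfig] = None) -> PlotGeometry:
    """Assemble the plot-data layer from coordinates, labels and velocity."""
    config = config or PlotConfig()
    if coords.barcodes is not None and list(coords.barcodes) != list(annotation.barcodes):
        raise ValidationError("coordinates and annotation are not aligned")
    if coords.values.shape[0] != annotation.n_cells:
        raise ValidationError("coordinates and annotation disagree on cell count")
    n = coords.n_vertices
    vertices = simplex_vertices(n)
    points = barycentric_to_cartesian(coords)

    palette = cluster_palette(list(annotation.clusters) + coords.terminal_labels)
    if config.vertex_colors is not None:
        if len(config.vertex_colors) != n:
            raise ValidationError("vertex_colors length must equal N")
        vcolors = list(config.vertex_colors)
    else:
        vcolors = [palette[t] for t in coords.terminal_labels]
    fate_color = dict(zip(coords.terminal_labels, vcolors))

    terminal_set = set(coords.terminal_labels)
    point_colors = []
    for lab in annotation.clusters:
        if lab in terminal_set:
            point_colors.append(fate_color[lab])
        elif config.color_all_clusters:
            point_colors.append(palette[lab])
        else:
            point_colors.append(GRAY)

    arrow_list: list[Arrow] = []
    if field is not None:
        for origin, direction, length in velocity_arrows(
                field, vertices, max_len=config.arrow_max_len):
            # color by the vertex the arrow points at: the direction is the
            # unit vector toward exactly one vertex
            to_vertex = vertices - origin[np.newaxis, :]
            norms = np.maximum(np.linalg.norm(to_vertex, axis=1), 1e-30)
            j = int(np.argmax((to_vertex @ direction) / norms))
            arrow_list.append(Arrow(tuple(origin), tuple(direction),
                                    float(length), vcolors[j]))
    return PlotGeometry(points=points, point_colors=point_colors,
                        point_clusters=list(annotation.clusters),
                        vertices=vertices,
                        vertex_labels=list(coords.terminal_labels),
                        vertex_colors=vcolors, arrows=arrow_list)


def _save(fig, path: Optional[PathLike], config: PlotConfig) -> Optional[Path]:
    if path is None:
        plt.close(fig)
        return None
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix("." + config.output_format)
    fig.savefig(path, dpi=config.dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_ternary(coords: BarycentricCoordinates, annotation: CellAnnotation,
                 field: Optional[VelocityField] = None,
                 config: Optional[PlotConfig] = None,
                 path: Optional[PathLike] = None) -> PlotGeometry:
    """Triangle plot of a 3-fate simplex with optional velocity arrows."""
    if coords.n_vertices != 3:
        raise ValidationError(
            f"plot_ternary needs 3 vertices, got {coords.n_vertices}; use "
            "plot_binary (N=2) or plot_quaternary (N=4)")
    config = config or PlotConfig()
    geom = build_geometry(coords, annotation, field, config)

    fig, ax = plt.subplots(figsize=(6, 5.5))
    tri = np.vstack([geom.vertices, geom.vertices[:1]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    ax.scatter(geom.points[:, 0], geom.points[:, 1], s=config.point_size,
               c=geom.point_colors, linewidths=0, alpha=0.8, zorder=2)
    offsets = np.array([[-0.03, -0.05], [0.03, -0.05], [0.0, 0.05]])
    for v, lab, col, off in zip(geom.vertices, geom.vertex_labels,
                                geom.vertex_colors, offsets):
        ax.annotate(lab, v, v + off, color=col, fontsize=11,
                    ha="center", fontweight="bold")
    for a in geom.arrows:
        tip = np.asarray(a.origin) + np.asarray(a.direction) * a.length
        ax.annotate("", xy=tip, xytext=a.origin,
                    arrowprops=dict(arrowstyle="->", color=a.color, lw=1.2))
    ax.set_aspect("equal")
    ax.set_axis_off()
    if config.title:
        ax.set_title(config.title)
    _save(fig, path, config)
    return geom


def plot_quaternary(coords: BarycentricCoordinates, annotation: CellAnnotation,
                    field: Optional[VelocityField] = None,
                    config: Optional[PlotConfig] = None,
                    path: Optional[PathLike] = None,
                    view_angles: Sequence[tuple[float, float]] = ((30.0, 20.0),)
                    ) -> PlotGeometry:
    """Tetrahedron plot of a 4-fate simplex; one file per view angle."""
    if coords.n_vertices != 4:
        raise ValidationError(
            f"plot_quaternary needs 4 vertices, got {coords.n_vertices}; use "
            "plot_ternary (N=3) or plot_binary (N=2)")
    config = config or PlotConfig()
    geom = build_geometry(coords, annotation, field, config)

    edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    multi = len(view_angles) > 1
    for k, (azim, elev) in enumerate(view_angles):
        fig = plt.figure(figsize=(6, 6))
        ax = fig.add_subplot(projection="3d")
        for i, j in edges:
            seg = geom.vertices[[i, j]]
            ax.plot(seg[:, 0], seg[:, 1], seg[:, 2], color="black", lw=0.8)
        ax.scatter(geom.points[:, 0], geom.points[:, 1], geom.points[:, 2],
                   s=config.point_size, c=geom.point_colors, alpha=0.7,
                   linewidths=0)
        for v, lab, col in zip(geom.vertices, geom.vertex_labels,
                               geom.vertex_colors):
            ax.text(*v, lab, color=col, fontsize=11, fontweight="bold")
        for a in geom.arrows:
            d = np.asarray(a.direction) * a.length
            ax.quiver(*a.origin, *d, color=a.color, lw=1.0,
                      arrow_length_ratio=0.25)
        ax.view_init(elev=elev, azim=azim)
        ax.set_axis_off()
        if config.title:
            ax.set_title(config.title)
        out = path
        if path is not None and multi:
            p = Path(path)
            suffix = p.suffix or "." + config.output_format
            out = p.with_name(f"{p.stem}_view{k}{suffix}")
        _save(fig, out, config)
    return geom


def plot_binary(coords: BarycentricCoordinates, annotation: CellAnnotation,
                field: Optional[VelocityField] = None,
                config: Optional[PlotConfig] = None,
                path: Optional[PathLike] = None) -> PlotGeometry:
    """Two-fate plot: cells along the unit segment at their coordinate for
    the second vertex, vertically jittered by a seeded RNG for visibility."""
    if coords.n_vertices != 2:
        raise ValidationError(
            f"plot_binary needs 2 vertices, got {coords.n_vertices}; use "
            "plot_ternary (N=3) or plot_quaternary (N=4)")
    config = config or PlotConfig()
    geom = build_geometry(coords, annotation, field, config)

    rng = np.random.default_rng(config.jitter_seed)
    jitter = rng.uniform(-0.05, 0.05, size=geom.points.shape[0])

    fig, ax = plt.subplots(figsize=(6, 2))
    ax.plot([0, 1], [0, 0], color="black", lw=1)
    ax.scatter(geom.points[:, 0], jitter, s=config.point_size,
               c=geom.point_colors, linewidths=0, alpha=0.8)
    for x, lab, col in zip((0.0, 1.0), geom.vertex_labels, geom.vertex_colors):
        ax.annotate(lab, (x, 0), (x, 0.09), color=col, fontsize=11,
                    ha="center", fontweight="bold")
    for a in geom.arrows:
        tip = a.origin[0] + a.direction[0] * a.length
        ax.annotate("", xy=(tip, -0.08), xytext=(a.origin[0], -0.08),
                    arrowprops=dict(arrowstyle="->", color=a.color, lw=1.2))
    ax.set_ylim(-0.15, 0.15)
    ax.set_axis_off()
    if config.title:
        ax.set_title(config.title)
    _save(fig, path, config)
    return geom


def plot_simplex(coords: BarycentricCoordinates, annotation: CellAnnotation,
                 field: Optional[VelocityField] = None,
                 config: Optional[PlotConfig] = None,
                 path: Optional[PathLike] = None, **kwargs) -> PlotGeometry:
    """Dispatch to the segment / ternary / quaternary plot by vertex count."""
    n = coords.n_vertices
    if n == 2:
        return plot_binary(coords, annotation, field, config, path)
    if n == 3:
        return plot_ternary(coords, annotation, field, config, path)
    return plot_quaternary(coords, annotation, field, config, path, **kwargs)
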