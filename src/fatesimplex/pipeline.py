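"""End-to-end pipeline entry point: read inputs, compute, write outputs.

:func:`run` is the programmatic equivalent of a one-shot command: given a
:class:`RunConfig` it reads the matrix, annotation and optional transition
graph, computes markers, barycentric coordinates and velocity aggregation,
and writes TSV tables, a plot and a JSON run manifest into the output
directory.  Outputs are byte-deterministic for a fixed config and seed, and
the manifest records every parameter plus the package version so a run can
be reproduced from it alone.  On failure, partial outputs are removed and
the error names the stage that failed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .io import (SimplexSpec, ValidationError, PathLike, read_annotation,
                 read_matrix, read_transition_graph)
from .coords import DEFAULT_SIGMA, compute_simplex
from .plotting import PlotConfig, plot_simplex

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one run needs; serialized verbatim into the manifest."""

    matrix: str
    annotation: str
    terminals: list[str]
    out_dir: str
    graph: Optional[str] = None
    method: str = "markers"            # or "pca"
    top_k: int = 30
    sigma: float = DEFAULT_SIGMA
    n_components: int = 10
    resolution: int = 10
    normalize: bool = True
    log_transform: bool = True
    modality: str = "rna"
    plot_format: str = "png"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 2 <= len(self.terminals) <= 4:
            raise ValidationError(
                f"terminals must list 2-4 cluster labels, got {len(self.terminals)}")
        if self.method not in ("markers", "pca"):
            raise ValidationError("method must be 'markers' or 'pca'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: PathLike) -> "RunConfig":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        payload.pop("version", None)
        return cls(**payload)


def run(config: RunConfig) -> Path:
    """Execute the pipeline described by ``config``; returns the output dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    spec = SimplexSpec(list(config.terminals))

    matrix = _stage("read_matrix", read_matrix, config.matrix,
                    modality=config.modality)
    annotation = _stage("read_annotation", read_annotation, config.annotation)
    graph = None
    if config.graph is not None:
        graph = _stage("read_transition_graph", read_transition_graph,
                       config.graph, matrix.barcodes)

    result = _stage("compute_simplex", compute_simplex, matrix, annotation,
                    spec, graph=graph, method=config.method,
                    top_k=config.top_k, sigma=config.sigma,
                    n_components=config.n_components,
                    resolution=config.resolution,
                    normalize=config.normalize,
                    log_transform=config.log_transform)

    def _write_all():
        written.append(result.coordinates.to_tsv(out_dir / "coordinates.tsv"))
        if result.markers is not None:
            written.append(result.markers.to_tsv(out_dir / "markers.tsv"))
        if result.field is not None:
            written.append(result.field.to_tsv(out_dir / "velocity.tsv"))
        plot_cfg = PlotConfig(output_format=config.plot_format,
                              jitter_seed=config.seed,
                              title=" / ".join(config.terminals))
        plot_path = out_dir / f"simplex.{config.plot_format}"
        plot_simplex(result.coordinates, annotation, result.field,
                     plot_cfg, plot_path)
        written.append(plot_path)
        manifest = {"version": __version__, **config.to_dict()}
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True),
                                 encoding="utf-8")
        written.append(manifest_path)

    _stage("write_outputs", _write_all)
    logger.info("run complete: %d cells placed on a %d-vertex simplex -> %s",
                result.coordinates.values.shape[0], spec.n_vertices, out_dir)
    return out_dir
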