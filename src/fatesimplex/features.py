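"""Count normalization and feature-subspace selection.

Two routes define the space in which cell-to-centroid distances are measured:

* the default marker route — for each chosen terminal fate, a one-vs-rest
  (rest = the other chosen terminals) two-sided Wilcoxon rank-sum test per
  feature, keeping the top ``k`` (default 30) features with positive log
  fold change; the union of all terminals' markers is the shared subspace;
* a PCA route — cells represented by their scores on the leading principal
  components of the feature-centered matrix.

The rank-sum test uses midranks for ties, the tie-corrected normal
approximation and a 0.5 continuity correction; a feature identical in both
groups gets z = 0 and p = 1.  Only terminal-fate cells enter the test, so
relabeling any non-terminal cluster cannot change the selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import (CellAnnotation, DegenerateDataWarning, ExpressionMatrix,
                 SimplexSpec, ValidationError, PathLike)

__all__ = [
    "MarkerTable",
    "CellEmbedding",
    "normalize_counts",
    "wilcoxon_markers",
    "rank_sum_test",
    "pca_embed",
]

LFC_PSEUDOCOUNT = 1e-9


def normalize_counts(matrix: ExpressionMatrix, scale: float = 1e4,
                     log_transform: bool = True) -> ExpressionMatrix:
    """Scale each cell to ``scale`` total counts, then optionally log(1+x).

    All-zero cells pass through unchanged with a warning — Euclidean
    distances on raw counts are dominated by sequencing depth, so this
    counts-per-10k + log1p default mirrors standard single-cell practice.
    """
    totals = np.asarray(matrix.values.sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero total counts and "
                      "pass through normalization unchanged",
                      DegenerateDataWarning, stacklevel=2)
    factors = np.ones_like(totals, dtype=float)
    np.divide(scale, totals, out=factors, where=~zero)
    if sp.issparse(matrix.values):
        vals = matrix.values @ sp.diags(factors)
        if log_transform:
            vals = vals.log1p()
        vals = sp.csr_matrix(vals)
    else:
        vals = matrix.values * factors[np.newaxis, :]
        if log_transform:
            vals = np.log1p(vals)
    return ExpressionMatrix(vals, list(matrix.feature_ids),
                            list(matrix.barcodes), matrix.modality)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Returns ``(W, p)`` where W is the sum of the midranks of ``x`` in the
    pooled sample.  The p-value comes from the normal approximation with
    tie-corrected variance and a 0.5 continuity correction; when the
    variance vanishes (all pooled values identical) p is 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w, p


@dataclass
class MarkerTable:
    """Per-terminal ranked marker selections.

    ``tables[label]`` holds the selected markers of one terminal fate,
    sorted by ascending p-value, ties broken by descending log fold change
    then lexicographic feature id.  ``feature_union`` is the shared feature
    subspace used for distance computation, ordered lexicographically so it
    does not depend on the order in which terminals were listed.
    """

    tables: dict[str, pd.DataFrame]
    top_k: int

    def selected(self, label: str) -> list[str]:
        return self.tables[label]["feature_id"].tolist()

    @property
    def terminal_labels(self) -> list[str]:
        return list(self.tables)

    @property
    def feature_union(self) -> list[str]:
        union: set[str] = set()
        for df in self.tables.values():
            union.update(df["feature_id"])
        return sorted(union)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for label, df in self.tables.items():
            part = df.copy()
            part.insert(0, "rank", np.arange(1, len(part) + 1))
            part.insert(0, "terminal", label)
            parts.append(part)
        cols = ["terminal", "rank", "feature_id", "statistic", "p_value",
                "log_fold_change"]
        if not parts:
            return pd.DataFrame(columns=cols)
        return pd.concat(parts, ignore_index=True)[cols]

    def to_tsv(self, path: PathLike) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")
        return path


def wilcoxon_markers(matrix: ExpressionMatrix, annotation: CellAnnotation,
                     spec: SimplexSpec, top_k: int = 30) -> MarkerTable:
    """Select each terminal fate's top markers by Wilcoxon rank-sum test.

    The test population is the union of the chosen terminal clusters: each
    terminal's cells are compared against the cells of the *other* chosen
    terminals, because the simplex contrasts terminal fates against each
    other.  Only positive-log-fold-change features qualify as markers.
    ``top_k`` defaults to 30.
    """
    if top_k < 1:
        raise ValidationError("top_k must be positive")
    spec.validate_against(annotation)
    if matrix.barcodes != annotation.barcodes:
        raise ValidationError("matrix and annotation are not aligned; call align() first")

    clusters = np.asarray(annotation.clusters, dtype=object)
    terminal_mask = np.isin(clusters, spec.terminal_labels)
    # process terminal cells in barcode-sorted order so group means (hence
    # fold-change tie-breaks) are bit-identical under cell permutation
    term_idx = np.flatnonzero(terminal_mask)
    term_idx = term_idx[np.argsort([annotation.barcodes[i] for i in term_idx],
                                   kind="stable")]
    sub = matrix.values[:, term_idx]
    x = np.asarray(sub.todense(), dtype=float) if sp.issparse(sub) else np.asarray(sub, dtype=float)
    labels = clusters[term_idx]

    for t in spec.terminal_labels:
        if int((labels == t).sum()) < 2:
            raise ValidationError(f"terminal cluster {t!r} has fewer than 2 cells")

    g = matrix.n_features
    if top_k > g:
        warnings.warn(f"top_k={top_k} exceeds the {g} available features; "
                      "using all features with positive log fold change",
                      DegenerateDataWarning, stacklevel=2)

    tables: dict[str, pd.DataFrame] = {}
    for t in spec.terminal_labels:
        in_mask = labels == t
        xin, xout = x[:, in_mask], x[:, ~in_mask]
        stats_w = np.empty(g)
        pvals = np.empty(g)
        for i in range(g):
            stats_w[i], pvals[i] = rank_sum_test(xin[i], xout[i])
        lfc = np.log2((xin.mean(axis=1) + LFC_PSEUDOCOUNT)
                      / (xout.mean(axis=1) + LFC_PSEUDOCOUNT))
        df = pd.DataFrame({"feature_id": matrix.feature_ids,
                           "statistic": stats_w, "p_value": pvals,
                           "log_fold_change": lfc})
        df = df.sort_values(
            by=["p_value", "log_fold_change", "feature_id"],
            ascending=[True, False, True], kind="mergesort").reset_index(drop=True)
        df = df[df["log_fold_change"] > 0].head(top_k).reset_index(drop=True)
        tables[t] = df
    return MarkerTable(tables=tables, top_k=top_k)


@dataclass
class CellEmbedding:
    """A low-dimensional cell representation (components x cells).

    Shaped like :class:`~fatesimplex.io.ExpressionMatrix` (``values``,
    ``feature_ids``, ``barcodes``) so the distance stage consumes either,
    but entries may be negative.
    """

    values: np.ndarray
    feature_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.barcodes)):
            raise ValidationError("embedding shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("embedding contains NaN or Inf")

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return self.values

    def subset_cells(self, indices: Sequence[int]) -> "CellEmbedding":
        idx = np.asarray(indices, dtype=int)
        return CellEmbedding(self.values[:, idx], list(self.feature_ids),
                             [self.barcodes[i] for i in idx])


def pca_embed(matrix: ExpressionMatrix, n_components: int) -> CellEmbedding:
    """Project cells onto the leading principal components.

    Features are centered but not scaled.  Sign convention: each
    component's largest-magnitude feature loading is positive, so the
    embedding is deterministic.  Distances computed on the full-rank
    embedding equal the original feature-space distances (rotation +
    translation).
    """
    g, c = matrix.n_features, matrix.n_cells
    if n_components < 1:
        raise ValidationError("n_components must be positive")
    if n_components > min(g, c):
        raise ValidationError(
            f"n_components={n_components} exceeds min(G, C)={min(g, c)}")
    x = matrix.to_dense().T  # cells x features
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = (s[0] if s.size else 0.0) * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components > rank:
        raise ValidationError(
            f"n_components={n_components} exceeds the data rank {rank}")
    for j in range(n_components):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = (u[:, :n_components] * s[:n_components]).T  # components x cells
    names = [f"PC{i + 1}" for i in range(n_components)]
    return CellEmbedding(scores, names, list(matrix.barcodes))
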