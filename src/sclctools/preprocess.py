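"""Cell quality control, normalization, marker calling and batch testing.

QC follows the two-stage rule used for UMI-based single-cell data: cells
with fewer than 1000 genes detected or fewer than 1000 total UMIs are
low quality; among the remainder, the top 1% by total UMI count are
treated as likely doublets.  Differential expression is a two-sided
Wilcoxon rank-sum test with Bonferroni correction; genes with adjusted
p < 0.05 and avg_logFC > 0.5 are flagged as markers.  The batch test is
a k-nearest-neighbor chi-square rejection rate in the style of k-BET: a
well-mixed dataset has neighborhood batch compositions matching the
global proportions, so the rejection rate stays near the nominal level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, ExprMatrix

__all__ = [
    "QcReport",
    "filter_cells",
    "normalize",
    "batch_rejection_rate",
    "differential_expression",
]


@dataclass
class QcReport:
    n_input_cells: int
    n_low_quality_removed: int
    n_doublet_removed: int
    n_retained: int
    genes_detected: pd.Series  # per input cell
    total_umis: pd.Series

    def __post_init__(self) -> None:
        assert self.n_input_cells == (
            self.n_low_quality_removed + self.n_doublet_removed + self.n_retained
        )

    def to_dict(self) -> dict:
        return {
            "n_input_cells": self.n_input_cells,
            "n_low_quality_removed": self.n_low_quality_removed,
            "n_doublet_removed": self.n_doublet_removed,
            "n_retained": self.n_retained,
        }


def filter_cells(
    cm: CountMatrix,
    min_genes: int = 1000,
    min_umis: int = 1000,
    doublet_top_frac: float = 0.01,
    doublet_metric: str = "total_umis",
) -> tuple[CountMatrix, QcReport]:
    """Two-stage cell filter: low-quality cells, then putative doublets.

    Stage 1 removes cells with ``genes_detected < min_genes`` OR
    ``total_umis < min_umis``.  Stage 2 removes the
    ``ceil(doublet_top_frac * n_remaining)`` cells with the highest
    total UMI count (or genes detected, with
    ``doublet_metric="genes_detected"``) among the remainder.
    Removing every cell is reported with a warning, not an error.
    """
    if min_genes < 0 or min_umis < 0:
        raise ValueError("thresholds must be >= 0")
    if not 0.0 <= doublet_top_frac < 1.0:
        raise ValueError("doublet_top_frac must be in [0, 1)")
    genes_det = cm.genes_detected()
    umis = cm.total_umis()
    low_quality = (genes_det < min_genes) | (umis < min_umis)
    remaining = np.flatnonzero(~low_quality)

    n_doublets = math.ceil(doublet_top_frac * len(remaining)) if doublet_top_frac > 0 else 0
    doublet_mask = np.zeros(cm.n_cells, dtype=bool)
    if n_doublets > 0 and len(remaining):
        metric = umis if doublet_metric == "total_umis" else genes_det
        # ties broken by cell index for determinism
        order = remaining[np.lexsort((remaining, -metric[remaining]))]
        doublet_mask[order[:n_doublets]] = True

    keep = ~low_quality & ~doublet_mask
    report = QcReport(
        n_input_cells=cm.n_cells,
        n_low_quality_removed=int(low_quality.sum()),
        n_doublet_removed=int(doublet_mask.sum()),
        n_retained=int(keep.sum()),
        genes_detected=pd.Series(genes_det, index=cm.cell_ids),
        total_umis=pd.Series(umis, index=cm.cell_ids),
    )
    if report.n_retained == 0:
        warnings.warn("all cells removed by QC filters", stacklevel=2)
    return cm.subset_cells(keep), report


def normalize(cm: CountMatrix, scale: float = 1e4) -> ExprMatrix:
    """Library-size normalization to ``scale`` counts per cell, then log1p.

    Cells with zero total counts are left at zero everywhere (with a
    warning); zeros always map to zero.
    """
    if cm.n_cells == 0:
        raise ValueError("empty matrix")
    umis = cm.total_umis().astype(float)
    zero_cells = umis == 0
    if zero_cells.any():
        warnings.warn(f"{int(zero_cells.sum())} zero-count cells normalized to all-zero",
                      stacklevel=2)
    factors = np.divide(scale, umis, out=np.zeros_like(umis), where=~zero_cells)
    mat = sp.csr_matrix(cm.counts, dtype=float)
    mat = mat.multiply(sp.csr_matrix(factors[None, :]))
    values = np.log1p(np.asarray(mat.todense()))
    return ExprMatrix(values=values, gene_ids=cm.gene_ids, cell_ids=cm.cell_ids)


def batch_rejection_rate(
    features: np.ndarray,
    batch_labels,
    k: int = 25,
    alpha: float = 0.05,
    subsample_frac: float = 0.1,
    seed: int = 0,
) -> float:
    """kNN chi-square batch-mixing rejection rate (k-BET style).

    For a random 10% subsample of cells, tests the batch composition of
    each cell's ``k`` Euclidean nearest neighbors (excluding self)
    against the global batch proportions with a chi-square
    goodness-of-fit test; returns the fraction of tests rejecting at
    ``alpha``.  A single batch returns 0 by definition.
    """
    features = np.asarray(features, dtype=float)
    batch_labels = np.asarray(batch_labels)
    n = features.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    levels, codes = np.unique(batch_labels, return_inverse=True)
    if len(levels) < 2:
        return 0.0
    rng = np.random.default_rng(seed)
    n_sample = int(round(subsample_frac * n))
    if n_sample == 0:
        raise ValueError("subsample_frac yields 0 cells")
    sampled = rng.choice(n, size=n_sample, replace=False)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(features)
    _, idx = nn.kneighbors(features[sampled])
    neigh = idx[:, 1:]  # drop self

    global_props = np.bincount(codes, minlength=len(levels)) / n
    expected = k * global_props
    rejected = 0
    for row in neigh:
        observed = np.bincount(codes[row], minlength=len(levels))
        _, p = stats.chisquare(observed, f_exp=expected)
        if p < alpha:
            rejected += 1
    return rejected / n_sample


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    mid-rank normal approximation with continuity correction otherwise."""
    n = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def differential_expression(
    expr: ExprMatrix,
    labels,
    group,
    p_adj_cutoff: float = 0.05,
    logfc_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DEG table for ``group`` versus all other cells.

    One row per tested gene (genes expressed in no cell are skipped)
    with columns ``p_value``, ``p_adj`` (Bonferroni over tested genes),
    ``avg_logFC`` (mean log-normalized expression, group minus rest),
    ``pct_in``, ``pct_out`` and the boolean ``marker`` flag
    (``p_adj < 0.05`` and ``avg_logFC > 0.5`` by default).
    """
    labels = np.asarray(labels)
    in_group = labels == group
    if not in_group.any():
        raise ValueError(f"group {group!r} not present in labels")
    if in_group.all():
        raise ValueError("group contains every cell; nothing to compare against")
    vals = expr.values
    tested = np.flatnonzero((vals != 0).any(axis=1))
    rows = []
    x_all, y_all = vals[:, in_group], vals[:, ~in_group]
    for gi in tested:
        x, y = x_all[gi], y_all[gi]
        p = 1.0 if (x == x[0]).all() and (y == x[0]).all() else _rank_sum_p(x, y)
        rows.append(
            (
                expr.gene_ids[gi],
                p,
                float(x.mean() - y.mean()),
                float((x > 0).mean()),
                float((y > 0).mean()),
            )
        )
    table = pd.DataFrame(rows, columns=["gene", "p_value", "avg_logFC", "pct_in", "pct_out"])
    table["group"] = group
    table["p_adj"] = np.minimum(1.0, table["p_value"] * len(tested))
    table["marker"] = (table["p_adj"] < p_adj_cutoff) & (table["avg_logFC"] > logfc_cutoff)
    return table[["gene", "group", "p_value", "p_adj", "avg_logFC", "pct_in", "pct_out", "marker"]]
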