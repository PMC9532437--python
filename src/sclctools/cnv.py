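"""Expression-inferred copy-number profiles and malignant-cell calling.

Large-scale CNVs are inferred from log-normalized expression by
centering each gene on the mean of a set of reference cells (normal
epithelial cells from adjacent normal tissue), clipping the residuals,
ordering genes by genomic position and smoothing with a centered moving
average of 100 genes within each chromosome.  Copy-number gains push
the smoothed log-ratio above zero over the segment; losses push it
below.  Cells are called malignant from their CNV burden (mean squared
profile value) by a deterministic 1-D two-means split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExprMatrix, GeneAnnotation

__all__ = ["CnvProfile", "CnvCalls", "infer_cnv_profiles", "call_malignant",
           "moving_average"]


@dataclass
class CnvProfile:
    """Per-cell smoothed, reference-centered CNV log-ratio profiles."""

    values: np.ndarray  # cells x ordered genes
    cell_ids: np.ndarray
    gene_order: pd.DataFrame  # gene_id, chromosome, start (genomic order)
    reference_cell_ids: np.ndarray
    window: int

    def segment_mean(self, chromosome: str, start_idx: int, length: int) -> np.ndarray:
        """Mean profile value per cell over a run of genes on one chromosome."""
        on_chrom = np.flatnonzero(self.gene_order["chromosome"].to_numpy() == chromosome)
        sel = on_chrom[start_idx : start_idx + length]
        return self.values[:, sel].mean(axis=1)


@dataclass
class CnvCalls:
    burden: pd.Series  # mean squared profile value per cell
    malignant: pd.Series  # boolean per cell
    threshold: float
    separation: float  # |center gap| / pooled sd


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis, truncated at edges.

    Position i averages indices [i - (window-1)//2, i + window//2],
    intersected with the array; edge windows therefore shrink.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    left = (window - 1) // 2
    right = window // 2
    csum = np.cumsum(values, axis=-1)
    csum = np.concatenate([np.zeros(values.shape[:-1] + (1,)), csum], axis=-1)
    lo = np.maximum(np.arange(n) - left, 0)
    hi = np.minimum(np.arange(n) + right, n - 1) + 1
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def infer_cnv_profiles(
    expr: ExprMatrix,
    annotation: GeneAnnotation,
    reference_cell_ids,
    window: int = 100,
    min_mean_expr: float = 0.1,
    residual_clip: float = 3.0,
    final_clip: float = 1.0,
) -> CnvProfile:
    """Smoothed reference-centered CNV profiles over genomically ordered genes.

    Pipeline: drop unannotated / low-mean genes; subtract the per-gene
    reference-cell mean from log-normalized values; clip residuals to
    ``±residual_clip``; order genes by (chromosome rank, start,
    gene_id); centered moving average of ``window`` genes within each
    chromosome (truncated at chromosome edges); subtract the per-cell
    median; clip to ``±final_clip``.
    """
    ref_ids = np.asarray(reference_cell_ids, dtype=object)
    cell_pos = {c: i for i, c in enumerate(expr.cell_ids)}
    missing = [c for c in ref_ids if c not in cell_pos]
    if missing:
        raise ValueError(f"reference cells not in matrix: {missing[:5]}")
    if len(ref_ids) < 2:
        raise ValueError("need at least 2 reference cells")
    ref_idx = np.array([cell_pos[c] for c in ref_ids])

    mean_expr = expr.values.mean(axis=1)
    expressed = mean_expr >= min_mean_expr
    keep_genes = set(expr.gene_ids[expressed])
    order = annotation.ordered(gene_ids=keep_genes)
    if len(order) == 0:
        raise ValueError("no annotated genes pass the expression filter")
    chrom_sizes = order["chromosome"].value_counts()
    if (chrom_sizes < window).all():
        raise ValueError(
            f"no chromosome has >= {window} usable genes "
            f"(max {int(chrom_sizes.max())}); use a smaller window"
        )

    gidx = expr.gene_index(order["gene_id"].to_numpy())
    vals = expr.values[gidx, :]  # ordered genes x cells
    ref_mean = vals[:, ref_idx].mean(axis=1, keepdims=True)
    resid = np.clip(vals - ref_mean, -residual_clip, residual_clip)

    smoothed = np.empty_like(resid)
    chroms = order["chromosome"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        smoothed[sel, :] = moving_average(resid[sel, :].T, window).T

    profile = smoothed.T  # cells x genes
    profile = profile - np.median(profile, axis=1, keepdims=True)
    profile = np.clip(profile, -final_clip, final_clip)
    return CnvProfile(
        values=profile,
        cell_ids=expr.cell_ids,
        gene_order=order,
        reference_cell_ids=ref_ids,
        window=window,
    )


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> tuple[float, float, np.ndarray]:
    """Deterministic 1-D two-means: centers initialized at min and max."""
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return lo, hi, np.zeros(len(x), dtype=bool)
    for _ in range(max_iter):
        upper = np.abs(x - hi) < np.abs(x - lo)  # ties go to the lower center
        if not upper.any() or upper.all():
            break
        new_lo, new_hi = float(x[~upper].mean()), float(x[upper].mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return lo, hi, upper


def call_malignant(
    profile: CnvProfile, min_gap: float = 0.2, null_sds: float = 5.0
) -> CnvCalls:
    """Call cells malignant from CNV burden (mean squared profile value).

    When the profile contains at least two reference cells their burdens
    define the null (diploid) distribution: the decision threshold is
    ``ref_mean + null_sds * ref_sd``, and the separation statistic is
    the distance of the two-means upper center from the reference mean
    in reference-sd units.  If that separation falls below ``null_sds``
    the burdens are one karyotypically uniform population and every
    cell is called nonmalignant.

    Without usable reference cells, falls back to a deterministic 1-D
    two-means split (centers initialized at min/max; the higher-burden
    group is malignant) guarded by the between-cluster nearest-point
    gap in units of the overall burden sd: a two-means split of a
    unimodal sample leaves this gap near zero, while genuinely bimodal
    burdens leave a gap of order 1, so the split is accepted only when
    the gap exceeds ``min_gap``.
    """
    if profile.values.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    burden = np.mean(profile.values**2, axis=1)
    lo, hi, upper = _two_means_1d(burden)
    pos = {c: i for i, c in enumerate(profile.cell_ids)}
    ref_idx = [pos[c] for c in profile.reference_cell_ids if c in pos]
    ref_burden = burden[ref_idx]
    if len(ref_idx) >= 2 and ref_burden.std() > 0:
        ref_mean, ref_sd = float(ref_burden.mean()), float(ref_burden.std())
        separation = (hi - ref_mean) / ref_sd
        threshold = ref_mean + null_sds * ref_sd
        malignant = burden > threshold if separation >= null_sds else np.zeros(
            len(burden), dtype=bool
        )
    else:
        pooled_sd = float(burden.std())
        if pooled_sd > 0 and upper.any() and not upper.all():
            separation = float(burden[upper].min() - burden[~upper].max()) / pooled_sd
        else:
            separation = 0.0
        malignant = upper if separation >= min_gap else np.zeros(len(burden), dtype=bool)
        threshold = (lo + hi) / 2.0
    return CnvCalls(
        burden=pd.Series(burden, index=profile.cell_ids, name="cnv_burden"),
        malignant=pd.Series(malignant, index=profile.cell_ids, name="malignant"),
        threshold=float(threshold),
        separation=float(separation),
    )
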