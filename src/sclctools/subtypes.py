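"""SCLC molecular subtyping, intratumor heterogeneity, and hot/cold calling.

SCLC tumors are classified by the dominant lineage transcription factor
among ASCL1 (SCLC-A), NEUROD1 (SCLC-N), POU2F3 (SCLC-P) and YAP1
(SCLC-Y); cells co-expressing ASCL1 and NEUROD1 form the hybrid
SCLC-A/N state, and cells expressing none of the four are non-NE
(non-neuroendocrine).  Intratumor heterogeneity is summarized by the
Shannon entropy of the per-cell subtype mix.  Bulk samples are split
into immune "hot" and "cold" phenotypes from a z-scored immune
signature score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BulkMatrix, ExprMatrix

__all__ = [
    "SUBTYPE_LABELS",
    "classify_cell_subtype",
    "classify_tumor_subtype",
    "subtype_heterogeneity",
    "classify_hot_cold",
    "HotColdCall",
]

TF_ORDER = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")
SUBTYPE_LABELS = ("SCLC-A", "SCLC-N", "SCLC-A/N", "SCLC-P", "SCLC-Y", "non-NE")


def _label_from_flags(a: bool, n: bool, p: bool, y: bool) -> str:
    if a and n:
        return "SCLC-A/N"
    if a:
        return "SCLC-A"
    if n:
        return "SCLC-N"
    if p:
        return "SCLC-P"
    if y:
        return "SCLC-Y"
    return "non-NE"


def classify_cell_subtype(expr: ExprMatrix, tau: float = 0.0) -> pd.Series:
    """Per-cell subtype from the four TFs; "+" means expression > ``tau``.

    Rule order: A+ and N+ -> SCLC-A/N; A+ only -> SCLC-A; N+ only ->
    SCLC-N; else P+ -> SCLC-P; else Y+ -> SCLC-Y; else non-NE.
    Raises if any TF row is missing, naming it.
    """
    lookup = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [tf for tf in TF_ORDER if tf not in lookup]
    if missing:
        raise ValueError(f"missing transcription factor rows: {missing}")
    flags = {tf: expr.values[lookup[tf], :] > tau for tf in TF_ORDER}
    labels = [
        _label_from_flags(flags["ASCL1"][j], flags["NEUROD1"][j],
                          flags["POU2F3"][j], flags["YAP1"][j])
        for j in range(expr.values.shape[1])
    ]
    return pd.Series(labels, index=expr.cell_ids, name="subtype")


def classify_tumor_subtype(cell_labels, min_minor_frac: float = 0.10):
    """Tumor-level subtype from per-cell labels.

    The dominant label is the mode of the per-cell labels excluding
    non-NE (unless every cell is non-NE).  A tumor whose dominant label
    is SCLC-A or SCLC-A/N is called SCLC-A/N when the combined fraction
    of SCLC-N and SCLC-A/N cells is at least ``min_minor_frac``.
    Returns ``(label, fractions over all six labels)``.
    """
    labels = pd.Series(cell_labels)
    if labels.empty:
        raise ValueError("no cells")
    unknown = set(labels) - set(SUBTYPE_LABELS)
    if unknown:
        raise ValueError(f"unknown subtype labels: {sorted(unknown)}")
    fractions = labels.value_counts(normalize=True).reindex(SUBTYPE_LABELS, fill_value=0.0)
    voting = labels[labels != "non-NE"]
    if voting.empty:
        return "non-NE", fractions
    counts = voting.value_counts()
    top = counts.max()
    dominant = sorted(counts[counts == top].index)[0]  # deterministic tie-break
    if dominant in ("SCLC-A", "SCLC-A/N"):
        if fractions["SCLC-N"] + fractions["SCLC-A/N"] >= min_minor_frac:
            dominant = "SCLC-A/N"
        else:
            dominant = "SCLC-A"
    return dominant, fractions


def subtype_heterogeneity(fractions, min_frac: float = 0.10) -> tuple:
    """Shannon entropy (bits) of a subtype fraction vector, plus a flag.

    A tumor is heterogeneous when at least two labels have fraction >=
    ``min_frac``.  The 0 * log 0 convention applies.
    """
    frac = np.asarray(pd.Series(fractions), dtype=float)
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {frac.sum()}, not 1")
    nz = frac[frac > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    heterogeneous = int((frac >= min_frac).sum()) >= 2
    return entropy, heterogeneous


@dataclass
class HotColdCall:
    scores: pd.Series  # per-sample immune signature score
    labels: pd.Series  # "hot" / "cold"
    hot_center: float
    cold_center: float


def classify_hot_cold(bulk: BulkMatrix, immune_signature) -> HotColdCall:
    """Split bulk samples into immune hot / cold by signature score.

    The per-sample score is the mean of per-gene z-scores (across
    samples) of the signature genes present in the matrix; samples are
    split by a deterministic 1-D two-means (centers initialized at the
    min and max score) and the higher-center group is hot.  Constant
    scores give all-cold with a warning.
    """
    from .cnv import _two_means_1d  # same deterministic 1-D split

    if len(bulk.samples) < 2:
        raise ValueError("need at least 2 samples")
    present = [g for g in immune_signature if g in bulk.values.index]
    if not present:
        raise ValueError("no signature gene present in the bulk matrix")
    sub = bulk.values.loc[present].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    z = np.divide(sub - mean, sd, out=np.zeros_like(sub), where=sd > 0)
    scores = pd.Series(z.mean(axis=0), index=bulk.samples, name="immune_score")
    if scores.nunique() == 1:
        warnings.warn("constant signature scores; all samples called cold", stacklevel=2)
        labels = pd.Series("cold", index=scores.index, name="label")
        return HotColdCall(scores, labels, float(scores.iloc[0]), float(scores.iloc[0]))
    lo, hi, upper = _two_means_1d(scores.to_numpy())
    labels = pd.Series(np.where(upper, "hot", "cold"), index=scores.index, name="label")
    return HotColdCall(scores, labels, hot_center=hi, cold_center=lo)
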