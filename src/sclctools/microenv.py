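"""Microenvironment analyses: deconvolution, ligand-receptor testing,
and a gene-counts differentiation score.

Deconvolution follows the MCP-counter idea: the abundance of each of 10
immune / stromal populations in a bulk sample is the mean log2
expression of that population's marker genes.  Cell-cell communication
is scored CellPhoneDB-style: the interaction strength of a
ligand-receptor pair between an ordered (source, target) cluster pair
is the average of the two cluster means, and significance comes from
shuffling cluster labels.  The differentiation score follows the
CytoTRACE premise that less differentiated cells express more genes:
genes-detected counts, optionally kNN-smoothed, rank-scaled to [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .io import BulkMatrix, ExprMatrix, GeneSetCollection

__all__ = [
    "DEFAULT_MCP_POPULATIONS",
    "mcp_abundance",
    "lr_permutation_test",
    "cytotrace_like_score",
]

#: The 10 populations quantified by marker-mean deconvolution
#: (8 immune populations plus endothelial cells and fibroblasts).
DEFAULT_MCP_POPULATIONS = (
    "T_cells",
    "CD8_T_cells",
    "Cytotoxic_lymphocytes",
    "NK_cells",
    "B_lineage",
    "Monocytic_lineage",
    "Myeloid_dendritic_cells",
    "Neutrophils",
    "Endothelial_cells",
    "Fibroblasts",
)


def mcp_abundance(bulk: BulkMatrix, marker_config: GeneSetCollection) -> pd.DataFrame:
    """Marker-mean abundance per population and sample.

    score(pop, sample) = mean over the population's detected markers of
    log2(1 + expression).  Populations with no marker in the matrix are
    reported as NaN with a warning.
    """
    if len(marker_config) == 0:
        raise ValueError("empty marker config")
    log2_vals = np.log2(1.0 + bulk.values)
    rows = {}
    for pop, markers in marker_config.items():
        present = [g for g in markers if g in bulk.values.index]
        if not present:
            warnings.warn(f"population {pop!r} has no detected marker; flagged absent",
                          stacklevel=2)
            rows[pop] = pd.Series(np.nan, index=bulk.values.columns)
            continue
        rows[pop] = log2_vals.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def lr_permutation_test(
    expr: ExprMatrix,
    cluster_labels,
    pairs,
    min_expr_frac: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Ligand-receptor permutation test over ordered cluster pairs.

    For each (ligand, receptor) pair and ordered (source, target)
    cluster pair, the interaction mean is (mean ligand expression in
    source + mean receptor expression in target) / 2.  The null
    shuffles cluster labels; p = (1 + #{null >= observed}) /
    (1 + n_perm).  Pairs where the ligand is expressed in fewer than
    ``min_expr_frac`` of source cells (or the receptor in target cells)
    are reported with p = 1 and ``filtered = True``.  Pairs naming an
    unknown gene are skipped with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(cluster_labels)
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    lookup = {g: i for i, g in enumerate(expr.gene_ids)}
    rng = np.random.default_rng(seed)

    cluster_masks = {c: labels == c for c in clusters}
    # one set of label permutations shared by every pair, for determinism
    perms = np.array([rng.permutation(len(labels)) for _ in range(n_perm)])

    rows = []
    for lig, rec in pairs:
        if lig not in lookup or rec not in lookup:
            warnings.warn(f"pair ({lig}, {rec}) has unknown gene; skipped", stacklevel=2)
            continue
        lig_expr = expr.values[lookup[lig], :]
        rec_expr = expr.values[lookup[rec], :]
        for src in clusters:
            for tgt in clusters:
                if src == tgt:
                    continue
                m_src, m_tgt = cluster_masks[src], cluster_masks[tgt]
                obs = 0.5 * (lig_expr[m_src].mean() + rec_expr[m_tgt].mean())
                filtered = (
                    (lig_expr[m_src] > 0).mean() < min_expr_frac
                    or (rec_expr[m_tgt] > 0).mean() < min_expr_frac
                )
                if filtered:
                    p = 1.0
                else:
                    null = 0.5 * (
                        lig_expr[perms].T[m_src].mean(axis=0)
                        + rec_expr[perms].T[m_tgt].mean(axis=0)
                    )
                    p = (1 + int(np.sum(null >= obs))) / (1 + n_perm)
                rows.append((lig, rec, src, tgt, float(obs), p, filtered))
    return pd.DataFrame(
        rows,
        columns=["ligand", "receptor", "source", "target",
                 "interaction_mean", "p_value", "filtered"],
    ).assign(n_permutations=n_perm, seed=seed)


def cytotrace_like_score(expr: ExprMatrix, k_smooth: int = 10) -> pd.DataFrame:
    """Per-cell differentiation potential from genes-detected counts.

    Raw value = number of genes with nonzero expression per cell; with
    ``k_smooth > 0`` each cell's value is replaced by the mean over its
    k nearest neighbors (Euclidean distance in the expression matrix,
    the cell itself included).  The score rank-scales the (smoothed)
    values to [0, 1]; higher means less differentiated.
    """
    if k_smooth < 0:
        raise ValueError("k_smooth must be >= 0")
    n_cells = expr.values.shape[1]
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if k_smooth >= n_cells:
        raise ValueError("k_smooth must be smaller than the number of cells")
    genes_detected = (expr.values > 0).sum(axis=0).astype(float)
    if k_smooth > 0:
        nn = NearestNeighbors(n_neighbors=k_smooth).fit(expr.values.T)
        _, idx = nn.kneighbors(expr.values.T)
        smoothed = genes_detected[idx].mean(axis=1)
    else:
        smoothed = genes_detected.copy()
    ranks = stats.rankdata(smoothed, method="average") - 1.0
    score = ranks / (n_cells - 1)
    return pd.DataFrame(
        {
            "genes_detected": genes_detected.astype(int),
            "smoothed": smoothed,
            "score": score,
        },
        index=expr.cell_ids,
    )
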