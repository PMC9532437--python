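"""Transcriptional-program scoring and gene-set enrichment.

Covers the expression-program workflow: select the 2000 most variable
genes among malignant cells, map them to hallmark gene sets with a
hypergeometric overlap test (BH FDR), group the top enriched hallmarks
into programs by hierarchical clustering of their Pearson correlations,
and score each cell as the mean z-scored expression of up to 45 program
genes.  Also provides preranked GSEA (weighted Kolmogorov-Smirnov
enrichment score with gene-set permutation null, NES and FDR) and a
per-cell single-sample GSEA (ssGSEA) score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import ExprMatrix, GeneSetCollection

__all__ = [
    "select_variable_genes",
    "hallmark_enrichment",
    "group_hallmarks",
    "program_score",
    "marker_set_score",
    "gsea_preranked",
    "gsea_collection",
    "ssgsea_cell_score",
]


def select_variable_genes(expr: ExprMatrix, cells=None, n: int = 2000) -> list:
    """Top ``n`` genes by standard deviation over the given cells.

    Ties are broken by gene_id for determinism.  ``cells`` may be a
    boolean mask or a list of cell ids; None uses all cells.
    """
    vals = expr.values
    if cells is not None:
        cells = np.asarray(cells)
        if cells.dtype == bool:
            vals = vals[:, cells]
        else:
            pos = {c: i for i, c in enumerate(expr.cell_ids)}
            vals = vals[:, [pos[c] for c in cells]]
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 cells to compute SD")
    if n > vals.shape[0]:
        raise ValueError(f"n={n} exceeds {vals.shape[0]} genes")
    sd = vals.std(axis=1, ddof=0)
    order = np.lexsort((expr.gene_ids.astype(str), -sd))
    return list(expr.gene_ids[order[:n]])


def hallmark_enrichment(gene_list, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric overlap of ``gene_list`` with each set, BH-corrected.

    ``gene_list`` must be a subset of ``universe``; sets are intersected
    with the universe first, and sets disjoint from it are excluded with
    a warning.  The p-value is the upper tail
    P(overlap >= observed) under sampling |gene_list| genes from the
    universe without replacement.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list)
    stray = gene_list - universe
    if stray:
        raise ValueError(f"gene_list genes outside universe: {sorted(stray)[:5]}")
    M, N = len(universe), len(gene_list)
    rows = []
    for name, members in collection.items():
        in_universe = set(members) & universe
        if not in_universe:
            warnings.warn(f"set {name!r} disjoint from universe; excluded", stacklevel=2)
            continue
        K = len(in_universe)
        overlap = len(gene_list & in_universe)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, N))
        rows.append((name, overlap, M, N, K, p))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "universe_size", "list_size", "set_size", "p_value"]
    )
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["q_value"] = pd.Series(dtype=float)
    return table.sort_values(["p_value", "set"], kind="mergesort").reset_index(drop=True)


def group_hallmarks(score_matrix: pd.DataFrame, n_groups: int = 3) -> dict:
    """Partition hallmark score columns into ``n_groups`` correlated groups.

    Average-linkage hierarchical clustering on distance 1 - Pearson r
    between per-cell hallmark score columns, cut at ``n_groups``.
    Constant columns (undefined correlation) each get their own group,
    with a warning.  Returns {hallmark name -> group index}.
    """
    names = list(score_matrix.columns)
    if len(names) < n_groups:
        raise ValueError(f"need >= {n_groups} hallmarks, got {len(names)}")
    vals = score_matrix.to_numpy(dtype=float)
    constant = vals.std(axis=0) == 0
    groups: dict = {}
    next_group = 0
    if constant.any():
        warnings.warn(
            f"constant hallmark columns get singleton groups: "
            f"{[n for n, c in zip(names, constant) if c]}",
            stacklevel=2,
        )
    ok = [n for n, c in zip(names, constant) if not c]
    n_cluster_groups = max(1, n_groups - int(constant.sum()))
    if ok:
        sub = vals[:, ~constant]
        corr = np.corrcoef(sub.T)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        if len(ok) == 1:
            labels = np.array([1])
        else:
            Z = linkage(squareform(dist, checks=False), method="average")
            labels = fcluster(Z, t=min(n_cluster_groups, len(ok)), criterion="maxclust")
        for name, lab in zip(ok, labels):
            groups[name] = int(lab) - 1
        next_group = int(labels.max())
    for name, c in zip(names, constant):
        if c:
            groups[name] = next_group
            next_group += 1
    return groups


def _zscore_rows(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    ok = sd.ravel() > 0
    z = np.divide(vals - mean, sd, out=np.zeros_like(vals), where=sd > 0)
    return z, ok


def program_score(expr: ExprMatrix, program_genes, top_n: int = 45) -> pd.Series:
    """Mean per-gene z-score over up to ``top_n`` program genes, per cell.

    Each gene is z-scored across all cells; constant genes are dropped
    with a warning; the score averages the first ``top_n`` usable genes
    of the provided list.  Score columns therefore have mean 0 over the
    scored cells.
    """
    idx = expr.gene_index(program_genes)
    vals = expr.values[idx, :]
    z, ok = _zscore_rows(vals)
    if not ok.any():
        raise ValueError("all program genes are constant across cells")
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} constant program genes", stacklevel=2)
    usable = np.flatnonzero(ok)[:top_n]
    return pd.Series(z[usable, :].mean(axis=0), index=expr.cell_ids, name="program_score")


def marker_set_score(expr: ExprMatrix, marker_genes) -> pd.Series:
    """Mean marker expression per cell, min-max scaled to [0, 1].

    Markers absent from the matrix raise; if every cell has the same
    raw mean the score is 0 everywhere (declared degenerate rule).
    """
    idx = expr.gene_index(marker_genes)
    raw = expr.values[idx, :].mean(axis=0)
    lo, hi = raw.min(), raw.max()
    scaled = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return pd.Series(scaled, index=expr.cell_ids, name="marker_score")


def _es_curve(stats_sorted: np.ndarray, in_set: np.ndarray, weight: float) -> np.ndarray:
    """Running enrichment sum for one membership vector over sorted stats."""
    w = np.abs(stats_sorted) ** weight
    hit = np.where(in_set, w, 0.0)
    total = hit.sum()
    if total == 0:  # all in-set stats are zero; fall back to unweighted hits
        hit = in_set.astype(float)
        total = hit.sum()
    miss = (~in_set).astype(float)
    n_miss = miss.sum()
    return np.cumsum(hit / total - miss / n_miss)


def _es_value(curve: np.ndarray) -> float:
    i = int(np.argmax(np.abs(curve)))
    return float(curve[i])


def _null_es(stats_sorted: np.ndarray, set_size: int, n_perm: int, weight: float,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized null ES distribution from random gene-label sets."""
    N = len(stats_sorted)
    w = np.abs(stats_sorted) ** weight
    # membership masks: n_perm x N
    masks = np.zeros((n_perm, N), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(N, size=set_size, replace=False)] = True
    hit = masks * w
    totals = hit.sum(axis=1, keepdims=True)
    degenerate = totals.ravel() == 0
    if degenerate.any():
        hit[degenerate] = masks[degenerate].astype(float)
        totals = hit.sum(axis=1, keepdims=True)
    miss = (~masks).astype(float) / (N - set_size)
    curves = np.cumsum(hit / totals - miss, axis=1)
    idx = np.argmax(np.abs(curves), axis=1)
    return curves[np.arange(n_perm), idx]


def _rank_stats(ranked_stats: dict) -> tuple[np.ndarray, np.ndarray]:
    genes = np.array(list(ranked_stats.keys()), dtype=object)
    vals = np.array([ranked_stats[g] for g in genes], dtype=float)
    order = np.lexsort((genes.astype(str), -vals))
    return genes[order], vals[order]


def _gsea_single(genes_sorted, stats_sorted, gene_set, weight, n_perm, rng) -> dict:
    in_set = np.isin(genes_sorted.astype(str), [str(g) for g in gene_set])
    s = int(in_set.sum())
    if s == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if s == len(genes_sorted):
        raise ValueError("gene set covers the entire ranked list")
    es = _es_value(_es_curve(stats_sorted, in_set, weight))
    null = _null_es(stats_sorted, s, n_perm, weight, rng)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same_sign) == 0:
        p = 1.0 / (n_perm + 1)
        nes = 0.0
    else:
        p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + len(same_sign))
        nes = es / float(np.mean(np.abs(same_sign)))
    return {"es": es, "nes": nes, "p": p, "null": null, "n_overlap": s}


def gsea_preranked(
    ranked_stats: dict,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Preranked GSEA of one gene set.

    Genes are ordered by decreasing statistic (ties by gene_id); the
    running sum takes hit steps proportional to |stat|^weight
    (normalized over the set) and miss steps of 1/(N - |S|); ES is the
    maximum-magnitude deviation.  The null is random gene-label sets of
    the same size; NES divides ES by the mean |null ES| of the same
    sign, and the nominal p uses the same-sign tail with an add-one
    estimator.  With a single set the FDR q equals the nominal p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes_sorted, stats_sorted = _rank_stats(ranked_stats)
    rng = np.random.default_rng(seed)
    res = _gsea_single(genes_sorted, stats_sorted, gene_set, weight, n_perm, rng)
    return pd.Series(
        {
            "es": res["es"],
            "nes": res["nes"],
            "p_value": res["p"],
            "q_value": res["p"],
            "n_overlap": res["n_overlap"],
            "n_permutations": n_perm,
            "seed": seed,
        }
    )


def gsea_collection(
    ranked_stats: dict,
    collection: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection, with NES-based FDR across sets.

    FDR q for a set with NES* is the ratio of the null tail fraction
    {|null NES| >= |NES*|, same sign} to the observed tail fraction,
    clipped to [0, 1] — the canonical preranked procedure.
    """
    genes_sorted, stats_sorted = _rank_stats(ranked_stats)
    rng = np.random.default_rng(seed)
    rows, null_nes_all = [], []
    for name, members in collection.items():
        res = _gsea_single(genes_sorted, stats_sorted, members, weight, n_perm, rng)
        null = res["null"]
        for sign in (1, -1):
            tail = null[np.sign(null) == sign]
            if len(tail):
                null_nes_all.extend(tail / np.mean(np.abs(tail)))
        rows.append((name, res["es"], res["nes"], res["p"], res["n_overlap"]))
    table = pd.DataFrame(rows, columns=["set", "es", "nes", "p_value", "n_overlap"])
    null_nes = np.asarray(null_nes_all)
    obs_nes = table["nes"].to_numpy()
    qs = []
    for nes in obs_nes:
        if nes == 0:
            qs.append(1.0)
            continue
        sign = np.sign(nes)
        null_tail = np.mean((np.sign(null_nes) == sign) & (np.abs(null_nes) >= abs(nes)))
        null_frac = np.mean(np.sign(null_nes) == sign)
        obs_tail = np.mean((np.sign(obs_nes) == sign) & (np.abs(obs_nes) >= abs(nes)))
        obs_frac = np.mean(np.sign(obs_nes) == sign)
        if null_frac == 0 or obs_tail == 0 or obs_frac == 0:
            qs.append(1.0)
        else:
            qs.append(min(1.0, (null_tail / null_frac) / (obs_tail / obs_frac)))
    table["q_value"] = qs
    table["n_permutations"] = n_perm
    table["seed"] = seed
    return table


def ssgsea_cell_score(
    expr: ExprMatrix,
    gene_set,
    alpha: float = 0.25,
    scale: bool = False,
) -> pd.Series:
    """Single-sample GSEA score per cell.

    Per cell, genes are ranked by expression (descending, ties broken
    by gene_id); the score is the sum over rank positions of the
    difference between the weighted in-set ECDF (weights rank^alpha,
    where the top gene has rank N) and the unweighted out-of-set ECDF.
    ``scale=True`` min-max scales scores across cells.
    """
    set_mask = np.isin(expr.gene_ids.astype(str), [str(g) for g in gene_set])
    if not set_mask.any():
        raise ValueError("gene set has no overlap with the matrix")
    if set_mask.all():
        raise ValueError("gene set covers every gene")
    N = len(expr.gene_ids)
    n_out = N - int(set_mask.sum())
    gene_key = expr.gene_ids.astype(str)
    scores = np.empty(expr.values.shape[1])
    ranks = np.arange(N, 0, -1, dtype=float)  # rank N for the top gene
    weights = ranks**alpha
    for j in range(expr.values.shape[1]):
        order = np.lexsort((gene_key, -expr.values[:, j]))
        in_sorted = set_mask[order]
        hit = np.where(in_sorted, weights, 0.0)
        ecdf_in = np.cumsum(hit) / hit.sum()
        ecdf_out = np.cumsum(~in_sorted) / n_out
        scores[j] = float(np.sum(ecdf_in - ecdf_out))
    if scale:
        lo, hi = scores.min(), scores.max()
        scores = np.zeros_like(scores) if hi == lo else (scores - lo) / (hi - lo)
    return pd.Series(scores, index=expr.cell_ids, name="ssgsea")
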