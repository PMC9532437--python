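"""Variable genes, enrichment, program scores, GSEA and ssGSEA tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sclctools import (
    ExprMatrix,
    GeneSetCollection,
    group_hallmarks,
    gsea_preranked,
    hallmark_enrichment,
    marker_set_score,
    program_score,
    select_variable_genes,
    ssgsea_cell_score,
)


def _expr(vals, genes=None, cells=None):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    cells = cells or [f"c{i}" for i in range(vals.shape[1])]
    return ExprMatrix(vals, genes, cells)


# ---------------------------------------------------------------- variable genes

def test_variable_genes_hand_ranking():
    # SDs (population): g0 -> 0, g1 -> ~2.24, g2 -> ~1.12
    expr = _expr([[5, 5, 5, 5], [1, 3, 5, 7], [1, 2, 3, 4]])
    assert select_variable_genes(expr, n=3) == ["g1", "g2", "g0"]
    assert select_variable_genes(expr, n=1) == ["g1"]


def test_variable_genes_requires_two_cells():
    with pytest.raises(ValueError, match="2 cells"):
        select_variable_genes(_expr(np.ones((3, 1))), n=2)


def test_variable_genes_tie_break_by_gene_id():
    expr = _expr([[0, 2], [0, 2], [0, 1]], genes=["zz", "aa", "mm"])
    assert select_variable_genes(expr, n=2) == ["aa", "zz"]


# ------------------------------------------------------------------- enrichment

def _brute_force_hypergeom_p(M, K, N, k_obs):
    """P(overlap >= k_obs) by exhaustive enumeration over C(M, N) draws."""
    universe = range(M)
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, N):
        total += 1
        hits += sum(1 for g in draw if g < K) >= k_obs
    return hits / total


def test_hypergeometric_p_matches_enumeration():
    universe = [f"u{i}" for i in range(10)]
    coll = GeneSetCollection(sets={"S": universe[:5]})
    gene_list = universe[:3] + [universe[7]]  # overlap 3 of list 4
    table = hallmark_enrichment(gene_list, coll, universe)
    expected = _brute_force_hypergeom_p(10, 5, 4, 3)
    assert table.loc[0, "overlap"] == 3
    assert table.loc[0, "p_value"] == pytest.approx(expected, abs=1e-12)


def test_empty_gene_list_gives_p_one():
    universe = [f"u{i}" for i in range(6)]
    coll = GeneSetCollection(sets={"S": universe[:3]})
    table = hallmark_enrichment([], coll, universe)
    assert table.loc[0, "p_value"] == pytest.approx(1.0)


def test_disjoint_set_excluded_with_warning():
    universe = ["a", "b"]
    coll = GeneSetCollection(sets={"S": ["x", "y"], "T": ["a"]})
    with pytest.warns(UserWarning, match="disjoint"):
        table = hallmark_enrichment(["a"], coll, universe)
    assert list(table["set"]) == ["T"]


def test_gene_list_outside_universe_rejected():
    coll = GeneSetCollection(sets={"S": ["a"]})
    with pytest.raises(ValueError, match="outside universe"):
        hallmark_enrichment(["zzz"], coll, ["a", "b"])


# ------------------------------------------------------------- hallmark grouping

def test_identical_columns_share_a_group():
    rng = np.random.default_rng(0)
    base = rng.normal(size=100)
    other = rng.normal(size=100)
    third = rng.normal(size=100)
    scores = pd.DataFrame({"h1": base, "h2": base, "h3": other, "h4": third})
    groups = group_hallmarks(scores, n_groups=3)
    assert groups["h1"] == groups["h2"]
    assert len({groups["h1"], groups["h3"], groups["h4"]}) == 3


def test_planted_three_factor_recovery():
    rng = np.random.default_rng(1)
    factors = rng.normal(size=(200, 3))
    assignment = [0, 0, 0, 1, 1, 1, 2, 2]  # 8 hallmarks from 3 latent factors
    cols = {
        f"h{i}": factors[:, a] + rng.normal(0, 0.1, size=200)
        for i, a in enumerate(assignment)
    }
    groups = group_hallmarks(pd.DataFrame(cols), n_groups=3)
    recovered = {}
    for name, g in groups.items():
        recovered.setdefault(g, set()).add(name)
    expected = [{"h0", "h1", "h2"}, {"h3", "h4", "h5"}, {"h6", "h7"}]
    assert sorted(recovered.values(), key=sorted) == sorted(expected, key=sorted)


def test_constant_hallmark_gets_own_group():
    rng = np.random.default_rng(2)
    scores = pd.DataFrame(
        {"h1": rng.normal(size=50), "h2": rng.normal(size=50), "flat": np.ones(50)}
    )
    with pytest.warns(UserWarning, match="constant"):
        groups = group_hallmarks(scores, n_groups=3)
    assert groups["flat"] not in {groups["h1"], groups["h2"]}


# --------------------------------------------------------------- program scores

def test_single_gene_program_score_is_z_score():
    expr = _expr([[1.0, 2.0, 6.0]])
    score = program_score(expr, ["g0"])
    v = np.array([1.0, 2.0, 6.0])
    z = (v - v.mean()) / v.std()
    np.testing.assert_allclose(score.to_numpy(), z, atol=1e-12)


def test_program_score_hand_arithmetic():
    expr = _expr([[1.0, 2.0, 3.0], [4.0, 4.0, 10.0]])
    score = program_score(expr, ["g0", "g1"])
    z0 = (np.array([1, 2, 3]) - 2) / np.std([1, 2, 3])
    z1 = (np.array([4, 4, 10]) - 6) / np.std([4, 4, 10])
    np.testing.assert_allclose(score.to_numpy(), (z0 + z1) / 2, atol=1e-12)


def test_program_score_mean_zero_and_affine_invariant():
    rng = np.random.default_rng(3)
    vals = rng.lognormal(size=(10, 30))
    expr = _expr(vals)
    genes = [f"g{i}" for i in range(10)]
    s1 = program_score(expr, genes)
    assert abs(s1.mean()) < 1e-9
    # per-gene affine transform is absorbed by the z-scoring
    scale = rng.uniform(0.5, 2.0, size=(10, 1))
    shift = rng.normal(size=(10, 1))
    s2 = program_score(_expr(vals * scale + shift), genes)
    np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)


def test_program_score_top_n_truncates():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=(5, 20))
    expr = _expr(vals)
    s = program_score(expr, [f"g{i}" for i in range(5)], top_n=2)
    s_direct = program_score(expr, ["g0", "g1"])
    np.testing.assert_allclose(s.to_numpy(), s_direct.to_numpy(), atol=1e-12)


def test_all_constant_program_raises():
    with pytest.raises(ValueError, match="constant"):
        program_score(_expr(np.ones((2, 4))), ["g0", "g1"])


def test_marker_set_score_min_max_and_degenerate():
    expr = _expr([[2.0, 4.0, 6.0]])
    np.testing.assert_allclose(marker_set_score(expr, ["g0"]).to_numpy(), [0, 0.5, 1])
    flat = marker_set_score(_expr(np.ones((2, 3))), ["g0", "g1"])
    np.testing.assert_allclose(flat.to_numpy(), [0, 0, 0])
    rng = np.random.default_rng(5)
    s = marker_set_score(_expr(rng.lognormal(size=(4, 25))), ["g0", "g3"])
    assert (s >= 0).all() and (s <= 1).all()


# ------------------------------------------------------------------------- GSEA

def brute_force_es(genes_ranked, stats_ranked, gene_set, weight):
    """Independent running-sum ES computation."""
    in_set = [g in set(gene_set) for g in genes_ranked]
    n_out = sum(1 for f in in_set if not f)
    denom = sum(abs(s) ** weight for g, s, f in zip(genes_ranked, stats_ranked, in_set) if f)
    running, best = 0.0, 0.0
    for g, s, f in zip(genes_ranked, stats_ranked, in_set):
        running += (abs(s) ** weight / denom) if f else (-1.0 / n_out)
        if abs(running) > abs(best):
            best = running
    return best


def test_es_top_genes_weight_zero_hand_value():
    """Set = top 2 genes of 10, weight 0: the running sum peaks at
    2 * (1/2) - 0 = 1 after the second gene."""
    stats = {f"g{i}": 10.0 - i for i in range(10)}
    res = gsea_preranked(stats, ["g0", "g1"], weight=0.0, n_perm=10, seed=0)
    assert res["es"] == pytest.approx(1.0)


@pytest.mark.parametrize("weight", [0.0, 1.0])
def test_es_matches_brute_force(weight):
    stats = {"a": 3.0, "b": 2.0, "c": -1.0, "d": -2.5, "e": 0.5}
    gene_set = ["b", "d"]
    ranked = sorted(stats, key=lambda g: (-stats[g], g))
    expected = brute_force_es(ranked, [stats[g] for g in ranked], gene_set, weight)
    res = gsea_preranked(stats, gene_set, weight=weight, n_perm=10, seed=0)
    assert res["es"] == pytest.approx(expected, abs=1e-12)


def test_es_invariant_under_monotone_transform_at_weight_zero():
    rng = np.random.default_rng(6)
    genes = [f"g{i}" for i in range(50)]
    vals = rng.normal(size=50)
    stats1 = dict(zip(genes, vals))
    stats2 = dict(zip(genes, np.exp(vals)))  # rank-preserving
    gene_set = genes[::7]
    r1 = gsea_preranked(stats1, gene_set, weight=0.0, n_perm=5, seed=1)
    r2 = gsea_preranked(stats2, gene_set, weight=0.0, n_perm=5, seed=1)
    assert r1["es"] == pytest.approx(r2["es"], abs=1e-12)


def test_gsea_result_invariants():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(100)]
    stats = dict(zip(genes, rng.normal(size=100)))
    res = gsea_preranked(stats, genes[:10], n_perm=200, seed=2)
    assert np.sign(res["nes"]) == np.sign(res["es"]) or res["nes"] == 0
    assert res["p_value"] >= 1.0 / (200 + 1)
    assert 0 <= res["q_value"] <= 1
    assert -1.0 - 1e-12 <= res["es"] <= 1.0 + 1e-12


def test_gsea_no_overlap_raises():
    with pytest.raises(ValueError, match="no overlap"):
        gsea_preranked({"a": 1.0, "b": 0.5}, ["zzz"], n_perm=5, seed=0)


# ----------------------------------------------------------------------- ssGSEA

def test_ssgsea_set_expressors_score_higher():
    genes = ["s1", "s2", "o1", "o2"]
    # cell 0 expresses only set genes, cell 1 only non-set genes
    expr = _expr([[5, 0], [4, 0], [0, 5], [0, 4]], genes=genes)
    scores = ssgsea_cell_score(expr, ["s1", "s2"])
    assert scores.iloc[0] > scores.iloc[1]


def test_ssgsea_hand_computed_alpha_zero():
    # ranking for the cell: a(4) > b(3) > c(2) > d(1); set = {a, c}
    # ECDF_in  = 1/2, 1/2, 1, 1 ; ECDF_out = 0, 1/2, 1/2, 1
    # sum of differences = .5 + 0 + .5 + 0 = 1
    expr = _expr([[4.0], [3.0], [2.0], [1.0]], genes=["a", "b", "c", "d"])
    s = ssgsea_cell_score(expr, ["a", "c"], alpha=0.0)
    assert s.iloc[0] == pytest.approx(1.0)


def test_ssgsea_rank_invariance_per_cell():
    rng = np.random.default_rng(8)
    vals = rng.lognormal(size=(30, 4))
    genes = [f"g{i}" for i in range(30)]
    s1 = ssgsea_cell_score(_expr(vals, genes=genes), genes[:6])
    s2 = ssgsea_cell_score(_expr(np.log1p(vals), genes=genes), genes[:6])
    np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)
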