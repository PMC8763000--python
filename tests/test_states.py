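import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import somcell
from somcell.prep import ExpressionMatrix
from somcell.states import (
    GeneSet,
    alpha_diversity,
    cluster_portraits,
    compare_groups,
    composition,
    diversity,
    load_gene_sets,
    score_signature,
)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def test_entropy_reference_values():
    assert alpha_diversity([1.0, 0.0, 0.0]) == 0.0
    assert alpha_diversity([0.25] * 4) == pytest.approx(np.log(4), abs=1e-12)
    # direct summation: -(0.5 ln 0.5 + 0.3 ln 0.3 + 0.2 ln 0.2)
    assert alpha_diversity([0.5, 0.3, 0.2]) == pytest.approx(1.0297, abs=5e-5)


def test_entropy_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        alpha_diversity([-0.1, 1.1])
    with pytest.raises(ValueError):
        alpha_diversity([0.5, 0.3])


@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=10))
def test_entropy_bounds_and_permutation_invariance(weights):
    p = np.array(weights) / sum(weights)
    h = alpha_diversity(p)
    assert 0.0 <= h <= np.log(len(p)) + 1e-12
    assert alpha_diversity(p[::-1]) == pytest.approx(h, abs=1e-12)


@given(st.integers(2, 8), st.integers(0, 10_000))
def test_uniform_is_the_strict_entropy_maximum(n, seed):
    uniform = np.full(n, 1.0 / n)
    rng = np.random.default_rng(seed)
    delta = rng.normal(0, 0.05, n)
    delta -= delta.mean()
    perturbed = np.clip(uniform + delta, 1e-9, None)
    perturbed /= perturbed.sum()
    if not np.allclose(perturbed, uniform):
        assert alpha_diversity(perturbed) < alpha_diversity(uniform)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_composition_matches_hand_tally():
    states = np.array(["C1", "C1", "C2", "C3", "C1", "C2",
                       "C3", "C3", "C1", "C2", "C1", "C1"])
    groups = np.array(["S", "RV", "S", "S", "RV", "RV",
                       "RV", "S", "S", "S", "RV", "S"])
    table = composition(states, groups)
    assert table.counts.loc["C1", "S"] == 3
    assert table.counts.loc["C1", "RV"] == 3
    assert table.counts.loc["C2", "S"] == 2
    assert table.counts.loc["C2", "RV"] == 1
    assert table.counts.loc["C3", "S"] == 2
    assert table.counts.loc["C3", "RV"] == 1
    assert table.n_cells == 12
    # fractions re-derive counts exactly
    re_counts = table.row_fractions.mul(table.counts.sum(axis=1), axis=0)
    np.testing.assert_allclose(re_counts.to_numpy(), table.counts.to_numpy())
    assert np.allclose(table.row_fractions.sum(axis=1), 1.0)
    assert np.allclose(table.col_fractions.sum(axis=0), 1.0)


def test_single_state_row_fractions_equal_group_sizes():
    states = np.array(["C1"] * 10)
    groups = np.array(["A"] * 4 + ["B"] * 6)
    table = composition(states, groups)
    assert table.row_fractions.loc["C1", "A"] == pytest.approx(0.4)
    assert table.row_fractions.loc["C1", "B"] == pytest.approx(0.6)


def test_diversity_per_group_and_state(tiny_dataset, tiny_model):
    assign = cluster_portraits(tiny_model, k=3)
    table = composition(assign, tiny_dataset.cell_groups)
    div = diversity(table)
    assert set(div.per_group.index) == {"A", "B"}
    assert ((div.per_group >= 0) & (div.per_group <= np.log(assign.k))).all()
    assert ((div.per_state >= 0) & (div.per_state <= np.log(2))).all()


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_two_cells_two_clusters(tiny_model):
    assign = cluster_portraits(tiny_model, cells=[0, 1], k=2)
    assert assign.k == 2
    assert assign.labels[0] != assign.labels[1]


def test_k_larger_than_cells_rejected(tiny_model):
    with pytest.raises(ValueError):
        cluster_portraits(tiny_model, cells=[0, 1], k=5)


def test_planted_programs_recovered(tiny_model, tiny_dataset):
    from sklearn.metrics import adjusted_rand_score

    assign = cluster_portraits(tiny_model, k="auto", k_range=(2, 6))
    assert assign.k == tiny_dataset.config.n_programs
    assert adjusted_rand_score(tiny_dataset.true_program, assign.labels) >= 0.9
    # C1 is the largest state
    sizes = [np.sum(assign.labels == f"C{i+1}") for i in range(assign.k)]
    assert sizes == sorted(sizes, reverse=True)


def test_duplicating_cells_keeps_cluster_count(tiny_model):
    assign = cluster_portraits(tiny_model, k="auto", k_range=(2, 6))
    doubled = np.concatenate([np.arange(tiny_model.n_cells),
                              np.arange(tiny_model.n_cells)])
    assign2 = cluster_portraits(tiny_model, cells=doubled, k="auto", k_range=(2, 6))
    assert assign2.k == assign.k


def test_kmeans_fallback_is_deterministic(tiny_model):
    a = cluster_portraits(tiny_model, k=3, method="kmeans", seed=1)
    b = cluster_portraits(tiny_model, k=3, method="kmeans", seed=1)
    np.testing.assert_array_equal(a.labels, b.labels)


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

def test_single_gene_signature_equals_gene_column(tiny_logc):
    gene = tiny_logc.gene_ids[5]
    score = score_signature(tiny_logc, GeneSet("one", [gene]))
    np.testing.assert_allclose(score, tiny_logc.values[:, 5])


def test_union_score_is_size_weighted_mean(tiny_logc):
    g = list(tiny_logc.gene_ids)
    s1, s2 = GeneSet("a", g[:4]), GeneSet("b", g[4:10])
    su = GeneSet("u", g[:10])
    score_u = score_signature(tiny_logc, su)
    expected = (4 * score_signature(tiny_logc, s1) + 6 * score_signature(tiny_logc, s2)) / 10
    np.testing.assert_allclose(score_u, expected, atol=1e-12)


def test_planted_set_scores_higher_in_its_state(tiny_logc, tiny_dataset):
    sets = {name: genes for name, genes in
            tiny_dataset.program_gene_sets().items()}
    gs = GeneSet("program_1", sets["program_1"])
    score = score_signature(tiny_logc, gs)
    own = score[tiny_dataset.true_program == 1].mean()
    other = score[tiny_dataset.true_program != 1].mean()
    assert own - other > 1.0


def test_missing_genes_warned_and_empty_overlap_rejected(tiny_logc, caplog):
    import logging

    gs = GeneSet("partial", [tiny_logc.gene_ids[0], "NOT_A_GENE"])
    with caplog.at_level(logging.WARNING, logger="somcell.states"):
        score = score_signature(tiny_logc, gs)
    np.testing.assert_allclose(score, tiny_logc.values[:, 0])
    assert any("absent" in r.message for r in caplog.records)
    with pytest.raises(ValueError):
        score_signature(tiny_logc, GeneSet("none", ["X1", "X2"]))


def test_gmt_round_trip(tmp_path, tiny_dataset):
    from somcell.states import read_gmt, write_gmt

    sets = tiny_dataset.program_gene_sets()
    write_gmt(sets, tmp_path / "sets.gmt")
    back = read_gmt(tmp_path / "sets.gmt")
    assert back == {k: list(v) for k, v in sets.items()}
    loaded = load_gene_sets(tmp_path / "sets.gmt")
    assert [gs.name for gs in loaded] == list(sets)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def test_anova_f_matches_hand_computation():
    # 3 groups x 4 observations; SS decomposition by hand:
    # means 2, 4, 6; grand mean 4; SSB = 4*(4+0+4) = 32
    # within each group deviations (-1, 0, 0, 1) -> SSW = 2 per group = 6
    # F = (32/2) / (6/9) = 24
    scores = np.array([1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7], dtype=float)
    labels = np.repeat(["a", "b", "c"], 4)
    res = compare_groups(scores, labels)
    assert res.f_statistic == pytest.approx(24.0, rel=1e-10)
    assert res.p_value < 0.05


def test_null_groups_not_significant():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=300)
    labels = np.repeat(["a", "b", "c"], 100)
    res = compare_groups(scores, labels)
    assert res.p_value > 0.05
    assert not res.pairwise["significant"].any()


def test_extreme_shift_is_significant():
    rng = np.random.default_rng(1)
    scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
    labels = np.repeat(["a", "b"], 50)
    res = compare_groups(scores, labels)
    assert res.p_value < 1e-10
    assert res.pairwise["significant"].all()


def test_compare_groups_input_validation():
    with pytest.raises(ValueError):
        compare_groups(np.ones(3), np.array(["a", "a", "b"]))
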