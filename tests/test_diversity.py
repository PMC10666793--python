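import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import TreeNode

from biocrustdiv.diversity import (
    alpha_table,
    beta_matrix,
    bray_curtis,
    faith_pd,
    pairwise_beta,
    pielou,
    richness,
    shannon,
    sorensen_partition,
    weighted_unifrac,
)
from biocrustdiv.io import FeatureTable, ParameterError
from biocrustdiv.simulate import SimParams, simulate_metacommunity, simulate_tree
from conftest import make_meta, SMALL_SIM


def subtree_oracle_pd(abund, taxa, tree):
    """Brute-force Faith PD: sum lengths of edges with any observed tip
    below, by explicit per-edge tip enumeration."""
    observed = {t for t, v in zip(taxa, abund) if v > 0}
    total = 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips()} | ({node.name} if node.is_tip() else set())
        if below & observed:
            total += node.length
    return total


def edge_oracle_unifrac(x, y, taxa, tree, normalized=False):
    """Brute-force weighted UniFrac by explicit edge enumeration."""
    px = {t: v / sum(x) for t, v in zip(taxa, x)}
    py = {t: v / sum(y) for t, v in zip(taxa, y)}
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips()} | ({node.name} if node.is_tip() else set())
        ax = sum(px.get(t, 0.0) for t in below)
        ay = sum(py.get(t, 0.0) for t in below)
        num += node.length * abs(ax - ay)
        den += node.length * (ax + ay)
    return num / den if normalized else num


class TestAlpha:
    @pytest.mark.parametrize("vec,expected", [
        ([10, 10, 10, 10], np.log(4)),
        ([5, 0, 0], 0.0),
        ([4, 2, 2], 1.039721),
    ])
    def test_shannon(self, vec, expected):
        assert shannon(vec) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("vec,expected", [
        ([3, 3, 3], 1.0),
        ([4, 2, 2], 1.039721 / np.log(3)),
    ])
    def test_pielou(self, vec, expected):
        assert pielou(vec) == pytest.approx(expected, abs=1e-6)

    def test_pielou_single_taxon_undefined(self):
        assert np.isnan(pielou([7, 0]))

    def test_all_zero_rejected(self):
        for fn in (shannon, pielou, richness):
            with pytest.raises(ParameterError):
                fn([0, 0, 0])

    def test_faith_pd_star_counts_observed_tips(self, star_tree):
        taxa = ["A", "B", "C", "D"]
        assert faith_pd([1, 1, 1, 1], taxa, star_tree) == pytest.approx(4.0)
        assert faith_pd([1, 1, 0, 0], taxa, star_tree) == pytest.approx(2.0)

    def test_faith_pd_cherry_hand_sum(self, cherry_tree):
        assert faith_pd([1, 1, 0], ["A", "B", "C"], cherry_tree) == pytest.approx(3.0)

    def test_faith_pd_missing_taxon_listed(self, cherry_tree):
        with pytest.raises(Exception, match="ghost"):
            faith_pd([1, 1], ["A", "ghost"], cherry_tree)


class TestBetaMetrics:
    def test_bray_curtis_limits(self):
        assert bray_curtis([3, 1, 2], [3, 1, 2]) == pytest.approx(0.0)
        assert bray_curtis([1, 0], [0, 5]) == pytest.approx(1.0)
        assert bray_curtis([6, 2, 0], [2, 2, 4]) == pytest.approx(0.5)

    def test_unifrac_identity_and_star_l1(self, star_tree):
        taxa = ["A", "B", "C", "D"]
        assert weighted_unifrac([1, 2, 3, 4], [1, 2, 3, 4], taxa, star_tree) == 0.0
        # star tree with unit branches: raw form is the L1 distance of
        # the proportion vectors
        assert weighted_unifrac([1, 0, 0, 0], [0, 1, 0, 0], taxa, star_tree) == pytest.approx(2.0)

    def test_oracle_agreement_random_trees(self):
        rng = np.random.default_rng(1)
        taxa = [f"sp{i:04d}" for i in range(8)]
        for seed in range(10):
            tree = simulate_tree(8, seed=seed)
            x = rng.integers(0, 20, 8) + (rng.random(8) < 0.5)
            y = rng.integers(0, 20, 8) + (rng.random(8) < 0.5)
            x[0] += 1
            y[-1] += 1
            assert faith_pd(x, taxa, tree) == pytest.approx(
                subtree_oracle_pd(x, taxa, tree), abs=1e-10)
            for norm in (False, True):
                assert weighted_unifrac(x, y, taxa, tree, normalized=norm) == pytest.approx(
                    edge_oracle_unifrac(x, y, taxa, tree, normalized=norm), abs=1e-10)

    def test_normalized_unifrac_bounded(self):
        rng = np.random.default_rng(2)
        tree = simulate_tree(12, seed=3)
        taxa = [f"sp{i:04d}" for i in range(12)]
        for _ in range(25):
            x = rng.integers(1, 30, 12)
            y = rng.integers(1, 30, 12)
            d = weighted_unifrac(x, y, taxa, tree, normalized=True)
            assert 0.0 <= d <= 1.0


@given(
    x=st.lists(st.booleans(), min_size=1, max_size=40),
    y=st.lists(st.booleans(), min_size=1, max_size=40),
)
@settings(deadline=None, derandomize=True, max_examples=200)
def test_sorensen_partition_invariants_property(x, y):
    """For any presence pair: components bounded, partition additive,
    counts consistent with the vectors."""
    n = max(len(x), len(y))
    x = x + [False] * (n - len(x))
    y = y + [False] * (n - len(y))
    if not any(x) or not any(y):
        return
    p = sorensen_partition(x, y)
    assert p.a + p.b == sum(x)
    assert p.a + p.c == sum(y)
    assert 0 <= p.beta_sim <= p.beta_sor <= 1
    assert p.beta_sor == pytest.approx(p.beta_sim + p.beta_nes, abs=1e-12)


class TestSorensenPartition:
    def test_identical_vectors(self):
        p = sorensen_partition([1, 1, 0], [1, 1, 0])
        assert p.beta_sor == p.beta_sim == p.beta_nes == 0
        assert np.isnan(p.turnover_ratio)

    def test_worked_values(self):
        x = [True] * 5 + [True] * 3 + [False] * 2
        y = [True] * 5 + [False] * 3 + [True] * 2
        p = sorensen_partition(x, y)
        assert (p.a, p.b, p.c) == (5, 3, 2)
        assert p.beta_sor == pytest.approx(0.33333, abs=1e-5)
        assert p.beta_sim == pytest.approx(0.28571, abs=1e-5)
        assert p.beta_nes == pytest.approx(0.04762, abs=1e-5)

    def test_perfect_nestedness(self):
        x = [True] * 4 + [False] * 3
        y = [True] * 4 + [True] * 3
        p = sorensen_partition(x, y)
        assert p.beta_sim == 0
        assert p.beta_nes == p.beta_sor == pytest.approx(3 / 11)

    def test_additivity_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.random(30) < 0.5
            y = rng.random(30) < 0.5
            if not x.any() or not y.any():
                continue
            p = sorensen_partition(x, y)
            assert p.beta_sor == pytest.approx(p.beta_sim + p.beta_nes, abs=0)
            assert 0 <= p.beta_sim <= p.beta_sor <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            sorensen_partition([False, False], [True, False])


class TestPairwiseBeta:
    def test_local_pair_count(self):
        meta = make_meta(n_sites=1, reps=4, stages=("A",))
        table = FeatureTable(pd.DataFrame(
            np.arange(1, 13).reshape(4, 3), index=meta.sample_ids))
        pb = pairwise_beta(table, meta, scale="local")
        assert len(pb) == 6  # C(4,2) among the four parallel replicates

    def test_continental_pairs_cross_site_only(self):
        meta = make_meta(n_sites=2, reps=4, stages=("A",))
        table = FeatureTable(pd.DataFrame(
            np.arange(1, 25).reshape(8, 3), index=meta.sample_ids))
        pb = pairwise_beta(table, meta, scale="continental")
        assert len(pb) == 16  # 4 x 4 cross-site pairs
        assert (pb["distance_km"] == 100.0).all()

    def test_small_cell_skipped_with_warning(self):
        meta = make_meta(n_sites=1, reps=1, stages=("A", "C", "M"))
        table = FeatureTable(pd.DataFrame(
            np.arange(1, 10).reshape(3, 3), index=meta.sample_ids))
        with pytest.warns(UserWarning, match="<2 samples"):
            pb = pairwise_beta(table, meta, scale="local")
        assert pb.empty

    def test_convergence_reduces_within_stage_beta(self):
        table, meta, _ = simulate_metacommunity(SimParams(seed=11, **SMALL_SIM))
        for scale in ("local", "continental"):
            pb = pairwise_beta(table, meta, scale=scale)
            means = pb.groupby("stage", observed=True)["value"].mean()
            assert means["M"] < means["A"]


def test_alpha_table_columns(small_table, star_tree):
    table = FeatureTable(small_table.data.rename(
        columns={"t1": "A", "t2": "B", "t3": "C"}))
    at = alpha_table(table, star_tree)
    assert list(at.columns) == ["shannon", "richness", "pielou", "faith_pd"]
    assert at.loc["s3", "richness"] == 3


def test_beta_matrix_symmetric_zero_diagonal(small_table):
    dm = beta_matrix(small_table)
    assert np.allclose(dm.data, dm.data.T)
    assert np.all(np.diag(dm.data) == 0)
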