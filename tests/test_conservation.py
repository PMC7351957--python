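"""Stage-combination scoring: expdist, tree traversal, Ptop, Friedman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import friedmanchisquare, spearmanr

from phylostage import (
    SimulationConfig,
    SpeciesTree,
    UndefinedCorrelationError,
    CombinationCapError,
    combination_distance,
    expdist,
    friedman_test,
    pairwise_stage_matrix,
    ptop_from_scores,
    ptop_with_bri,
    score_all_combinations,
    simulate_expression_dataset,
)

from conftest import make_table


class TestExpdist:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 0.0),        # monotone transform, rho = 1
            ([1, 2, 3], [3, 2, 1], 2.0),        # perfect rank inversion
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.2),  # rho = 0.8
        ],
    )
    def test_unit_identities(self, x, y, expected):
        assert expdist(x, y) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scipy_spearman(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x, y = rng.random(40), rng.random(40)
            rho, _ = spearmanr(x, y)
            assert expdist(x, y) == pytest.approx(1.0 - rho, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(20), rng.random(20)
        assert expdist(x, y) == pytest.approx(expdist(y, x), abs=1e-15)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0.1, 1e4), min_size=4, max_size=30, unique=True),
           st.floats(0.5, 3.0), st.floats(0.0, 5.0))
    def test_monotone_transform_invariance(self, x, power, shift):
        rng = np.random.default_rng(len(x))
        y = rng.permutation(len(x)).astype(float)
        x = np.array(x)
        assert expdist(x, y) == pytest.approx(
            expdist(x**power + shift, y), abs=1e-9
        )

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            expdist([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            expdist([1, 2, 3], [1, 2, 3, 4])


class TestCombinationDistance:
    def test_identical_vectors_give_zero(self, default_tree):
        v = np.array([5.0, 1.0, 3.0, 2.0])
        vecs = {sp: {"s": v} for sp in default_tree.leaves}
        score = combination_distance({sp: "s" for sp in default_tree.leaves},
                                     default_tree, vecs)
        assert score.expdist_total == pytest.approx(0.0, abs=1e-12)

    def test_two_species_reduces_to_pairwise(self):
        tree = SpeciesTree.from_newick("(A:1,B:1);")
        rng = np.random.default_rng(3)
        x, y = rng.random(15), rng.random(15)
        score = combination_distance({"A": "s", "B": "s"}, tree,
                                     {"A": {"s": x}, "B": {"s": y}})
        assert score.expdist_total == pytest.approx(expdist(x, y), abs=1e-12)

    def test_hand_traversal_example(self):
        # (A,(B,C)): node BC gives rho=0.8 -> 0.2; root compares A against
        # the BC mean profile [1,2.5,2.5,4] with ranks [1,2.5,2.5,4]:
        # rho = -4.5/sqrt(22.5) -> total = 0.2 + 1 + 4.5/sqrt(22.5)
        tree = SpeciesTree.from_newick("(A:1,(B:1,C:1):1);")
        vecs = {
            "A": {"s": np.array([4.0, 3.0, 2.0, 1.0])},
            "B": {"s": np.array([1.0, 2.0, 3.0, 4.0])},
            "C": {"s": np.array([1.0, 3.0, 2.0, 4.0])},
        }
        score = combination_distance({sp: "s" for sp in "ABC"}, tree, vecs)
        assert score.expdist_total == pytest.approx(0.2 + 1 + 4.5 / np.sqrt(22.5),
                                                    abs=1e-12)


class TestScoreAllCombinations:
    def _vectors(self, tree, n_stages, n_groups=8, seed=0):
        rng = np.random.default_rng(seed)
        return {
            sp: {f"s{i}": rng.random(n_groups) for i in range(n_stages)}
            for sp in tree.leaves
        }

    def test_product_counts(self):
        tree2 = SpeciesTree.from_newick("(A,B);")
        assert len(score_all_combinations(tree2, self._vectors(tree2, 4))) == 16
        tree4 = SpeciesTree.from_newick("(A,(B,(C,D)));")
        assert len(score_all_combinations(tree4, self._vectors(tree4, 10))) == 10_000

    def test_matches_single_combination_path(self, default_tree):
        vecs = self._vectors(default_tree, 3, seed=5)
        for score in score_all_combinations(default_tree, vecs):
            redo = combination_distance(score.combination, default_tree, vecs)
            assert score.expdist_total == pytest.approx(redo.expdist_total, abs=1e-12)

    def test_lexicographic_enumeration(self):
        tree = SpeciesTree.from_newick("(A,B);")
        vecs = self._vectors(tree, 2)
        combos = [tuple(s.combination.values()) for s in score_all_combinations(tree, vecs)]
        assert combos == [("s0", "s0"), ("s0", "s1"), ("s1", "s0"), ("s1", "s1")]

    def test_cap_enforced(self):
        tree = SpeciesTree.from_newick("(A,B);")
        with pytest.raises(CombinationCapError):
            score_all_combinations(tree, self._vectors(tree, 4), cap=10)


class TestPtop:
    def test_sum_law_and_top_set(self):
        tree = SpeciesTree.from_newick("(A,B);")
        rng = np.random.default_rng(2)
        vecs = {sp: {f"s{i}": rng.random(10) for i in range(4)} for sp in "AB"}
        scores = score_all_combinations(tree, vecs)
        ptop = ptop_from_scores(scores, q=0.01)
        # 16 combinations, q=0.01 -> n_top=1: the single best combination's
        # stages get 100, everything else 0
        best = min(scores, key=lambda s: s.expdist_total)
        for sp in "AB":
            assert ptop[sp].sum() == pytest.approx(100.0, abs=1e-9)
            assert ptop[sp][best.combination[sp]] == 100.0
            assert sorted(ptop[sp])[-2] == 0.0

    def test_ptop_with_bri_single_replicate_sd_zero(self):
        tables = [make_table(sp, [f"g{i}" for i in range(12)], ["s0", "s1", "s2"], ["r1"],
                             seed=i) for i, sp in enumerate("AB")]
        tree = SpeciesTree.from_newick("(A,B);")
        res = ptop_with_bri(tables, tree, B=10, q=0.2, seed=0)
        for sp in "AB":
            assert (res.sd[sp] == 0.0).all()

    def test_ptop_with_bri_seed_determinism(self):
        tables = [make_table(sp, [f"g{i}" for i in range(12)], ["s0", "s1"], ["r1", "r2"],
                             seed=i) for i, sp in enumerate("AB")]
        tree = SpeciesTree.from_newick("(A,B);")
        a = ptop_with_bri(tables, tree, B=12, q=0.25, seed=9)
        b = ptop_with_bri(tables, tree, B=12, q=0.25, seed=9)
        for sp in "AB":
            pd.testing.assert_frame_equal(a.matrices[sp], b.matrices[sp])

    def test_hourglass_argmax_recovers_conserved_window(self, small_config, default_tree):
        tables, truth = simulate_expression_dataset(small_config)
        res = ptop_with_bri(list(tables.values()), default_tree, B=20, q=0.01, seed=1)
        for sp in res.level:
            assert res.mean[sp].idxmax() in truth.true_conserved_stages[sp]

    def test_ptop_sums_to_100_per_bri_table(self, small_config, default_tree):
        tables, _ = simulate_expression_dataset(small_config)
        res = ptop_with_bri(list(tables.values()), default_tree, B=10, q=0.01, seed=2)
        for sp in res.level:
            sums = res.matrices[sp].sum(axis=1).to_numpy()
            np.testing.assert_allclose(sums, 100.0, atol=1e-9)


class TestFriedman:
    def test_identical_treatments_give_zero(self):
        m = np.tile([3.0, 3.0, 3.0], (4, 1))
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.degenerate

    def test_worked_value(self):
        # both blocks ranked 1<2<3: sum Rj^2 = 4+16+36 = 56 ->
        # 12/(2*3*4)*56 - 3*2*4 = 4
        res = friedman_test(np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]]))
        assert res.statistic == pytest.approx(4.0, abs=1e-12)
        assert res.df == 2

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        m = rng.random((6, 4))
        a = friedman_test(m)
        b = friedman_test(np.exp(3.0 * m))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(8)
        m = rng.integers(0, 5, size=(12, 5)).astype(float)  # many ties
        ours = friedman_test(m)
        ref = friedmanchisquare(*[m[:, j] for j in range(5)])
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-10)


class TestPairwiseStageMatrix:
    def test_self_comparison_zero_diagonal(self):
        t = make_table("A", [f"g{i}" for i in range(10)], ["s0", "s1", "s2"], ["r1", "r2"])
        m = pairwise_stage_matrix(t, t)
        np.testing.assert_allclose(np.diag(m.to_numpy()), 0.0, atol=1e-12)

    def test_transpose_identity(self):
        ta = make_table("A", [f"g{i}" for i in range(10)], ["s0", "s1"], ["r1"], seed=1)
        tb = make_table("B", [f"g{i}" for i in range(10)], ["u0", "u1", "u2"], ["r1"], seed=2)
        m_ab = pairwise_stage_matrix(ta, tb)
        m_ba = pairwise_stage_matrix(tb, ta)
        np.testing.assert_allclose(m_ab.to_numpy(), m_ba.to_numpy().T, atol=1e-12)

    def test_matches_scalar_expdist(self):
        ta = make_table("A", [f"g{i}" for i in range(8)], ["s0", "s1"], ["r1", "r2"], seed=3)
        tb = make_table("B", [f"g{i}" for i in range(8)], ["u0", "u1"], ["r1"], seed=4)
        m = pairwise_stage_matrix(ta, tb)
        for sa in ta.stages:
            for sb in tb.stages:
                assert m.loc[sa, sb] == pytest.approx(
                    expdist(ta.stage_mean(sa), tb.stage_mean(sb)), abs=1e-12
                )
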