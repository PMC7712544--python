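import itertools
import math

import numpy as np
import pytest
from scipy import stats
from hypothesis import given, settings
from hypothesis import strategies as st

from epiforest import (bh_adjust, fisher_combine, pair_cooccurrence,
                       paired_selection_test, screen_pairs,
                       selection_asymmetry_test, train_forest)
from epiforest.epistasis import (DIRECTION_EPISTASIS, DIRECTION_LD,
                                 asymmetry_test, directional_asymmetry_counts)
from epiforest.forest import ForestModel, Tree


def make_tree(feature, threshold, left, right, oob=()):
    """Hand-built tree; counts are dummies consistent in length."""
    n = len(feature)
    return Tree(feature=np.array(feature, dtype=np.int32),
                threshold=np.array(threshold, dtype=np.float32),
                left=np.array(left, dtype=np.int32),
                right=np.array(right, dtype=np.int32),
                n_node=np.ones(n), case_count=np.ones(n) * 0.5,
                ctrl_count=np.ones(n) * 0.5,
                oob_idx=np.array(oob, dtype=np.int32))


def forest_from_trees(trees, n_features):
    return ForestModel(trees=trees, n_features=n_features, n_subjects=10,
                       mtry_fraction=1 / 3, min_node_fraction=0.1,
                       class_sampling_weights=(0.1, 0.1), seed=0)


def stump(f):
    """Single split on feature f with two leaves."""
    return make_tree([f, -1, -1], [0.5, 0, 0], [1, -1, -1], [2, -1, -1])


def chain(f_top, f_left):
    """f_top at root; f_left splits the left daughter."""
    return make_tree([f_top, f_left, -1, -1, -1], [0.5, 0.5, 0, 0, 0],
                     [1, 3, -1, -1, -1], [2, 4, -1, -1, -1])


def chain_right(f_top, f_right):
    return make_tree([f_top, -1, f_right, -1, -1], [0.5, 0, 0.5, 0, 0],
                     [1, -1, 3, -1, -1], [2, -1, 4, -1, -1])


class TestPairCooccurrence:
    def test_counting_example(self):
        # trees with feature sets {A,B}, {A}, {B} -> t_AB=1, p_A=p_B=2/3
        forest = forest_from_trees([chain(0, 1), stump(0), stump(1)], 2)
        t, p, N = pair_cooccurrence(forest, [0, 1])
        assert t[0, 1] == 1
        assert p[0] == pytest.approx(2 / 3)
        assert p[1] == pytest.approx(2 / 3)
        assert N == 3

    def test_feature_counted_once_per_tree(self):
        # same feature in two nodes of one tree counts once
        tree = make_tree([0, 0, -1, -1, -1], [0.5, 1.5, 0, 0, 0],
                        [1, 3, -1, -1, -1], [2, 4, -1, -1, -1])
        forest = forest_from_trees([tree], 2)
        _, p, _ = pair_cooccurrence(forest, [0])
        assert p[0] == 1.0

    def test_single_tree_all_features(self):
        forest = forest_from_trees([chain(0, 1)], 2)
        t, _, _ = pair_cooccurrence(forest, [0, 1])
        assert t[0, 1] == 1

    def test_matches_brute_force_on_random_forests(self, small_cohort):
        gm, pheno = small_cohort
        ctx = train_forest(gm.dosages, pheno.status, n_trees=40, seed=19)
        forest = ctx.forest
        features = np.arange(forest.n_features)
        t, p, N = pair_cooccurrence(forest, features)
        # oracle: double loop over per-tree feature sets
        sets = [set(map(int, tr.features_used())) for tr in forest.trees]
        for i, j in itertools.combinations(range(len(features)), 2):
            brute = sum(1 for s in sets if i in s and j in s)
            assert t[i, j] == brute, (i, j)
        for i in range(len(features)):
            assert p[i] == pytest.approx(
                sum(1 for s in sets if i in s) / N)

    def test_absent_feature(self):
        forest = forest_from_trees([stump(0)], 3)
        t, p, N = pair_cooccurrence(forest, [0, 2])
        assert p[1] == 0.0
        assert paired_selection_test(int(t[0, 1]), p[0], p[1], N) == 1.0


def binom_upper_tail(t, N, prob):
    """Oracle: direct summation of the binomial pmf."""
    return sum(math.comb(N, k) * prob ** k * (1 - prob) ** (N - k)
               for k in range(t, N + 1))


class TestPairedSelectionTest:
    def test_t_zero_gives_one(self):
        assert paired_selection_test(0, 0.5, 0.5, 10) == 1.0

    def test_degenerate_certainty(self):
        assert paired_selection_test(10, 1.0, 1.0, 10) == pytest.approx(1.0)

    def test_exact_tail_example(self):
        p = paired_selection_test(100, 0.3, 0.2, 1000)
        oracle = binom_upper_tail(100, 1000, 0.06)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p < 0.001

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            N = int(rng.integers(1, 60))
            pi, pj = rng.random(2)
            t = int(rng.integers(0, N + 1))
            got = paired_selection_test(t, pi, pj, N)
            want = binom_upper_tail(t, N, pi * pj) if t > 0 else 1.0
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestSelectionAsymmetry:
    def test_perfect_symmetry(self):
        assert asymmetry_test(5, 5) == pytest.approx(1.0)

    def test_one_sided_example(self):
        # n_L=10, n_R=0 -> two-sided p = 2 * 0.5^10
        assert asymmetry_test(10, 0) == pytest.approx(2 * 0.5 ** 10)

    def test_no_observations_convention(self):
        forest = forest_from_trees([stump(0), stump(1)], 2)
        n_L, n_R, p = selection_asymmetry_test(forest, 0, 1)
        assert (n_L, n_R) == (0, 0)
        assert p == 1.0

    def test_left_daughter_counting(self):
        # feature 1 under the left daughter of feature 0 in every tree;
        # all subtree opportunity is also on the left, so the calibrated
        # null absorbs it (p0 = 1 -> no evidence)
        forest = forest_from_trees([chain(0, 1)] * 6, 2)
        n_L, n_R, p = selection_asymmetry_test(forest, 0, 1)
        assert (n_L, n_R) == (6, 0)
        assert p == 1.0

    def test_fixed_null_example(self):
        # the raw binomial building block at p0 = 0.5
        assert asymmetry_test(6, 0, p0=0.5) == pytest.approx(2 * 0.5 ** 6)

    def test_asymmetry_against_balanced_opportunity(self):
        # both daughters of the root have one internal node, but feature 1
        # always lands on the left: p_t = 0.5 per observation
        tree = make_tree([0, 1, 2, -1, -1, -1, -1],
                         [0.5, 0.5, 0.5, 0, 0, 0, 0],
                         [1, 3, 5, -1, -1, -1, -1],
                         [2, 4, 6, -1, -1, -1, -1])
        forest = forest_from_trees([tree] * 10, 3)
        n_L, n_R, p = selection_asymmetry_test(forest, 0, 1)
        assert (n_L, n_R) == (10, 0)
        # normal approximation of Binomial(10, 0.5) with continuity corr.
        want = 2 * stats.norm.sf((abs(10 - 5.0) - 0.5) / np.sqrt(2.5))
        assert p == pytest.approx(want, rel=1e-12)

    def test_orientations_pooled(self):
        forest = forest_from_trees([chain(0, 1), chain(1, 0)], 2)
        n_L, n_R, _ = selection_asymmetry_test(forest, 0, 1)
        assert (n_L, n_R) == (2, 0)

    def test_balanced_chains_symmetric(self):
        forest = forest_from_trees([chain(0, 1), chain_right(0, 1)], 2)
        n_L, n_R, p = selection_asymmetry_test(forest, 0, 1)
        assert (n_L, n_R) == (1, 1)
        assert p == 1.0

    def test_both_daughters_may_count(self):
        tree = make_tree([0, 1, 1, -1, -1, -1, -1],
                        [0.5, 0.5, 0.5, 0, 0, 0, 0],
                        [1, 3, 5, -1, -1, -1, -1],
                        [2, 4, 6, -1, -1, -1, -1])
        forest = forest_from_trees([tree], 2)
        n_L, n_R, mu, var = directional_asymmetry_counts(forest, [0, 1])
        assert n_L[0, 1] == 1 and n_R[0, 1] == 1
        # two observations at p_t = 0.5 (one internal node on each side)
        assert mu[0, 1] == pytest.approx(1.0)
        assert var[0, 1] == pytest.approx(0.5)

    def test_null_asymmetry_calibrated_on_real_forest(self, small_cohort):
        """Noise pairs should not show wholesale asymmetry significance
        (the un-calibrated 0.5-null fails this badly on unbalanced splits)."""
        gm, pheno = small_cohort
        ctx = train_forest(gm.dosages, pheno.status, n_trees=300, seed=29,
                           min_node_fraction=0.05)
        res = screen_pairs(ctx.forest, np.arange(20))
        frac_sig = (res.table["p_asym"] < 0.05).mean()
        assert frac_sig < 0.25


class TestFisherCombine:
    def test_unit_inputs(self):
        assert fisher_combine(1.0, 1.0) == pytest.approx(1.0)

    def test_half_half(self):
        x = -2 * (math.log(0.5) + math.log(0.5))
        want = math.exp(-x / 2) * (1 + x / 2)
        assert fisher_combine(0.5, 0.5) == pytest.approx(want, rel=1e-12)
        assert fisher_combine(0.5, 0.5) == pytest.approx(0.5966, abs=2e-4)

    def test_small_inputs(self):
        got = fisher_combine(0.01, 0.02)
        x = -2 * (math.log(0.01) + math.log(0.02))
        want = math.exp(-x / 2) * (1 + x / 2)
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(0.0019, abs=2e-4)

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = fisher_combine(0.0, 0.5)
        assert 0 < p < 1e-100

    def test_closed_form_matches_chi2_sf(self, rng):
        for _ in range(100):
            p1, p2 = rng.random(2)
            x = -2 * (math.log(p1) + math.log(p2))
            want = math.exp(-x / 2) * (1 + x / 2)
            assert fisher_combine(p1, p2) == pytest.approx(want, rel=1e-10)

    @given(st.floats(1e-10, 1.0), st.floats(1e-10, 1.0),
           st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_argument(self, p1, p2, shrink):
        smaller = max(p1 * shrink, 1e-12)
        assert fisher_combine(smaller, p2) <= fisher_combine(p1, p2) + 1e-12


def bh_oracle(pvals):
    """Step-up formula: q_(i) = min_{j>=i} min(1, m * p_(j) / j)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


class TestBHAdjust:
    def test_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_second_example(self):
        q = bh_adjust([0.001, 0.04, 0.9])
        np.testing.assert_allclose(q, [0.003, 0.06, 0.9])

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)


class TestScreenPairs:
    def test_fewer_than_two_features_empty(self):
        forest = forest_from_trees([stump(0)], 2)
        res = screen_pairs(forest, [0])
        assert len(res.table) == 0

    def test_ld_like_never_retained(self, small_cohort):
        gm, pheno = small_cohort
        ctx = train_forest(gm.dosages, pheno.status, n_trees=50, seed=23)
        res = screen_pairs(ctx.forest, np.arange(10), fdr_threshold=0.9)
        tab = res.table
        ld = tab[tab["direction"] == DIRECTION_LD]
        assert not ld["retained"].any()
        # LD label requires a co-occurrence deficit with no asymmetry signal
        for _, row in tab.iterrows():
            if row["direction"] == DIRECTION_LD:
                assert row["t_ij"] < row["expected"]
                assert row["p_asym"] >= 0.05
            elif row["t_ij"] >= row["expected"]:
                assert row["direction"] == DIRECTION_EPISTASIS

    def test_retained_requires_q_below_threshold(self, small_cohort):
        gm, pheno = small_cohort
        ctx = train_forest(gm.dosages, pheno.status, n_trees=50, seed=23)
        res = screen_pairs(ctx.forest, np.arange(10), fdr_threshold=0.05)
        tab = res.table
        assert (tab.loc[tab["retained"], "q_ensemble"] < 0.05).all()

    def test_feature_ids_used(self):
        forest = forest_from_trees([chain(0, 1), stump(0), stump(1)], 2)
        res = screen_pairs(forest, [0, 1], feature_ids=["rsA", "rsB"])
        assert set(res.table[["feature_i", "feature_j"]].iloc[0]) == {"rsA", "rsB"}

    def test_ld_duplicate_columns_cooccur_less_than_expected(self):
        """Noisy duplicate columns compete for the same splits, landing in
        the same tree less often than independence predicts."""
        from epiforest import SimulationSpec, simulate

        under = 0
        reps = 6
        for seed in range(reps):
            spec = SimulationSpec(n_subjects=1500, n_variants=30,
                                  maf_range=(0.2, 0.5), case_fraction=0.4,
                                  main_effects=[(0, 0.5)],
                                  ld_blocks=[(0, 1, 0.05)], seed=seed)
            gm, pheno, _ = simulate(spec)
            dup = gm.n_variants - 1  # the LD copy of column 0
            ctx = train_forest(gm.dosages, pheno.status, n_trees=120,
                               seed=seed + 7, min_node_fraction=0.05)
            t, p, N = pair_cooccurrence(ctx.forest, [0, dup])
            if t[0, 1] < N * p[0] * p[1]:
                under += 1
        assert under > reps / 2
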