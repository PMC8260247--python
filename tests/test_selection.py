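import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connsel.selection import (
    MATCHED_STRONG,
    MATCHED_WEAK,
    make_split_scheme,
    matched_activation_pairs,
    pooled_t,
    select_most_activated,
    select_top_k,
)


class TestSplitScheme:
    def test_three_folds_two_run_selection_four_run_decoding(self):
        scheme = make_split_scheme(6, seed=0)
        assert len(scheme.folds) == 3
        for fold in scheme.folds:
            assert len(fold.selection_split) == 2
            assert len(fold.decoding_runs) == 4
            assert not set(fold.selection_split) & set(fold.decoding_runs)

    def test_selection_splits_partition_runs(self):
        scheme = make_split_scheme(6, seed=3)
        all_sel = sorted(r for f in scheme.folds for r in f.selection_split)
        assert all_sel == list(range(6))

    def test_deterministic_under_seed(self):
        assert make_split_scheme(6, seed=4).splits == make_split_scheme(6, seed=4).splits

    def test_non_six_runs_need_override(self):
        with pytest.raises(ValueError):
            make_split_scheme(4, seed=0)
        scheme = make_split_scheme(splits=[(0, 1), (2, 3)])
        assert len(scheme.folds) == 2


class TestSelectTopK:
    def test_small_example_most_and_least(self):
        scores = np.array([0.1, 0.5, -0.2, 0.3])
        assert set(select_top_k(scores, 2, "most").indices) == {1, 3}
        assert set(select_top_k(scores, 2, "least").indices) == {2, 0}

    def test_k_equals_eligible_over_two(self):
        scores = np.arange(10.0)
        top = select_top_k(scores, 5, "most")
        assert set(top.indices) == {5, 6, 7, 8, 9}

    def test_matches_fullsort_oracle(self, rng):
        for _ in range(200):
            scores = rng.normal(size=50)
            k = int(rng.integers(1, 25))
            got = select_top_k(scores, k, "most").indices
            oracle = sorted(range(50), key=lambda i: (-scores[i], i))[:k]
            assert list(got) == oracle

    def test_tie_break_by_ascending_index(self):
        scores = np.zeros(8)
        assert list(select_top_k(scores, 3, "most").indices) == [0, 1, 2]

    def test_insufficient_eligible_raises(self):
        with pytest.raises(ValueError, match="eligible"):
            select_top_k(np.arange(5.0), 3, "most")

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 20))
    def test_most_min_geq_least_max(self, seed, k):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=3 * k)
        most = select_top_k(scores, k, "most")
        least = select_top_k(scores, k, "least")
        assert scores[most.indices].min() >= scores[least.indices].max()
        assert not set(most.indices) & set(least.indices)

    def test_most_activated_includes_planted_peak(self):
        t = np.zeros(300)
        t[137] = 10.0
        vset = select_most_activated(t, 5, contrast="tools>faces")
        assert 137 in vset.indices
        assert vset.contrast_used == "tools>faces"


class TestPooledT:
    def test_agrees_with_scipy(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.4, 1.3, size=30)
        t = pooled_t(a.mean(), a.var(ddof=1), b.mean(), b.var(ddof=1), 30, 30)
        ref = stats.ttest_ind(a, b, equal_var=True).statistic
        assert t == pytest.approx(ref, abs=1e-12)

    def test_degenerate_equal_values_is_zero(self):
        assert pooled_t(1.0, 0.0, 1.0, 0.0, 10, 10) == 0.0


class TestMatchedActivationPairs:
    def test_liberal_retention_near_ninety_percent(self, rng):
        """Activation independent of connectivity: matching t is null,
        so ~90% of draws pass the two-tailed p > 0.10 gate."""
        rates = []
        for rep in range(60):
            z = rng.normal(size=400)
            t_vals = rng.normal(size=400)
            pairs = matched_activation_pairs(
                z, t_vals, k=100, threshold_mode="liberal", n_draws=2000,
                seed=rep)
            rates.append(len(pairs) / 2000)
        # per-pool retention varies (the draws share one median split);
        # the rate is 0.90 only on average over pools
        assert abs(np.mean(rates) - 0.90) < 0.02

    def test_perfect_confound_strict_retention_near_zero(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=400)
        pairs = matched_activation_pairs(
            z, z.copy(), k=100, threshold_mode="strict", n_draws=10000, seed=1)
        assert len(pairs) / 10000 < 0.001

    def test_identical_t_values_all_retained_liberal(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=300)
        pairs = matched_activation_pairs(
            z, np.full(300, 3.3), k=100, threshold_mode="liberal",
            n_draws=200, seed=0)
        assert len(pairs) == 200

    def test_pairs_split_by_connectivity_median(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=300)
        med = np.median(z)
        pairs = matched_activation_pairs(
            z, rng.normal(size=300), k=100, threshold_mode="liberal",
            n_draws=50, seed=4)
        for strong, weak in pairs:
            assert (z[strong.indices] > med).all()
            assert (z[weak.indices] <= med).all()
            assert strong.mode == MATCHED_STRONG and weak.mode == MATCHED_WEAK

    def test_retained_pairs_repass_threshold_independently(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=300)
        t_vals = rng.normal(size=300)
        pairs = matched_activation_pairs(
            z, t_vals, k=100, threshold_mode="intermediate", n_draws=500, seed=6)
        assert pairs  # intermediate retains ~38% under independence
        for strong, weak in pairs:
            t = stats.ttest_ind(t_vals[strong.indices], t_vals[weak.indices],
                                equal_var=True).statistic
            assert -0.5 <= t <= 0.5

    def test_unknown_threshold_rejected(self):
        with pytest.raises(ValueError):
            matched_activation_pairs(np.arange(300.0), np.arange(300.0),
                                     threshold_mode="bogus")
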