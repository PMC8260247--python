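import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connsel import make_split_scheme
from connsel.decoding import (
    PatternPair,
    batch_accuracy,
    comparison_label,
    comparisons_for,
    decode_all,
    extract_patterns,
    fold_average,
    splithalf_accuracy,
    tsnr,
)
from connsel.selection import VoxelSet


def brute_splithalf(pair: PatternPair) -> float:
    """Explicit-loop oracle for the 2x2 split-half correlation statistic."""
    corr = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            a, b = pair.split_a[i], pair.split_b[j]
            corr[i, j] = np.corrcoef(a, b)[0, 1]
    return (corr[0, 0] + corr[1, 1]) / 2 - (corr[0, 1] + corr[1, 0]) / 2


class TestSplithalfAccuracy:
    def test_hand_computed_orthogonal_patterns(self):
        """cond1=[1,0,0], cond2=[0,1,0] in both halves: within r = 1,
        between r = -0.5, accuracy = 1.5."""
        a = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        pair = PatternPair(a, a.copy(), ("tools", "faces"))
        assert splithalf_accuracy(pair) == pytest.approx(1.5, abs=1e-12)

    def test_identical_patterns_zero_accuracy(self):
        p = np.tile(np.array([[0.3, -1.2, 0.8, 0.1]]), (2, 1))
        pair = PatternPair(p, p.copy(), ("tools", "faces"))
        assert splithalf_accuracy(pair) == pytest.approx(0.0, abs=1e-12)

    def test_swapping_splits_preserves_accuracy(self, rng):
        a, b = rng.normal(size=(2, 2, 30))
        assert splithalf_accuracy(PatternPair(a, b, ("x", "y"))) == pytest.approx(
            splithalf_accuracy(PatternPair(b, a, ("x", "y"))), abs=1e-12)

    def test_zero_variance_pattern_flagged_missing(self):
        a = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 0.0]])
        b = np.ones((2, 3))
        assert np.isnan(splithalf_accuracy(PatternPair(a, b, ("x", "y"))))

    def test_matches_bruteforce_oracle(self, rng):
        """Vectorized statistic equals the explicit-loop oracle to 1e-12."""
        for _ in range(1000):
            nv = int(rng.integers(3, 40))
            a, b = rng.normal(size=(2, 2, nv))
            pair = PatternPair(a, b, ("x", "y"))
            assert splithalf_accuracy(pair) == pytest.approx(
                brute_splithalf(pair), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_in_pm2(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 2, 10))
        acc = splithalf_accuracy(PatternPair(a, b, ("x", "y")))
        assert -2.0 <= acc <= 2.0

    def test_batch_accuracy_agrees_subsetwise(self, rng):
        pa, pb = rng.normal(size=(2, 2, 60))
        sets = np.array([rng.permutation(60)[:20] for _ in range(15)])
        batch = batch_accuracy(pa, pb, sets)
        for i, s in enumerate(sets):
            ref = splithalf_accuracy(PatternPair(pa[:, s], pb[:, s], ("x", "y")))
            assert batch[i] == pytest.approx(ref, abs=1e-12)


class TestExtractPatterns:
    def test_split_mean_of_identical_runs(self, planted_analysis, small_layout):
        sa = planted_analysis
        vox = small_layout.regions["tool_A"][:50]
        vset = VoxelSet(np.arange(50), 50, "most_connected")
        gset = VoxelSet(vox, 50, "most_connected")
        pair = extract_patterns(sa.statmaps, gset, ((0, 1), (2, 3)), ("tools", "faces"))
        c = sa.statmaps[0].condition_names.index("tools")
        expected = (sa.statmaps[0].betas[c, vox] + sa.statmaps[1].betas[c, vox]) / 2
        assert np.allclose(pair.split_a[0], expected)
        assert pair.split_a.shape == (2, 50)

    def test_voxel_order_alignment(self, planted_analysis, small_layout):
        sa = planted_analysis
        vox = small_layout.regions["tool_A"][:30]
        perm = np.random.default_rng(0).permutation(30)
        p1 = extract_patterns(sa.statmaps, VoxelSet(vox, 30, "m"), ((0, 1), (2, 3)),
                              ("tools", "faces"))
        p2 = extract_patterns(sa.statmaps, VoxelSet(vox[perm], 30, "m"),
                              ((0, 1), (2, 3)), ("tools", "faces"))
        assert np.allclose(p1.split_a[:, perm], p2.split_a)
        assert np.allclose(p1.split_b[:, perm], p2.split_b)

    def test_out_of_range_voxels_rejected(self, planted_analysis):
        bad = VoxelSet(np.array([10**7]), 1, "m")
        with pytest.raises(ValueError, match="outside"):
            extract_patterns(planted_analysis.statmaps, bad, ((0, 1), (2, 3)),
                             ("tools", "faces"))


class TestTsnr:
    def test_definition(self):
        rng = np.random.default_rng(0)
        ts = 100 + rng.normal(size=(2000, 1)) * 10
        assert tsnr(ts)[0] == pytest.approx(10.0, rel=0.05)

    def test_scale_invariance(self, rng):
        ts = 50 + rng.normal(size=(100, 5))
        assert np.allclose(tsnr(ts), tsnr(2.0 * ts))

    def test_zero_mean_noise_near_zero(self, rng):
        vals = tsnr(rng.normal(size=(5000, 3)))
        assert np.abs(vals).max() < 0.1

    def test_zero_variance_flagged_infinite(self):
        ts = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        assert np.isinf(tsnr(ts)[0])


class TestDecodeAll:
    def test_planted_most_beats_least_in_each_region(
            self, planted_subject, planted_analysis, scheme):
        tab = decode_all([planted_subject], scheme,
                         analyses={planted_subject.subject_id: planted_analysis})
        avg = fold_average(tab)
        wide = avg.pivot_table(index="region", columns="mode", values="accuracy")
        assert (wide["most_connected"] > wide["least_connected"]).all()

    def test_table_covers_regions_comparisons_modes_folds(
            self, planted_subject, planted_analysis, scheme):
        tab = decode_all([planted_subject], scheme,
                         analyses={planted_subject.subject_id: planted_analysis})
        assert set(tab["region"]) == {"tool_A", "tool_B"}
        assert set(tab["comparison"]) == {"TvF", "TvP"}
        assert set(tab["fold"]) == {0, 1, 2}
        assert len(tab) == 2 * 2 * 3 * 3

    def test_deterministic_on_rerun(self, planted_subject, scheme):
        a = decode_all([planted_subject], scheme)
        b = decode_all([planted_subject], scheme)
        assert a.equals(b)

    def test_fold_average_means_over_folds(self, planted_subject, scheme):
        tab = decode_all([planted_subject], scheme)
        avg = fold_average(tab)
        cell = tab[(tab.region == "tool_A") & (tab.comparison == "TvF")
                   & (tab["mode"] == "most_connected")]
        got = avg[(avg.region == "tool_A") & (avg.comparison == "TvF")
                  & (avg["mode"] == "most_connected")]["accuracy"].iloc[0]
        assert got == pytest.approx(cell["accuracy"].mean())


def test_comparisons_for_category():
    assert comparisons_for("tools") == [("tools", "faces"), ("tools", "places")]
    assert comparison_label("places", "faces") == "PvF"
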