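import numpy as np
import pandas as pd
import pytest

from connsel.stats import (
    bonferroni_threshold,
    paired_t,
    rm_anova,
    signflip_group_map,
    tfce,
)


class TestPairedT:
    def test_identical_inputs(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_known_differences(self):
        """Differences [1, 2, 3]: mean 2, sd 1, t = 2*sqrt(3), df = 2."""
        t, df, p = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert df == 2

    def test_sign_flip_symmetry(self, rng):
        a, b = rng.normal(size=(2, 15))
        t1, _, p1 = paired_t(a, b)
        t2, _, p2 = paired_t(b, a)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_listwise_deletion(self):
        a = np.array([1.0, np.nan, 3.0, 4.0])
        b = np.array([0.0, 5.0, 1.0, 1.0])
        t, df, p = paired_t(a, b)
        assert df == 2

    def test_constant_nonzero_difference_raises(self):
        with pytest.raises(ValueError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 4, 0.0125)])
    def test_division(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == expected

    def test_corrected_decisions_subset_of_uncorrected(self, rng):
        p = rng.uniform(size=100)
        thr = bonferroni_threshold(0.05, 10)
        assert set(np.flatnonzero(p < thr)) <= set(np.flatnonzero(p < 0.05))


def _two_level_table(rng, n=12):
    rows = []
    for s in range(n):
        base = rng.normal()
        rows.append((f"s{s}", "a", base + rng.normal() + 0.5))
        rows.append((f"s{s}", "b", base + rng.normal()))
    return pd.DataFrame(rows, columns=["subject", "cond", "y"])


class TestRmAnova:
    def test_two_level_factor_F_equals_t_squared(self, rng):
        tab = _two_level_table(rng)
        res = rm_anova(tab, "y", ["cond"])
        wide = tab.pivot(index="subject", columns="cond", values="y")
        t, df, p = paired_t(wide["a"], wide["b"])
        term = res.table.iloc[0]
        assert term["F"] == pytest.approx(t**2, abs=1e-10)
        assert term["p"] == pytest.approx(p, abs=1e-10)

    def test_constant_dv_all_F_zero(self):
        rows = [(f"s{s}", c, 1.0) for s in range(6) for c in "ab"]
        tab = pd.DataFrame(rows, columns=["subject", "cond", "y"])
        res = rm_anova(tab, "y", ["cond"])
        assert res.table["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_row_order_invariance(self, rng):
        tab = _two_level_table(rng)
        shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = rm_anova(tab, "y", ["cond"]).table
        b = rm_anova(shuffled, "y", ["cond"]).table
        assert np.allclose(a["F"], b["F"])

    def test_incomplete_subjects_dropped(self, rng):
        tab = _two_level_table(rng)
        tab = tab.drop(index=tab.index[-1])  # subject s11 loses one cell
        res = rm_anova(tab, "y", ["cond"])
        assert res.n_subjects == 11

    def test_three_way_matches_pingouin_two_way_margin(self, rng):
        """Two-way case cross-checked against pingouin's rm_anova."""
        pingouin = pytest.importorskip("pingouin")
        rows = []
        for s in range(10):
            for m in "xy":
                for r in "pq":
                    rows.append((f"s{s}", m, r,
                                 rng.normal() + (0.8 if m == "x" else 0)))
        tab = pd.DataFrame(rows, columns=["subject", "mode", "region", "dv"])
        mine = rm_anova(tab, "dv", ["mode", "region"])
        ref = pingouin.rm_anova(data=tab, dv="dv", within=["mode", "region"],
                                subject="subject", detailed=True)
        for term, pg_name in [("mode", "mode"), ("region", "region"),
                              ("mode:region", "mode * region")]:
            f_ref = float(ref.loc[ref["Source"] == pg_name, "F"].iloc[0])
            assert mine.table.loc[term, "F"] == pytest.approx(f_ref, rel=1e-6)

    def test_partial_eta_squared_in_unit_interval(self, rng):
        res = rm_anova(_two_level_table(rng), "y", ["cond"])
        assert ((res.table["partial_eta_sq"] >= 0)
                & (res.table["partial_eta_sq"] <= 1)).all()


class TestTfce:
    def test_zero_map_zero_output(self):
        assert np.all(tfce(np.zeros((5, 5, 5))) == 0)

    def test_single_voxel_closed_form(self):
        """Isolated voxel of height v: sum_h 1^E h^H dh -> v^3/3."""
        m = np.zeros((7, 7, 7))
        m[3, 3, 3] = 2.0
        out = tfce(m)
        assert out[3, 3, 3] == pytest.approx(2.0**3 / 3, rel=0.02)
        assert np.count_nonzero(out) == 1

    def test_monotone_under_scaling(self, rng):
        m = np.abs(rng.normal(size=(8, 8, 8)))
        assert np.all(tfce(2 * m) >= tfce(m) - 1e-12)

    def test_cluster_extent_boosts_enhancement(self):
        lone = np.zeros((9, 9, 9))
        lone[4, 4, 4] = 1.0
        blob = np.zeros((9, 9, 9))
        blob[3:6, 4, 4] = 1.0
        assert tfce(blob)[4, 4, 4] > tfce(lone)[4, 4, 4]

    def test_six_connectivity_not_diagonal(self):
        m = np.zeros((6, 6, 6))
        m[1, 1, 1] = m[2, 2, 2] = 1.0  # diagonal neighbors: separate clusters
        out = tfce(m)
        ref = np.zeros((6, 6, 6))
        ref[1, 1, 1] = 1.0
        assert out[1, 1, 1] == pytest.approx(tfce(ref)[1, 1, 1])


class TestSignflipGroupMap:
    def _diffs(self, rng, n_sub=8, dims=(6, 6, 6), effect=0.0):
        d = rng.normal(size=(n_sub, int(np.prod(dims)))) * 0.1
        d[:, :8] += effect
        return d

    def test_planted_effect_detected_null_untouched(self, rng):
        dims = (6, 6, 6)
        d = self._diffs(rng, effect=0.5)
        gm = signflip_group_map(d, grid_dims=dims, n_perm=300, seed=0)
        sup = gm.suprathreshold().ravel()
        assert sup[:8].any()
        assert not sup[100:].any()

    def test_deterministic_under_seed(self, rng):
        d = self._diffs(rng, effect=0.3)
        a = signflip_group_map(d, grid_dims=(6, 6, 6), n_perm=200, seed=7)
        b = signflip_group_map(d, grid_dims=(6, 6, 6), n_perm=200, seed=7)
        assert np.array_equal(a.z, b.z)

    def test_p_values_bounded_by_permutation_count(self, rng):
        d = self._diffs(rng, effect=1.0)
        gm = signflip_group_map(d, grid_dims=(6, 6, 6), n_perm=150, seed=1)
        inside = gm.p[gm.mask]
        assert inside.min() >= 1.0 / 151
        assert inside.max() <= 1.0

    def test_low_permutation_count_warns(self, rng):
        with pytest.warns(UserWarning, match="unstable"):
            signflip_group_map(self._diffs(rng), grid_dims=(6, 6, 6),
                               n_perm=50, seed=0)

    def test_mask_restricts_output(self, rng):
        dims = (6, 6, 6)
        mask = np.zeros(int(np.prod(dims)), bool)
        mask[:50] = True
        gm = signflip_group_map(self._diffs(rng, effect=0.6), grid_dims=dims,
                                n_perm=200, seed=2, mask=mask)
        assert not gm.suprathreshold().ravel()[50:].any()
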