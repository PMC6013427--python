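"""Group statistics: t tests, cluster permutation, sign-flip thresholds,
spatial aggregation, lateralization ANOVA, narrowband detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from navmem.stats import (
    build_contrast,
    cluster_permutation,
    group_ttest,
    laterality_anova,
    narrowband_detect,
    paired_ttest,
    signflip_map_threshold,
    spatial_aggregate,
    two_sample_ttest,
    within_subject_sem,
)


class TestContrast:
    def _channels(self):
        return pd.DataFrame(
            {
                "channel": ["a", "b"],
                "hemisphere": ["L", "L"],
                "region": ["hippocampus", "hippocampus"],
            }
        )

    def test_condition_mean_difference(self):
        vals = np.array([[0.5, 0.2], [0.5, 1.0], [0.1, 0.2], [0.1, 0.2]])
        a = np.array([True, True, False, False])
        out = build_contrast(vals, a, ~a, self._channels(), "S0", "memory", "low_theta")
        # electrode contrasts 0.4 and 0.4 -> subject value 0.4
        assert out["value"].iloc[0] == pytest.approx(0.4)
        assert out["n_electrodes"].iloc[0] == 2

    def test_electrode_averaging_rule(self):
        vals = np.array([[0.2, 0.6], [0.0, 0.0]])
        a = np.array([True, False])
        out = build_contrast(vals, a, ~a, self._channels(), "S0", "memory", "low_theta")
        assert out["value"].iloc[0] == pytest.approx((0.2 + 0.6) / 2)

    def test_empty_condition_electrode_skipped(self):
        vals = np.array([[np.nan, 0.3], [np.nan, 0.1], [0.2, 0.2]])
        a = np.array([True, True, False])
        with pytest.warns(UserWarning, match="empty condition"):
            out = build_contrast(vals, a, ~a, self._channels(), "S0", "m", "low_theta")
        assert out["n_electrodes"].iloc[0] == 1


class TestTTests:
    def test_closed_form_value(self):
        t, dof, p = group_ttest([0.1, 0.2, 0.3, 0.4, 0.5])
        assert t == pytest.approx(4.242640687119285)
        assert dof == 4

    def test_symmetric_pair_is_null(self):
        t, _, p = group_ttest([-1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            group_ttest([1.0, 1.0, 1.0, 1.0])

    def test_paired_and_two_sample_variants(self):
        a, b = [1.0, 2.0, 3.0], [0.5, 1.0, 2.0]
        tp, dofp, _ = paired_ttest(a, b)
        assert dofp == 2 and tp > 0
        tt, doft, _ = two_sample_ttest(a, b)
        assert doft == 4


class TestClusterPermutation:
    def test_all_zero_maps_empty(self):
        res = cluster_permutation(np.zeros((8, 6, 6)), n_perm=50, seed=0)
        assert res.clusters == []

    def test_planted_cluster_detected_with_power(self):
        """A contiguous 5x5 mean shift (d = 1.5) in 12 subjects is found with
        p < 0.05 and >= 50% coverage in >= 90% of runs."""
        rng = np.random.default_rng(42)
        hits = 0
        runs = 60
        planted = np.zeros((20, 20), bool)
        planted[5:10, 5:10] = True
        for _ in range(runs):
            maps = rng.normal(size=(12, 20, 20))
            maps[:, planted] += 1.5
            res = cluster_permutation(maps, n_perm=500, seed=int(rng.integers(2**31)))
            good = [
                c
                for c in res.clusters
                if c.p < 0.05 and planted.reshape(-1)[c.bins].sum() >= 0.5 * 25
            ]
            hits += bool(good)
        assert hits >= 0.9 * runs

    def test_sign_consistency_and_p_range(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(size=(10, 15, 15))
        maps[:, 2:6, 2:6] += 2.0
        res = cluster_permutation(maps, n_perm=200, seed=4)
        for c in res.clusters:
            assert 0 < c.p <= 1
            ts = res.t_map.reshape(-1)[c.bins]
            assert np.all(np.sign(ts) == c.sign)

    def test_one_dimensional_maps(self):
        rng = np.random.default_rng(5)
        maps = rng.normal(size=(10, 40))
        maps[:, 10:20] += 1.5
        res = cluster_permutation(maps, n_perm=300, seed=6)
        assert res.significant
        bins = res.significant[0].bins
        assert np.all(np.diff(sorted(bins)) == 1)  # contiguous in time

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="subjects"):
            cluster_permutation(np.zeros((3, 5, 5)))


class TestSignflip:
    def test_thresholds_roughly_symmetric(self):
        rng = np.random.default_rng(7)
        lo, hi = signflip_map_threshold(rng.normal(size=(20, 20)), n_perm=1000, seed=8)
        assert lo < 0 < hi
        assert abs(lo + hi) < 0.2

    def test_matches_parametric_critical_value(self):
        rng = np.random.default_rng(9)
        lo, hi = signflip_map_threshold(rng.normal(size=(20, 20)), n_perm=1000, seed=10)
        crit = sp_stats.t.ppf(0.975, 19)
        assert hi == pytest.approx(crit, rel=0.15)
        assert -lo == pytest.approx(crit, rel=0.15)

    def test_convergence_with_permutation_count(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(15, 12))
        lo1, hi1 = signflip_map_threshold(x, n_perm=1000, seed=12)
        lo4, hi4 = signflip_map_threshold(x, n_perm=4000, seed=13)
        assert hi4 == pytest.approx(hi1, rel=0.05)
        assert lo4 == pytest.approx(lo1, rel=0.05)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="subjects"):
            signflip_map_threshold(np.zeros((3, 4)))


class TestSpatialAggregate:
    def _effects(self, coords, values, subject="S0"):
        df = pd.DataFrame(coords, columns=["x", "y", "z"])
        df["value"] = values
        df["subject"] = subject
        return df

    def test_single_electrode_within_radius(self):
        eff = self._effects([[0, 0, 0]], [0.7])
        maps, excluded, _ = spatial_aggregate(
            eff, np.array([[10.0, 0, 0]]), radius=12.5, min_subjects=1
        )
        assert maps[0, 0] == pytest.approx(0.7)
        assert not excluded[0]

    def test_point_beyond_radius_unassigned(self):
        eff = self._effects([[0, 0, 0]], [0.7])
        maps, excluded, _ = spatial_aggregate(
            eff, np.array([[13.0, 0, 0]]), radius=12.5, min_subjects=1
        )
        assert np.isnan(maps[0, 0])
        assert excluded[0]

    def test_same_subject_electrodes_average(self):
        eff = self._effects([[0, 0, 0], [5, 0, 0]], [0.2, 0.6])
        maps, _, _ = spatial_aggregate(
            eff, np.array([[2.0, 0, 0]]), radius=12.5, min_subjects=1
        )
        assert maps[0, 0] == pytest.approx(0.4)

    def test_min_subject_exclusion(self):
        eff = pd.concat(
            [self._effects([[0, 0, 0]], [0.5], f"S{i}") for i in range(3)],
            ignore_index=True,
        )
        _, excluded, _ = spatial_aggregate(
            eff, np.array([[0.0, 0, 0]]), radius=5.0, min_subjects=5
        )
        assert excluded[0]

    def test_empty_targets_raise(self):
        with pytest.raises(ValueError, match="empty"):
            spatial_aggregate(self._effects([[0, 0, 0]], [1.0]), np.empty((0, 3)))

    def test_smoothing_preserves_constant_maps(self):
        eff = self._effects([[0, 0, 0], [4, 0, 0], [8, 0, 0]], [0.3, 0.3, 0.3])
        pts = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        maps, _, _ = spatial_aggregate(eff, pts, radius=3.0, smooth_fwhm=4.0, min_subjects=1)
        assert np.allclose(maps, 0.3)


class TestLateralityAnova:
    def _table(self, cell_means, sd=0.05, n=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (h, c), mu in cell_means.items():
            for i in range(n):
                rows.append(
                    {"subject": f"{h}{i}", "hemisphere": h, "contrast": c,
                     "value": mu + rng.normal(0, sd)}
                )
        return pd.DataFrame(rows)

    def test_equal_cells_no_interaction(self):
        tbl = self._table({("L", "m"): 0.3, ("L", "n"): 0.3, ("R", "m"): 0.3, ("R", "n"): 0.3})
        res = laterality_anova(tbl)
        assert res["p_interaction"] > 0.05

    def test_crossover_interaction(self):
        d = 0.5
        tbl = self._table({("L", "m"): d, ("L", "n"): -d, ("R", "m"): -d, ("R", "n"): d})
        res = laterality_anova(tbl)
        assert res["F_interaction"] > 50
        assert res["p_interaction"] < 0.001

    def test_matches_hand_computed_sums_of_squares(self):
        """Balanced 2x2: interaction F from explicit SS decomposition."""
        tbl = self._table(
            {("L", "m"): 0.4, ("L", "n"): 0.1, ("R", "m"): 0.0, ("R", "n"): 0.3},
            sd=0.1, n=6, seed=1,
        )
        res = laterality_anova(tbl)
        # brute-force oracle: cell/marginal means on the same data
        g = tbl.groupby(["hemisphere", "contrast"])["value"].mean()
        gh = tbl.groupby("hemisphere")["value"].mean()
        gc = tbl.groupby("contrast")["value"].mean()
        grand = tbl["value"].mean()
        n = 6
        ss_int = n * sum(
            (g[h, c] - gh[h] - gc[c] + grand) ** 2
            for h in ("L", "R") for c in ("m", "n")
        )
        resid = tbl["value"] - tbl.apply(lambda r: g[r["hemisphere"], r["contrast"]], axis=1)
        ss_err = (resid**2).sum()
        F = ss_int / 1 / (ss_err / (4 * n - 4))
        assert res["F_interaction"] == pytest.approx(F, rel=1e-6)
        assert res["dof"] == (1, 4 * n - 4)

    def test_empty_cell_raises(self):
        tbl = self._table({("L", "m"): 0.1, ("L", "n"): 0.1, ("R", "m"): 0.1, ("R", "n"): 0.1})
        with pytest.raises(ValueError, match="cell|hemispheres"):
            laterality_anova(tbl[~((tbl.hemisphere == "R") & (tbl.contrast == "n"))])


class TestNarrowband:
    def _powerlaw(self, exponent=2.0, n=30):
        freqs = np.logspace(0, np.log10(50), n)
        return freqs, -exponent * np.log(freqs) + 2.0

    def test_pure_power_law_flags_nothing(self):
        freqs, y = self._powerlaw()
        res = narrowband_detect(freqs, y)
        assert res.flagged.size == 0
        assert res.slope == pytest.approx(-2.0, abs=1e-8)

    def test_bump_flagged_and_slope_preserved(self):
        rng = np.random.default_rng(20)
        freqs, y = self._powerlaw()
        y = y + rng.normal(0, 0.05, y.size)
        bump = 0.8 * np.exp(-((np.log(freqs) - np.log(3.0)) ** 2) / (2 * 0.15**2))
        res = narrowband_detect(freqs, y + bump)
        assert any(2.4 <= f <= 3.8 for f in res.flagged)
        assert res.slope == pytest.approx(-2.0, rel=0.10)

    def test_robust_to_single_outlier(self):
        freqs, y = self._powerlaw()
        y_out = y.copy()
        y_out[12] += 5.0
        clean = narrowband_detect(freqs, y).slope
        robust = narrowband_detect(freqs, y_out).slope
        ols = np.polyfit(np.log(freqs), y_out, 1)[0]
        assert abs(robust - clean) / abs(clean) < 0.02
        assert abs(robust - clean) < abs(ols - clean)

    def test_nonfinite_rejected(self):
        freqs, y = self._powerlaw()
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            narrowband_detect(freqs, y)

    def test_remembered_flags_planted_oscillation_more(self, recovery_runs):
        """Left-hemisphere electrodes flag the planted 3-Hz oscillation more
        often for remembered than forgotten spectra (sign test)."""
        nb = pd.concat([r["narrowband"] for r in recovery_runs], ignore_index=True)
        left = nb[nb["hemisphere"] == "L"]
        wide = left.pivot_table(
            index=["subject", "channel"], columns="condition", values="osc_flagged",
            aggfunc="mean",
        ).dropna()
        pos = (wide["remembered"] > wide["forgotten"]).sum()
        neg = (wide["remembered"] < wide["forgotten"]).sum()
        assert pos + neg >= 20
        assert sp_stats.binomtest(int(pos), int(pos + neg)).pvalue < 0.05
        assert pos > neg


class TestWithinSubjectSem:
    def test_toy_matrix_hand_value(self):
        sem = within_subject_sem([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(sem, 0.0)

    def test_subject_offsets_removed(self):
        rng = np.random.default_rng(21)
        offsets = rng.normal(0, 10, size=(30, 1))
        conds = np.array([0.0, 0.5, 1.0])
        sem = within_subject_sem(offsets + conds[None, :])
        assert np.all(sem < 1e-9)

    def test_single_subject_raises(self):
        with pytest.raises(ValueError, match="subjects"):
            within_subject_sem([[1.0, 2.0]])

    def test_missing_cell_raises(self):
        with pytest.raises(ValueError, match="issing"):
            within_subject_sem([[1.0, np.nan], [2.0, 3.0]])
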