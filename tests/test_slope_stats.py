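import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phaseslope import slope_stats
from phaseslope.errors import LandmarkError
from phaseslope.preprocess import PopulationProfile, median_profile
from reference import ref_kruskal_h, ref_landmarks, ref_slopes


def profile_from(zt, med):
    zt = np.asarray(zt)
    return PopulationProfile(zt, np.asarray(med, dtype=float),
                             np.full(len(zt), 10), 30)


class TestSlopeFormula:
    def test_worked_example_rounds_to_0_38(self):
        # median activity 0 at minute 511, 67.6 at minute 691
        s = slope_stats.slope_between(0.0, 67.6, 511, 691)
        assert round(s, 2) == 0.38

    def test_equal_activity_gives_zero(self):
        assert slope_stats.slope_between(33.0, 33.0, 510, 690) == 0.0

    def test_decline_gives_negative_slope(self):
        assert slope_stats.slope_between(50.0, 20.0, 510, 690) < 0


class TestDetectLandmarks:
    def test_tie_rules_last_min_first_max(self):
        # pre-transition medians [10, 5, 5, 20, 40]; startle sits in the
        # transition bin and must not become the peak
        prof = profile_from([0, 30, 60, 90, 120, 150],
                            [10, 5, 5, 20, 40, 95])
        lm = slope_stats.detect_landmarks(prof, 150, (0, 150))
        assert (lm.zt_min, lm.zt_max) == (60, 120)
        assert (lm.act_at_min, lm.act_at_max) == (5.0, 40.0)

    def test_strictly_increasing_profile(self):
        prof = profile_from([0, 30, 60, 90], [1, 2, 3, 4])
        lm = slope_stats.detect_landmarks(prof, 120, (0, 120))
        assert (lm.zt_min, lm.zt_max) == (0, 90)

    def test_flat_profile_rejected(self):
        prof = profile_from([0, 30, 60, 90], [5, 5, 5, 5])
        with pytest.raises(LandmarkError, match="no anticipation structure"):
            slope_stats.detect_landmarks(prof, 120, (0, 120))

    def test_minimum_on_final_bin_needs_narrower_window(self):
        prof = profile_from([0, 30, 60], [9, 7, 2])
        with pytest.raises(LandmarkError, match="narrower"):
            slope_stats.detect_landmarks(prof, 90, (0, 90))

    def test_window_must_end_at_transition(self):
        prof = profile_from([0, 30, 60, 90], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="end at the transition"):
            slope_stats.detect_landmarks(prof, 120, (0, 90))

    def test_matches_exhaustive_scan_on_simulated_evening_peaks(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            zt = np.arange(0, 720, 30)
            med = np.clip(rng.normal(10, 3, zt.size), 0, None)
            med[17:24] += np.linspace(0, 60, 7)      # evening rise
            prof = profile_from(zt, med)
            lm = slope_stats.detect_landmarks(prof, 720, (360, 720))
            sel = (zt >= 360) & (zt < 720)
            exp_min, exp_max = ref_landmarks(zt[sel].tolist(),
                                             med[sel].tolist(), 720)
            assert (lm.zt_min, lm.zt_max) == (exp_min, exp_max)


class TestFlySlopes:
    def make_day(self):
        return pd.DataFrame(
            {"a": [0.0, 50.0], "b": [10.0, 10.0], "c": [40.0, 20.0]},
            index=[510, 690])

    def test_per_fly_values(self):
        slopes, excluded = slope_stats.fly_slopes(self.make_day(), 510, 690)
        assert excluded == []
        assert slopes["a"] == pytest.approx(50 / 180)
        assert slopes["b"] == 0.0
        assert slopes["c"] == pytest.approx(-20 / 180)   # negative is legal

    def test_missing_landmark_bin_excludes_fly(self):
        day = self.make_day()
        day.loc[510, "b"] = np.nan
        slopes, excluded = slope_stats.fly_slopes(day, 510, 690)
        assert excluded == ["b"]
        assert set(slopes.index) == {"a", "c"}

    def test_shared_landmarks_match_loop_oracle(self):
        rng = np.random.default_rng(10)
        day = pd.DataFrame(rng.random((48, 10)) * 100,
                           index=np.arange(48) * 30)
        slopes, _ = slope_stats.fly_slopes(day, 510, 690)
        expected = ref_slopes(day.index.tolist(),
                              day.to_numpy().tolist(), 510, 690)
        np.testing.assert_allclose(slopes.to_numpy(), expected, rtol=1e-12)


class TestSloTheSloExp:
    def test_slo_the_reproduces_worked_example(self):
        prof = profile_from([510, 540, 690], [0.0, 10.0, 67.6])
        assert round(slope_stats.slo_the(prof, 510, 690), 2) == 0.38

    def test_identical_flies_make_slo_the_equal_every_slope(self):
        day = pd.DataFrame({f: [5.0, 80.0] for f in "abcd"}, index=[510, 690])
        prof = median_profile(day)
        slopes, _ = slope_stats.fly_slopes(day, 510, 690)
        assert slope_stats.slo_the(prof, 510, 690) == slopes["a"]

    def test_slo_the_equals_fly_slope_of_independent_median(self):
        rng = np.random.default_rng(11)
        day = pd.DataFrame(rng.random((48, 7)) * 100,
                           index=np.arange(48) * 30)
        prof = median_profile(day)
        med_series = day.median(axis=1)
        direct = (med_series[690] - med_series[510]) / 180
        assert slope_stats.slo_the(prof, 510, 690) == pytest.approx(
            direct, rel=1e-12)

    @pytest.mark.parametrize("slopes,expected", [
        ([0.1, 0.2, 0.3], 0.2),
        ([0.42], 0.42),
    ])
    def test_slo_exp_is_median(self, slopes, expected):
        assert slope_stats.slo_exp(slopes) == pytest.approx(expected)

    def test_even_n_is_mean_of_central_pair(self):
        rng = np.random.default_rng(12)
        vals = rng.random(10).tolist()
        s = sorted(vals)
        assert slope_stats.slo_exp(vals) == pytest.approx(
            0.5 * (s[4] + s[5]), rel=1e-12)


class TestSyncRatio:
    def test_identical_flies_give_exactly_one(self):
        day = pd.DataFrame({f: [5.0, 80.0] for f in "abcde"}, index=[510, 690])
        a = slope_stats.evening_analysis(day, 720, zt_min=510, zt_max=690)
        assert a.ratio == 1.0
        assert a.fraction_anticipating == 100.0

    def test_half_ratio_arithmetic(self):
        assert slope_stats.sync_ratio(0.19, 0.38) == pytest.approx(0.5)

    def test_nonpositive_theoretical_slope_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            slope_stats.sync_ratio(0.1, 0.0)


class TestClassifier:
    def test_half_rule_flags_and_fraction(self):
        flags, frac = slope_stats.classify_anticipation(
            [0.1, 0.2, 0.3], 0.25)
        assert flags.tolist() == [False, True, True]
        assert frac == pytest.approx(200 / 3)

    def test_all_identical_is_100_percent(self):
        flags, frac = slope_stats.classify_anticipation([0.2] * 5, 0.2)
        assert frac == 100.0

    def test_nonpositive_slopes_none_anticipate(self):
        _, frac = slope_stats.classify_anticipation([-0.1, 0.0, -0.3], 0.4)
        assert frac == 0.0


class TestDownhill:
    def make_decreasing_day(self, n=6):
        vals = np.linspace(100, 10, 8)
        return pd.DataFrame({f"f{i}": vals for i in range(n)},
                            index=np.arange(8) * 30)

    def test_identical_decreasing_flies(self):
        day = self.make_decreasing_day()
        a = slope_stats.downhill_analysis(day, (0, 240))
        assert a.mode == "downhill"
        assert a.zt_max < a.zt_min
        assert a.slo_the < 0
        assert a.ratio == pytest.approx(1.0)
        assert a.fraction_anticipating == 100.0

    def test_flat_flies_rejected(self):
        day = pd.DataFrame({"a": [5.0] * 8, "b": [5.0] * 8},
                           index=np.arange(8) * 30)
        with pytest.raises(LandmarkError, match="no anticipation structure"):
            slope_stats.downhill_analysis(day, (0, 240))

    def test_shallow_decliners_fail_the_steepness_rule(self):
        steep = np.linspace(100, 10, 8)
        shallow = np.linspace(100, 90, 8)
        day = pd.DataFrame({"s1": steep, "s2": steep, "s3": steep,
                            "w1": shallow, "w2": shallow},
                           index=np.arange(8) * 30)
        a = slope_stats.downhill_analysis(day, (0, 240))
        assert a.anticipating[["s1", "s2", "s3"]].all()
        assert not a.anticipating[["w1", "w2"]].any()


class TestGroupCompare:
    def test_identical_groups_h_near_zero_ci_covers_zero(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        out = slope_stats.group_compare(g, n_boot=500, seed=0)
        assert out.h == pytest.approx(0.0, abs=1e-9)
        pw = out.pairwise[0]
        assert pw["ci_low"] <= 0.0 <= pw["ci_high"]

    def test_h_matches_textbook_rank_formula(self):
        groups = [[2.1, 3.5, 1.2, 4.4], [5.0, 3.5, 6.1], [0.5, 2.1, 7.7, 2.1]]
        named = {str(i): g for i, g in enumerate(groups)}
        out = slope_stats.group_compare(named, n_boot=10, seed=0)
        assert out.h == pytest.approx(ref_kruskal_h(groups), rel=1e-12)
        assert out.p == pytest.approx(sps.chi2.sf(out.h, 2), rel=1e-12)

    def test_translation_equivariance_of_bootstrap_difference(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 20).tolist()
        b = rng.normal(0, 1, 20).tolist()
        delta = 2.5
        out1 = slope_stats.group_compare({"a": a, "b": b},
                                         n_boot=2000, seed=7)
        out2 = slope_stats.group_compare({"a": a,
                                          "b": [x + delta for x in b]},
                                         n_boot=2000, seed=7)
        p1, p2 = out1.pairwise[0], out2.pairwise[0]
        assert p2["mean_diff"] - p1["mean_diff"] == pytest.approx(delta)
        assert p2["ci_low"] - p1["ci_low"] == pytest.approx(delta, abs=1e-9)
        assert p2["ci_high"] - p1["ci_high"] == pytest.approx(delta, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            slope_stats.group_compare({"a": [1.0], "b": [1.0, 2.0]})

    def test_permutation_p_close_to_chi2_on_moderate_samples(self):
        rng = np.random.default_rng(14)
        g = {"a": rng.normal(0, 1, 8).tolist(),
             "b": rng.normal(1.0, 1, 8).tolist()}
        out = slope_stats.group_compare(g, n_boot=10, seed=1,
                                        method="permutation", n_perm=2000)
        assert 0.0 < out.p < 1.0
        assert out.method == "permutation"


class TestBoxSummary:
    def test_quartiles_match_sort_oracle(self):
        rng = np.random.default_rng(15)
        vals = rng.normal(0, 1, 37)
        s = slope_stats.box_summary(vals)
        assert s["q1"] == pytest.approx(np.percentile(vals, 25))
        assert s["median"] == pytest.approx(np.median(vals))
        assert s["q3"] == pytest.approx(np.percentile(vals, 75))

    def test_tukey_whiskers_exclude_outliers(self):
        vals = list(np.linspace(0, 1, 20)) + [10.0]
        s = slope_stats.box_summary(vals)
        assert s["whisker_high"] == 1.0
        assert s["outliers"] == [10.0]

    def test_degenerate_all_equal(self):
        s = slope_stats.box_summary([3.0, 3.0, 3.0])
        assert s["q1"] == s["median"] == s["q3"] == 3.0
        assert s["whisker_low"] == s["whisker_high"] == 3.0
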