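"""CVR metric extraction and group statistics."""

import numpy as np
import pandas as pd
import pytest

from vasoreact import cvr, pipeline, synth
from vasoreact.cvr import (cvr_metrics, group_ttest, integrated_reactivity,
                           peak_response, recovery_time, sex_by_group_anova,
                           smooth_trace)

T_INJECT = 600.0
BASELINE = (0.0, 600.0)


def _grid(total_min: float = 40.0, dt_s: float = 1.0) -> np.ndarray:
    return np.arange(0.0, total_min * 60.0 + 1e-9, dt_s)


class TestPeakResponse:
    def test_flat_trace_zero(self):
        t = _grid()
        assert peak_response(t, np.zeros_like(t), T_INJECT) == 0.0

    def test_known_dip_depth(self):
        t = _grid()
        y = np.zeros_like(t)
        y[(t > T_INJECT + 60) & (t < T_INJECT + 300)] = -16.37
        assert peak_response(t, y, T_INJECT, smooth_window_s=0) == pytest.approx(-16.37)

    def test_equals_exhaustive_scan_of_smoothed_trace(self):
        rng = np.random.default_rng(3)
        t = _grid(dt_s=2.0)
        y = -10 * np.exp(-((t - 1200) / 300.0) ** 2) + rng.standard_normal(t.size)
        ys = smooth_trace(t, y, 30.0)
        brute = min(ys[i] for i in range(t.size) if t[i] > T_INJECT)
        assert peak_response(t, y, T_INJECT) == pytest.approx(brute)

    def test_no_post_injection_samples_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            peak_response(t, np.zeros_like(t), 1e5)


class TestRecoveryTime:
    def test_step_dip_recovering_at_five_minutes(self):
        t = _grid()
        y = np.zeros_like(t)
        y[(t > T_INJECT) & (t < T_INJECT + 300.0)] = -10.0
        # deterministic baseline wiggle so the band has a finite width
        wiggle = 0.1 * np.where(np.arange(t.size) % 2 == 0, 1.0, -1.0)
        y = y + np.where(t <= T_INJECT, wiggle, 0.0)
        rt, recovered, _ = recovery_time(t, y, T_INJECT, BASELINE,
                                         smooth_window_s=0.0)
        assert recovered
        assert rt == pytest.approx(5.0, abs=1.5 / 60.0)

    def test_exponential_recovery_matches_closed_form(self):
        """Dip -A exp(-(t - t_nadir)/tau) crosses mean - k*sd at
        t_nadir + tau ln(A / (k s)), within one sample interval."""
        t = _grid(dt_s=1.0)
        A, tau, t_nadir = 12.0, 240.0, T_INJECT + 120.0
        wiggle = 0.2 * np.where(np.arange(t.size) % 2 == 0, 1.0, -1.0)
        y = wiggle.copy()
        dip = (t > T_INJECT) & (t < t_nadir)
        y[dip] = -A
        fall = t >= t_nadir
        y[fall] = -A * np.exp(-(t[fall] - t_nadir) / tau)
        s = np.std(wiggle[(t >= BASELINE[0]) & (t <= BASELINE[1])], ddof=1)
        expected = (t_nadir - T_INJECT + tau * np.log(A / s)) / 60.0
        rt, recovered, _ = recovery_time(t, y, T_INJECT, BASELINE, k=1.0,
                                         smooth_window_s=0.0)
        assert recovered
        assert rt == pytest.approx(expected, abs=1.5 / 60.0)

    def test_no_response_reports_zero_with_note(self):
        t = _grid()
        wiggle = 0.1 * np.where(np.arange(t.size) % 2 == 0, 1.0, -1.0)
        rt, recovered, note = recovery_time(t, wiggle, T_INJECT, BASELINE)
        assert rt == 0.0 and recovered and "no response" in note

    def test_never_recovering_spans_record(self):
        t = _grid()
        y = 0.1 * np.where(np.arange(t.size) % 2 == 0, 1.0, -1.0)
        y[t > T_INJECT] = -20.0
        rt, recovered, _ = recovery_time(t, y, T_INJECT, BASELINE)
        assert not recovered
        assert rt == pytest.approx((t[-1] - T_INJECT) / 60.0)


class TestIntegratedReactivity:
    def test_zero_trace(self):
        t = _grid()
        assert integrated_reactivity(t, np.zeros_like(t), T_INJECT, 10.0) == 0.0

    def test_nonpositive_rt_gives_zero(self):
        t = _grid()
        assert integrated_reactivity(t, np.ones_like(t), T_INJECT, 0.0) == 0.0

    def test_rectangular_dip_closed_form(self):
        """Depth -10%, duration 5 min -> -50 %·min."""
        t = _grid()
        y = np.zeros_like(t)
        y[(t >= T_INJECT) & (t <= T_INJECT + 300.0)] = -10.0
        ir = integrated_reactivity(t, y, T_INJECT, 5.0, smooth_window_s=0.0)
        assert ir == pytest.approx(-50.0)

    def test_triangular_dip_closed_form(self):
        """Depth -10% at the apex, 10-min base -> -50 %·min."""
        t = _grid()
        y = np.zeros_like(t)
        up = (t >= T_INJECT) & (t <= T_INJECT + 300.0)
        down = (t > T_INJECT + 300.0) & (t <= T_INJECT + 600.0)
        y[up] = -10.0 * (t[up] - T_INJECT) / 300.0
        y[down] = -10.0 * (1.0 - (t[down] - T_INJECT - 300.0) / 300.0)
        ir = integrated_reactivity(t, y, T_INJECT, 10.0, smooth_window_s=0.0)
        assert ir == pytest.approx(-50.0)


class TestMetricInvariances:
    def _noisy_transient(self, seed=0):
        t = _grid(dt_s=2.0)
        rng = np.random.default_rng(seed)
        y = synth.build_cvr_trace(t, T_INJECT, -14.0, 12.0, -90.0, 0.3)
        return t, y + 0.3 * rng.standard_normal(t.size)

    def test_scale_equivariance_of_peak_and_ir(self):
        t, y = self._noisy_transient()
        m1 = cvr_metrics(t, y, T_INJECT, BASELINE)
        m2 = cvr_metrics(t, 3.0 * y, T_INJECT, BASELINE)
        assert m2.peak_response_pct == pytest.approx(3 * m1.peak_response_pct)
        # the baseline band scales with the trace, so RT is unchanged and
        # IR scales with the trace
        assert m2.recovery_time_min == pytest.approx(m1.recovery_time_min)
        assert m2.integrated_reactivity == pytest.approx(
            3 * m1.integrated_reactivity, rel=1e-9)

    def test_time_shift_invariance(self):
        t, y = self._noisy_transient()
        shift = 240.0
        m1 = cvr_metrics(t, y, T_INJECT, BASELINE)
        m2 = cvr_metrics(t + shift, y, T_INJECT + shift,
                         (BASELINE[0] + shift, BASELINE[1] + shift))
        assert m2.peak_response_pct == pytest.approx(m1.peak_response_pct)
        assert m2.recovery_time_min == pytest.approx(m1.recovery_time_min)
        assert m2.integrated_reactivity == pytest.approx(m1.integrated_reactivity)

    def test_zero_tail_extension_changes_nothing(self):
        t, y = self._noisy_transient()
        m1 = cvr_metrics(t, y, T_INJECT, BASELINE)
        dt = t[1] - t[0]
        t2 = np.concatenate([t, t[-1] + dt * np.arange(1, 301)])
        y2 = np.concatenate([y, np.zeros(300)])
        m2 = cvr_metrics(t2, y2, T_INJECT, BASELINE)
        assert m2.peak_response_pct == pytest.approx(m1.peak_response_pct)
        assert m2.recovery_time_min == pytest.approx(m1.recovery_time_min)
        assert m2.integrated_reactivity == pytest.approx(
            m1.integrated_reactivity, rel=1e-6)

    def test_prepending_baseline_frames_changes_nothing(self):
        """Extra constant-baseline history does not move any metric."""
        t, y = self._noisy_transient()
        dt = t[1] - t[0]
        n_pre = 150
        t2 = np.concatenate([t, t[-1] + dt * np.arange(1, n_pre + 1)])
        y2 = np.concatenate([np.zeros(n_pre), y])
        shift = n_pre * dt
        m1 = cvr_metrics(t, y, T_INJECT, BASELINE)
        m2 = cvr_metrics(t2, y2, T_INJECT + shift,
                         (BASELINE[0], BASELINE[1] + shift))
        assert m2.peak_response_pct == pytest.approx(m1.peak_response_pct)
        assert m2.recovery_time_min == pytest.approx(m1.recovery_time_min,
                                                     abs=2 * dt / 60.0)


class TestGroupTtest:
    def test_identical_groups(self):
        t, df, p = group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        t, df, p = group_ttest([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert df == 4
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_degenerate_zero_variance(self):
        t, df, p = group_ttest([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0
        with pytest.raises(ValueError, match="zero pooled variance"):
            group_ttest([2.0, 2.0], [3.0, 3.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([1.0], [2.0, 3.0])


class TestSexByGroupAnova:
    @staticmethod
    def _table(cells: dict) -> pd.DataFrame:
        rows = []
        for (sex, group), vals in cells.items():
            rows += [{"sex": sex, "group": group, "value": v} for v in vals]
        return pd.DataFrame(rows)

    def test_hand_computed_sums_of_squares(self):
        """Balanced 2x2, n=2 per cell; F = MS_effect / MS_error with
        MS_error = 2: F_sex = 9, F_group = 36, F_interaction = 4."""
        tab = self._table({("M", "WT"): [1, 3], ("M", "AD"): [5, 7],
                           ("F", "WT"): [2, 4], ("F", "AD"): [10, 12]})
        res = sex_by_group_anova(tab)
        aov = res["anova"]
        assert aov.loc["C(sex)", "F"] == pytest.approx(9.0, abs=1e-10)
        assert aov.loc["C(group)", "F"] == pytest.approx(36.0, abs=1e-10)
        assert aov.loc["C(sex):C(group)", "F"] == pytest.approx(4.0, abs=1e-10)
        assert len(res["pairwise"]) == 4
        assert (res["pairwise"]["p_bonferroni"] <=
                np.minimum(1.0, res["pairwise"]["p"] * 4 + 1e-12)).all()

    def test_equal_cell_means_give_zero_f(self):
        tab = self._table({("M", "WT"): [1, 3], ("M", "AD"): [0, 4],
                           ("F", "WT"): [2 - 1, 2 + 1], ("F", "AD"): [0, 4]})
        res = sex_by_group_anova(tab)
        aov = res["anova"]
        for eff in ("C(sex)", "C(group)", "C(sex):C(group)"):
            assert aov.loc[eff, "F"] == pytest.approx(0.0, abs=1e-10)
            assert aov.loc[eff, "PR(>F)"] == pytest.approx(1.0)

    def test_factor_swap_leaves_interaction_unchanged(self):
        tab = self._table({("M", "WT"): [1, 3], ("M", "AD"): [5, 7],
                           ("F", "WT"): [2, 4], ("F", "AD"): [10, 12]})
        res1 = sex_by_group_anova(tab)
        swapped = tab.rename(columns={"sex": "group", "group": "sex"})
        res2 = sex_by_group_anova(swapped)
        assert (res1["anova"].loc["C(sex):C(group)", "F"]
                == pytest.approx(res2["anova"].loc["C(sex):C(group)", "F"]))

    def test_empty_cell_rejected(self):
        tab = self._table({("M", "WT"): [1, 3], ("M", "AD"): [5, 7],
                           ("F", "WT"): [2, 4]})
        with pytest.raises(ValueError, match="cell"):
            sex_by_group_anova(tab)


class TestCohortParameterRecovery:
    def test_rt_estimator_unbiased_at_scale(self):
        """Over 1,000 WT-artery animals the extracted recovery-time mean
        sits within 0.5 min of the configured 14.96 min."""
        spec = synth.default_cohort_spec(seed=77, parts=("cvr",))
        spec.cvr = {g: {"artery": spec.cvr[g]["artery"]} for g in ("WT", "AD")}
        spec.n_cvr = {"WT": 1000, "AD": 2}
        co = synth.gen_cohort(spec)
        est = pipeline.extract_cvr_metrics(co)
        rt = est[(est.group == "WT") & (est.metric == "rt")]["value"]
        assert rt.mean() == pytest.approx(14.96, abs=0.5)

    def test_group_means_track_generator_truth(self):
        """On cohort defaults, extracted group means of peak/IR/RT land
        within 2 SEM of the drawn generator truth in >= 90% of seeds."""
        hits = total = 0
        for seed in range(12):
            co = synth.gen_cohort(synth.default_cohort_spec(
                seed=seed, parts=("cvr",)))
            est = pipeline.extract_cvr_metrics(co)
            merged = est.merge(
                co.truth, on=["animal_id", "group", "sex", "roi_class",
                              "metric"], suffixes=("_est", "_true"))
            g = merged.groupby(["group", "roi_class", "metric"])
            for _, sub in g:
                sem = sub["value_est"].std(ddof=1) / np.sqrt(len(sub))
                total += 1
                if abs(sub["value_est"].mean()
                       - sub["value_true"].mean()) <= 2 * sem:
                    hits += 1
        assert hits / total >= 0.9
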