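import dataclasses

import numpy as np
import pytest

from myolabel import (biomechanical_coupling, build_schedule, label_quality_report,
                      magnitude_error_stats, rest_drift, simulate_participant,
                      timing_error_stats, trace_rmse, uniform_coupling)
from myolabel.kinematics import KinematicTrace, trapezoid
from myolabel.simulate import SessionData
from conftest import single_knob_params


def _shift_trace(trace, k):
    vals = np.zeros_like(trace.values)
    if k >= 0:
        vals[k:] = trace.values[:len(vals) - k]
    else:
        vals[:k] = trace.values[-k:]
    return KinematicTrace(vals, trace.rate, list(trace.trial_boundaries))


class TestNoiseFreeZeroes:
    def test_all_metrics_zero(self, noise_free_session):
        s = noise_free_session
        assert biomechanical_coupling(s) == 0.0
        assert rest_drift(s) == 0.0
        for paradigm in ("mimic", "mirror"):
            rep = label_quality_report(s, paradigm)
            assert rep.mag_err_mean_pct == 0.0
            assert rep.mag_err_disp_pct == 0.0
            assert rep.timing_err_mean_ms == 0.0
            assert rep.timing_err_disp_ms == 0.0
            assert rep.rmse == 0.0


class TestCoupling:
    def test_uniform_coupling_matches_hand_computed_trapezoid_mean(self, small_schedule):
        c = 0.10
        p = single_knob_params(1, coupling_matrix=uniform_coupling(c))
        sess = simulate_participant(small_schedule, p, compute_emg=False)
        # leaked profile = c * trapezoid; mean |.| over the 45-sample movement
        expect = c * trapezoid(21, 3).mean() * 100
        assert biomechanical_coupling(sess) == pytest.approx(expect, rel=1e-9)

    def test_coupling_is_paradigm_invariant(self, healthy_session):
        a = label_quality_report(healthy_session, "mimic")
        b = label_quality_report(healthy_session, "mirror")
        assert a.coupling_pct == b.coupling_pct
        assert a.drift_pct == b.drift_pct


class TestDrift:
    def test_deterministic_step_drift_reads_five_percent(self, small_schedule):
        sess = simulate_participant(small_schedule, single_knob_params(0),
                                    compute_emg=False)
        # inject a +0.05 offset on all DOFs after the first trial
        vals = sess.truth.values.copy()
        first_end = sess.truth.trial_boundaries[0][3]
        vals[first_end:] += 0.05
        truth = KinematicTrace(vals, 30.0, list(sess.truth.trial_boundaries))
        sess2 = SessionData(schedule=sess.schedule, virtual=sess.virtual, truth=truth,
                            mirror=truth, emg=None, params=sess.params)
        assert rest_drift(sess2) == pytest.approx(5.0, rel=1e-9)

    def test_no_rest_interval_rejected(self, noise_free_session):
        bad = dataclasses.replace(
            noise_free_session,
            truth=KinematicTrace(noise_free_session.truth.values, 30.0,
                                 [(0, 0, 45, 45)]))
        with pytest.raises(ValueError, match="rest"):
            rest_drift(bad)


class TestMagnitudeError:
    def test_scaled_labels_give_ten_percent(self, noise_free_session):
        s = noise_free_session
        labels = KinematicTrace(0.9 * s.truth.values, 30.0, list(s.truth.trial_boundaries))
        mean, disp = magnitude_error_stats(labels, s.truth, s.schedule)
        assert mean == pytest.approx(10.0, rel=1e-9)
        assert disp == pytest.approx(0.0, abs=1e-9)

    def test_random_per_trial_scales_match_enumeration(self, rng):
        sch = build_schedule("biomech", 1)
        sess = simulate_participant(sch, single_knob_params(0), compute_emg=False)
        scales = 1 - rng.uniform(0.0, 0.3, sch.n_trials)
        vals = sess.truth.values.copy()
        for s_, (lo, onset, me, e) in zip(scales, sess.truth.trial_boundaries):
            vals[onset:me] *= s_
        labels = KinematicTrace(vals, 30.0, list(sess.truth.trial_boundaries))
        mean, disp = magnitude_error_stats(labels, sess.truth, sch)
        expect = np.abs(1 - scales) * 100
        assert mean == pytest.approx(expect.mean(), rel=1e-9)
        assert disp == pytest.approx(expect.std(ddof=1), rel=1e-9)

    def test_invariant_under_common_time_shift(self, healthy_session):
        s = healthy_session
        a = magnitude_error_stats(s.mirror, s.truth, s.schedule)
        b = magnitude_error_stats(_shift_trace(s.mirror, 2), _shift_trace(s.truth, 2),
                                  s.schedule)
        assert a[0] == pytest.approx(b[0], rel=1e-6)


class TestTimingError:
    def test_two_sample_delay_reads_66_7_ms(self, noise_free_session):
        s = noise_free_session
        labels = _shift_trace(s.truth, 2)
        mean, disp = timing_error_stats(labels, s.truth, s.schedule)
        assert mean == pytest.approx(2 / 30 * 1000, rel=1e-9)
        assert disp == pytest.approx(0.0, abs=1e-9)

    def test_pure_delay_shifts_mean_additively(self, noise_free_session):
        s = noise_free_session
        m1, _ = timing_error_stats(_shift_trace(s.truth, 1), s.truth, s.schedule)
        m3, _ = timing_error_stats(_shift_trace(s.truth, 3), s.truth, s.schedule)
        assert m3 - m1 == pytest.approx(2 / 30 * 1000, rel=1e-9)


class TestRMSE:
    def test_identical_traces_zero(self, noise_free_session):
        assert trace_rmse(noise_free_session.truth, noise_free_session.truth) == 0.0

    def test_constant_offset_closed_form(self, noise_free_session):
        s = noise_free_session
        labels = KinematicTrace(s.truth.values + 0.1, 30.0, list(s.truth.trial_boundaries))
        assert trace_rmse(labels, s.truth) == pytest.approx(0.1, rel=1e-12)

    def test_shape_mismatch_rejected(self, noise_free_session):
        s = noise_free_session
        short = KinematicTrace(s.truth.values[:-5], 30.0, [])
        with pytest.raises(ValueError, match="shape"):
            trace_rmse(short, s.truth)


class TestReportComposition:
    def test_report_fields_equal_individual_operations(self, healthy_session):
        s = healthy_session
        rep = label_quality_report(s, "mirror")
        assert rep.coupling_pct == biomechanical_coupling(s)
        assert rep.drift_pct == rest_drift(s)
        mean, disp = magnitude_error_stats(s.mirror, s.truth, s.schedule)
        assert (rep.mag_err_mean_pct, rep.mag_err_disp_pct) == (mean, disp)
        assert rep.rmse == trace_rmse(s.mirror, s.truth)
        assert rep.n_trials == s.schedule.n_trials

    def test_all_metrics_nonnegative(self, healthy_session):
        for paradigm in ("mimic", "mirror"):
            rep = label_quality_report(healthy_session, paradigm)
            assert rep.coupling_pct >= 0 and rep.drift_pct >= 0
            assert rep.mag_err_mean_pct >= 0 and rep.mag_err_disp_pct >= 0
            assert rep.timing_err_disp_ms >= 0 and rep.rmse >= 0
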