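import dataclasses

import numpy as np
import pytest

from myolabel import (build_schedule, make_params, noise_free_params,
                      simulate_participant, synthesize_emg, uniform_coupling,
                      sample_cohort)
from myolabel.kinematics import KinematicTrace
from conftest import single_knob_params


class TestNoiseFreeLimit:
    def test_truth_equals_virtual_equals_mirror(self, noise_free_session):
        s = noise_free_session
        np.testing.assert_array_equal(s.truth.values, s.virtual.values)
        np.testing.assert_array_equal(s.mirror.values, s.truth.values)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_schedule):
        p = make_params("paper_healthy", seed=11)
        a = simulate_participant(small_schedule, p)
        b = simulate_participant(small_schedule, p)
        np.testing.assert_array_equal(a.truth.values, b.truth.values)
        np.testing.assert_array_equal(a.mirror.values, b.mirror.values)
        np.testing.assert_array_equal(a.emg.values, b.emg.values)

    def test_different_seed_differs(self, small_schedule):
        a = simulate_participant(small_schedule, make_params("paper_healthy", seed=1))
        b = simulate_participant(small_schedule, make_params("paper_healthy", seed=2))
        assert not np.array_equal(a.truth.values, b.truth.values)

    def test_cohort_sampling_deterministic(self):
        a = sample_cohort("paper_healthy", 3, seed=5)
        b = sample_cohort("paper_healthy", 3, seed=5)
        for pa, pb in zip(a, b):
            assert pa.seed == pb.seed
            np.testing.assert_array_equal(pa.coupling_matrix, pb.coupling_matrix)


class TestCouplingInjection:
    def test_single_movement_peak_leakage_equals_c(self, small_schedule):
        c = 0.13
        p = single_knob_params(3, coupling_matrix=uniform_coupling(c))
        sess = simulate_participant(small_schedule, p, compute_emg=False)
        sch = sess.schedule
        # first trial is individuated D1 flexion; every non-target DOF peaks at c
        (m, _), (s, onset, me, e) = next(zip(sch.trials, sess.truth.trial_boundaries))
        assert not m.is_combination
        nontarget = [d for d in range(8) if d not in m.directions]
        peaks = np.abs(sess.truth.values[onset:me, nontarget]).max(axis=0)
        np.testing.assert_allclose(peaks, c, rtol=1e-12)

    def test_no_leakage_into_combination_targets(self, small_schedule):
        p = single_knob_params(3, coupling_matrix=uniform_coupling(0.3))
        sess = simulate_participant(small_schedule, p, compute_emg=False)
        for (m, _), (s, onset, me, e) in zip(sess.schedule.trials,
                                             sess.truth.trial_boundaries):
            if m.is_combination:
                for dof in m.directions:
                    assert np.abs(sess.truth.values[onset:me, dof]).max() == 1.0


class TestLagAndJitter:
    def test_excessive_lag_rejected(self, small_schedule):
        p = single_knob_params(0, mimic_lag_mean_s=1.5)
        with pytest.raises(ValueError, match="inter-trial"):
            simulate_participant(small_schedule, p, compute_emg=False)

    def test_positive_lag_delays_truth(self, small_schedule):
        p = single_knob_params(0, mimic_lag_mean_s=0.2)  # exactly 6 samples
        sess = simulate_participant(small_schedule, p, compute_emg=False)
        shift = round(0.2 * 30)
        v, t = sess.virtual.values, sess.truth.values
        np.testing.assert_allclose(t[shift:], v[:-shift], atol=1e-12)


class TestEMGSurrogate:
    def test_rest_mav_converges_to_half_normal_mean(self):
        # constant zero kinematics: expected MAV = baseline * sqrt(2/pi)
        p = noise_free_params(0)
        trace = KinematicTrace(np.zeros((3000, 8)), 30.0, [])
        emg = synthesize_emg(trace, p, rng=np.random.default_rng(0))
        mav = np.abs(emg.values).mean(axis=0)
        np.testing.assert_allclose(mav, p.emg_baseline * np.sqrt(2 / np.pi), rtol=0.02)

    def test_mav_linear_in_synergy_gain(self, rng):
        p = noise_free_params(0)
        p = dataclasses.replace(p, emg_baseline=np.zeros(32))
        p2 = dataclasses.replace(p, synergy_gain_pos=2 * p.synergy_gain_pos,
                                 synergy_gain_neg=2 * p.synergy_gain_neg)
        trace = KinematicTrace(np.clip(rng.standard_normal((2000, 8)), -1, 1), 30.0, [])
        m1 = np.abs(synthesize_emg(trace, p, rng=np.random.default_rng(1)).values).mean(axis=0)
        m2 = np.abs(synthesize_emg(trace, p2, rng=np.random.default_rng(1)).values).mean(axis=0)
        np.testing.assert_allclose(m2, 2 * m1, rtol=1e-10)

    def test_zero_baseline_zero_gain_gives_silence(self):
        p = noise_free_params(0)
        p = dataclasses.replace(p, emg_baseline=np.zeros(32),
                                synergy_gain_pos=np.zeros((32, 8)),
                                synergy_gain_neg=np.zeros((32, 8)))
        trace = KinematicTrace(np.zeros((300, 8)), 30.0, [])
        emg = synthesize_emg(trace, p, rng=np.random.default_rng(2))
        assert np.all(emg.values == 0.0)


class TestParamValidation:
    @pytest.mark.parametrize("field,value", [
        ("drift_step_sd", -0.1),
        ("mimic_lag_sd_s", -1.0),
        ("coupling_matrix", np.full((8, 8), 0.1)),   # nonzero diagonal
        ("synergy_gain_pos", -np.ones((32, 8))),
    ])
    def test_bad_params_rejected(self, field, value):
        with pytest.raises(ValueError):
            single_knob_params(0, **{field: value})

    def test_traces_clipped_to_unit_range(self, small_schedule):
        p = make_params("paper_healthy", seed=4)
        sess = simulate_participant(small_schedule, p, compute_emg=False)
        for tr in (sess.truth, sess.mirror):
            assert np.abs(tr.values).max() <= 1.0
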