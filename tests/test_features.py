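import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myolabel import (build_schedule, compute_mav_features, estimate_lag_crosscorr,
                      estimate_normalization, normalize_trace, denormalize_trace,
                      align_labels_crosscorr, preprogrammed_profile)
from myolabel.features import FeatureMatrix
from oracles import brute_force_mav


class TestMAVChannels:
    def test_32_channels_yield_528_columns(self, rng):
        raw = rng.standard_normal((1000, 32))
        fm = compute_mav_features(raw, raw_rate_hz=1000.0)
        assert fm.n_channels == 528
        assert fm.channel_names[0] == "e0"
        assert fm.channel_names[32] == "e0-e1"
        assert fm.channel_names[-1] == "e30-e31"

    def test_two_channel_reduced_mode(self, rng):
        fm = compute_mav_features(rng.standard_normal((500, 2)), raw_rate_hz=1000.0)
        assert fm.n_channels == 3

    def test_constant_signal_single_ended_and_differential(self):
        raw = np.full((600, 4), -1.7)
        fm = compute_mav_features(raw, raw_rate_hz=1000.0)
        np.testing.assert_allclose(fm.values[:, :4], 1.7)
        np.testing.assert_allclose(fm.values[:, 4:], 0.0)

    def test_window_below_one_sample_rejected(self, rng):
        with pytest.raises(ValueError, match="window"):
            compute_mav_features(rng.standard_normal((100, 2)),
                                 window_s=1e-4, raw_rate_hz=1000.0)


class TestMAVOracle:
    def test_matches_brute_force_on_random_signal(self, rng):
        raw = rng.standard_normal((2000, 6))
        fm = compute_mav_features(raw, raw_rate_hz=1000.0)
        expect = brute_force_mav(raw, 1000.0, 0.3, 30.0)
        np.testing.assert_allclose(fm.values, expect, rtol=1e-9, atol=1e-12)

    def test_shift_equivariance_away_from_edges(self, rng):
        raw = rng.standard_normal((3000, 3))
        k = 100  # 3 output samples at 30 Hz for a 1 kHz raw stream
        delayed = np.vstack([np.zeros((k, 3)), raw[:-k]])
        a = compute_mav_features(raw, raw_rate_hz=1000.0).values
        b = compute_mav_features(delayed, raw_rate_hz=1000.0).values
        shift_out = 3
        np.testing.assert_allclose(b[12:], a[12 - shift_out:-shift_out], rtol=1e-9)

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_absolute_homogeneity(self, scale):
        rng = np.random.default_rng(7)
        raw = rng.standard_normal((800, 3))
        a = compute_mav_features(raw, raw_rate_hz=1000.0).values
        b = compute_mav_features(scale * raw, raw_rate_hz=1000.0).values
        np.testing.assert_allclose(b, scale * a, rtol=1e-9)


class TestNormalization:
    def test_constant_trace_baseline_exact(self):
        trace = np.full((600, 8), 0.37)
        p = estimate_normalization(trace, rate_hz=30.0,
                                   extremes=(np.full(8, 2.0), np.full(8, -1.0)))
        np.testing.assert_allclose(p.rest_baseline, 0.37)

    def test_noisy_baseline_converges(self, rng):
        theta0 = 1.2
        trace = theta0 + 0.1 * rng.standard_normal((30 * 60, 8))
        p = estimate_normalization(trace, rate_hz=30.0, rest_window_s=60.0,
                                   extremes=(np.full(8, 3.0), np.full(8, 0.0)))
        np.testing.assert_allclose(p.rest_baseline, theta0, atol=0.02)

    def test_rest_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="rest window"):
            estimate_normalization(np.zeros((10, 8)), rate_hz=30.0, rest_window_s=15.0)

    def test_endpoints_and_midpoint(self):
        p = estimate_normalization(np.full((450, 1), 10.0), rate_hz=30.0,
                                   extremes=(np.array([30.0]), np.array([-10.0])))
        out = normalize_trace(np.array([[10.0], [30.0], [-10.0], [20.0]]), p)
        np.testing.assert_allclose(out.ravel(), [0.0, 1.0, -1.0, 0.5])

    @settings(deadline=None, max_examples=30)
    @given(v=st.floats(min_value=-1.0, max_value=1.0))
    def test_normalize_denormalize_roundtrip(self, v):
        p = estimate_normalization(np.full((450, 1), 5.0), rate_hz=30.0,
                                   extremes=(np.array([12.0]), np.array([-3.0])))
        angle = denormalize_trace(np.array([[v]]), p)
        np.testing.assert_allclose(normalize_trace(angle, p), v, atol=1e-12)


class TestLagAlignment:
    @staticmethod
    def _streams(shift_samples: float, rng):
        labels = preprogrammed_profile(build_schedule("biomech", 1))
        env = np.abs(labels.values).sum(axis=1, keepdims=True)
        grid = np.arange(env.shape[0], dtype=float)
        shifted = np.interp(grid - shift_samples, grid, env[:, 0], left=0, right=0)
        feats = shifted[:, None] + 0.01 * rng.standard_normal((env.shape[0], 4))
        return labels, FeatureMatrix(feats, 30.0, [f"e{i}" for i in range(4)])

    def test_recovers_injected_shift(self, rng):
        labels, feats = self._streams(4.0, rng)  # features trail by 133 ms
        lag = estimate_lag_crosscorr(labels.values, feats.values, 30.0)
        assert lag == 4

    def test_zero_shift_gives_zero_lag(self, rng):
        labels, feats = self._streams(0.0, rng)
        assert estimate_lag_crosscorr(labels.values, feats.values, 30.0) == 0

    def test_constant_labels_tie_break_to_zero(self):
        labels = np.ones((300, 8))
        feats = np.ones((300, 4))
        assert estimate_lag_crosscorr(labels, feats, 30.0) == 0

    def test_align_trims_edges_and_reports_seconds(self, rng):
        labels, feats = self._streams(3.0, rng)
        aligned, lag_s = align_labels_crosscorr(labels, feats)
        assert lag_s == pytest.approx(0.1)
        assert aligned.n_samples == labels.n_samples - 3
        # aligned label sample t pairs with feature sample t + 3
        np.testing.assert_allclose(
            np.abs(aligned.values).sum(axis=1), feats.values[3:, 0], atol=0.1)

    def test_max_lag_too_large_rejected(self):
        with pytest.raises(ValueError, match="max_lag"):
            estimate_lag_crosscorr(np.ones((20, 8)), np.ones((20, 4)), 30.0, max_lag_s=0.5)
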