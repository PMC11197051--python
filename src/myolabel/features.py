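"""EMG mean-absolute-value features, joint-angle normalization and
cross-correlation label alignment.

The feature stream is the 300-ms smoothed MAV computed at 30 Hz for the 32
single-ended electrodes and for all C(32,2) = 496 differential pairs,
528 channels in total. Differential channels are formed on the raw signal
(x_i - x_j, i < j) and then rectified and averaged -- not as differences of
single-ended MAVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import KinematicTrace
from .simulate import RawEMG


@dataclass
class FeatureMatrix:
    """Time x channel matrix of nonnegative MAV features at ``rate`` Hz."""

    values: np.ndarray
    rate: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def pair_names(n: int) -> list[str]:
    return [f"e{i}-e{j}" for i in range(n) for j in range(i + 1, n)]


def _window_bounds(n_raw: int, raw_rate: float, window_s: float, out_rate: float,
                   center: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-output-sample [lo, hi) raw-index bounds of the MAV window."""
    w = round(window_s * raw_rate)
    if w < 1:
        raise ValueError("window shorter than one raw sample")
    n_out = int(np.floor((n_raw - 1) * out_rate / raw_rate)) + 1
    anchors = np.round(np.arange(n_out) * raw_rate / out_rate).astype(np.int64)
    anchors = np.minimum(anchors, n_raw - 1)
    if center:
        lo = np.maximum(anchors - w // 2, 0)
        hi = np.minimum(anchors + (w - w // 2), n_raw)
    else:  # trailing (causal) window, shorter at stream start
        lo = np.maximum(anchors - w + 1, 0)
        hi = anchors + 1
    return lo, hi


def _windowed_mav(absx: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Mean of ``absx`` (time x channel) over [lo, hi) per output sample."""
    csum = np.vstack([np.zeros((1, absx.shape[1])), np.cumsum(absx, axis=0)])
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def compute_mav_features(raw: RawEMG | np.ndarray, window_s: float = 0.3,
                         out_rate_hz: float = 30.0, pairs: bool = True,
                         center: bool = False, raw_rate_hz: float | None = None,
                         pair_chunk: int = 64) -> FeatureMatrix:
    """Windowed MAV features for all single-ended channels and, when
    ``pairs`` is set, all ordered differential pairs (i < j).

    The window is trailing (causal) by default and averaged over the
    available samples at the stream start; ``center=True`` gives the
    zero-phase variant used as an alignment reference. Output columns:
    the single-ended channels first, then pairs in lexicographic order.
    """
    if isinstance(raw, RawEMG):
        x, rate = raw.values, raw.rate
    else:
        x = np.asarray(raw, dtype=np.float64)
        if raw_rate_hz is None:
            raise ValueError("raw_rate_hz required for plain-array input")
        rate = raw_rate_hz
    n_raw, n_ch = x.shape
    lo, hi = _window_bounds(n_raw, rate, window_s, out_rate_hz, center)

    names = [f"e{i}" for i in range(n_ch)]
    cols = [_windowed_mav(np.abs(x), lo, hi)]
    if pairs:
        idx = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
        for k in range(0, len(idx), pair_chunk):
            chunk = idx[k:k + pair_chunk]
            ii = np.array([c[0] for c in chunk])
            jj = np.array([c[1] for c in chunk])
            cols.append(_windowed_mav(np.abs(x[:, ii] - x[:, jj]), lo, hi))
        names += pair_names(n_ch)
    return FeatureMatrix(values=np.hstack(cols), rate=out_rate_hz, channel_names=names)


@dataclass
class NormalizationParams:
    """Per-DOF rest baseline and flexion/extension extremes (raw angle units)."""

    rest_baseline: np.ndarray
    flex_extreme: np.ndarray
    ext_extreme: np.ndarray

    def __post_init__(self) -> None:
        self.rest_baseline = np.asarray(self.rest_baseline, dtype=np.float64)
        self.flex_extreme = np.asarray(self.flex_extreme, dtype=np.float64)
        self.ext_extreme = np.asarray(self.ext_extreme, dtype=np.float64)
        if np.any(self.flex_extreme <= self.rest_baseline) or \
                np.any(self.ext_extreme >= self.rest_baseline):
            raise ValueError("require ext_extreme < rest_baseline < flex_extreme per DOF")


def estimate_normalization(raw_angles: np.ndarray, rate_hz: float,
                           rest_window_s: float = 15.0,
                           extremes: tuple[np.ndarray, np.ndarray] | None = None
                           ) -> NormalizationParams:
    """Rest baseline from the leading rest window; extremes from a
    calibration input or, absent one, the per-session observed min/max."""
    x = np.asarray(raw_angles, dtype=np.float64)
    n_rest = round(rest_window_s * rate_hz)
    if n_rest > x.shape[0]:
        raise ValueError("rest window longer than the trace")
    baseline = x[:n_rest].mean(axis=0)
    if extremes is not None:
        flex, ext = extremes
    else:
        flex, ext = x.max(axis=0), x.min(axis=0)
    return NormalizationParams(rest_baseline=baseline, flex_extreme=flex, ext_extreme=ext)


def normalize_trace(raw_angles: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map raw angles to [-1, 1]: baseline -> 0, flex_extreme -> +1,
    ext_extreme -> -1, piecewise linear, clipped."""
    x = np.asarray(raw_angles, dtype=np.float64)
    up = params.flex_extreme - params.rest_baseline
    dn = params.rest_baseline - params.ext_extreme
    if np.any(up == 0) or np.any(dn == 0):
        raise ValueError("degenerate extremes equal to baseline")
    d = x - params.rest_baseline
    out = np.where(d >= 0, d / up, d / dn)
    return np.clip(out, -1.0, 1.0)


def denormalize_trace(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Inverse of :func:`normalize_trace` on [-1, 1]."""
    v = np.asarray(values, dtype=np.float64)
    up = params.flex_extreme - params.rest_baseline
    dn = params.rest_baseline - params.ext_extreme
    return params.rest_baseline + np.where(v >= 0, v * up, v * dn)


def estimate_lag_crosscorr(labels: np.ndarray, features: np.ndarray,
                           rate: float, max_lag_s: float = 0.5) -> int:
    """Integer-sample lag by which the features trail the labels.

    Cross-correlates the summed absolute label deviation across DOFs with
    the summed mean-centered features across channels over integer shifts
    in [-max_lag, +max_lag]; ties break toward the smallest absolute lag,
    then toward the negative lag.
    """
    a = np.abs(np.asarray(labels, dtype=np.float64)).sum(axis=1)
    fv = np.asarray(features, dtype=np.float64)
    f = (fv - fv.mean(axis=0)).sum(axis=1)
    n = a.size
    m = int(round(max_lag_s * rate))
    if m >= n // 2:
        raise ValueError("max_lag must be below half the stream length")
    a = a - a.mean()
    shifts = np.arange(-m, m + 1)
    score = np.empty(shifts.size)
    for k, s in enumerate(shifts):
        if s >= 0:
            seg_a, seg_f = a[: n - s], f[s:]
        else:
            seg_a, seg_f = a[-s:], f[: n + s]
        score[k] = seg_a @ seg_f / seg_a.size
    best = score.max()
    cand = shifts[score >= best - 1e-12 * max(abs(best), 1.0)]
    cand = sorted(cand, key=lambda s: (abs(s), s))
    return int(cand[0])


def align_labels_crosscorr(labels: KinematicTrace, features: FeatureMatrix,
                           max_lag_s: float = 0.5) -> tuple[KinematicTrace, float]:
    """Shift labels onto the feature clock by the estimated reaction lag.

    Returns the lag-corrected label trace (shorter by ``|lag|`` samples,
    edge samples dropped) and the lag in seconds. A positive lag means the
    features (and the underlying movement) trailed the labels; aligned
    label sample ``t`` pairs with feature sample ``t + lag_samples`` when
    the lag is positive, or ``t`` after dropping the leading ``|lag|``
    feature samples when negative.
    """
    if labels.n_samples != features.n_samples:
        raise ValueError("labels and features must share length")
    if labels.rate != features.rate:
        raise ValueError("labels and features must share rate")
    lag = estimate_lag_crosscorr(labels.values, features.values, labels.rate, max_lag_s)
    n = labels.n_samples
    vals = labels.values[: n - lag] if lag >= 0 else labels.values[-lag:]
    # boundary indices stay on the label clock, shifted into the trimmed array
    shift = 0 if lag >= 0 else lag  # negative lag drops leading label samples
    bounds = []
    for (s, o, me, e) in labels.trial_boundaries:
        b = tuple(x + shift for x in (s, o, me, e))
        if b[0] >= 0 and b[3] <= vals.shape[0]:
            bounds.append(b)
    return KinematicTrace(vals, labels.rate, bounds), lag / labels.rate
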