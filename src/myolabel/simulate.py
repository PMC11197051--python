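"""Synthetic bilateral-movement sessions with surrogate EMG.

The generator emulates the study setting: a virtual hand plays preprogrammed
trapezoidal movements; the participant's right (ground-truth) hand mimics
them imperfectly -- with a positive reaction lag, per-trial magnitude error,
biomechanical coupling into non-target DOFs, and a slow random-walk drift of
the resting posture -- while the left (mirror) hand tracks the ground-truth
hand with small two-sided timing jitter and small magnitude noise. Surrogate
raw EMG is amplitude-modulated Gaussian noise whose envelope is a nonnegative
linear synergy map of the rectified ground-truth joint angles.

All randomness flows from ``ParticipantParams.seed``; identical inputs give
bit-identical sessions. Draws are consumed in a fixed order: per-trial
magnitude errors, per-trial reaction lags, per-trial mirror magnitude noise,
per-trial mirror jitter, per-rest-interval drift increments, EMG noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import truncnorm

from .kinematics import KinematicTrace, preprogrammed_profile, session_boundaries, trapezoid
from .schedule import N_DOF, TrialSchedule

N_ELECTRODES = 32


@dataclass
class RawEMG:
    """Time x 32 raw surface-EMG matrix at ``rate`` samples/s."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("EMG values must be 2-D (time x channel)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class ParticipantParams:
    """Generative parameters of one simulated participant.

    coupling_matrix[j, k] is the fraction of DOF k's scaled target profile
    leaked into non-target DOF j (zero diagonal). Drift is a random walk of
    the resting offset: one N(0, drift_step_sd) increment per DOF per rest
    interval, clipped to +/-drift_max. The mimic lag is truncated at zero
    (the hand always lags the virtual hand); mirror jitter is zero-mean and
    two-sided. Magnitude errors are fractions of the full unit deviation.
    """

    coupling_matrix: np.ndarray
    drift_step_sd: float
    drift_max: float
    mimic_lag_mean_s: float
    mimic_lag_sd_s: float
    mirror_jitter_sd_s: float
    mimic_mag_err_mean: float
    mimic_mag_err_sd: float
    mirror_mag_err_sd: float
    synergy_gain_pos: np.ndarray
    synergy_gain_neg: np.ndarray
    emg_baseline: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.coupling_matrix = np.asarray(self.coupling_matrix, dtype=np.float64)
        self.synergy_gain_pos = np.asarray(self.synergy_gain_pos, dtype=np.float64)
        self.synergy_gain_neg = np.asarray(self.synergy_gain_neg, dtype=np.float64)
        self.emg_baseline = np.atleast_1d(np.asarray(self.emg_baseline, dtype=np.float64))
        if self.emg_baseline.size == 1:
            self.emg_baseline = np.full(N_ELECTRODES, self.emg_baseline.item())
        if self.coupling_matrix.shape != (N_DOF, N_DOF):
            raise ValueError("coupling_matrix must be 8x8")
        if np.any(np.diag(self.coupling_matrix) != 0):
            raise ValueError("coupling_matrix diagonal must be zero")
        if np.any(self.coupling_matrix < 0) or np.any(self.coupling_matrix >= 1):
            raise ValueError("coupling entries must lie in [0, 1)")
        for name in ("drift_step_sd", "mimic_lag_sd_s", "mirror_jitter_sd_s",
                     "mimic_mag_err_sd", "mirror_mag_err_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.synergy_gain_pos.shape != (N_ELECTRODES, N_DOF) or \
                self.synergy_gain_neg.shape != (N_ELECTRODES, N_DOF):
            raise ValueError("synergy matrices must be 32x8")
        if np.any(self.synergy_gain_pos < 0) or np.any(self.synergy_gain_neg < 0):
            raise ValueError("synergy gains must be nonnegative")
        if np.any(self.emg_baseline < 0):
            raise ValueError("emg_baseline must be nonnegative")


@dataclass
class SessionData:
    """One participant-session: schedule, the three aligned kinematic traces
    (virtual, ground truth, mirror) and the raw EMG."""

    schedule: TrialSchedule
    virtual: KinematicTrace
    truth: KinematicTrace
    mirror: KinematicTrace
    emg: RawEMG | None
    params: ParticipantParams

    def __post_init__(self) -> None:
        n = self.virtual.n_samples
        if not (self.truth.n_samples == n and self.mirror.n_samples == n):
            raise ValueError("all kinematic traces must share length")
        if not (self.virtual.rate == self.truth.rate == self.mirror.rate):
            raise ValueError("all kinematic traces must share rate")
        if self.emg is not None:
            expect = n / self.virtual.rate * self.emg.rate
            if abs(self.emg.n_samples - expect) > 1:
                raise ValueError("EMG duration does not match kinematic duration")


def uniform_coupling(c: float) -> np.ndarray:
    """Uniform off-diagonal coupling matrix with leakage fraction ``c``."""
    m = np.full((N_DOF, N_DOF), float(c))
    np.fill_diagonal(m, 0.0)
    return m


def default_synergies(seed: int, electrodes_per_dof: int = 6,
                      gain_range: tuple[float, float] = (0.5, 1.5)) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sparse random synergy matrices (32 electrodes x 8 DOFs).

    Each DOF direction drives a random subset of electrodes with gains drawn
    uniformly from ``gain_range``; flexion and extension of a DOF recruit
    independent subsets, mimicking antagonist muscle groups.
    """
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(2):
        g = np.zeros((N_ELECTRODES, N_DOF))
        for dof in range(N_DOF):
            chans = rng.choice(N_ELECTRODES, size=electrodes_per_dof, replace=False)
            g[chans, dof] = rng.uniform(*gain_range, size=electrodes_per_dof)
        mats.append(g)
    return mats[0], mats[1]


def _preset_dir() -> Path:
    return Path(resources.files("myolabel") / "presets")  # type: ignore[arg-type]


def load_preset(name: str) -> dict:
    """Load a bundled preset (``paper_healthy``, ``noise_free``) or a YAML path."""
    path = Path(name)
    if not path.exists():
        path = _preset_dir() / f"{name}.yaml"
    if not path.exists():
        raise FileNotFoundError(f"unknown preset {name!r}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def make_params(preset: dict | str, seed: int) -> ParticipantParams:
    """Materialize ``ParticipantParams`` from a preset mapping or name."""
    if isinstance(preset, str):
        preset = load_preset(preset)
    p = dict(preset)
    syn = p.pop("synergy", {})
    syn_seed = int(syn.get("seed", 0)) + seed
    gpos, gneg = default_synergies(
        syn_seed,
        electrodes_per_dof=int(syn.get("electrodes_per_dof", 6)),
        gain_range=tuple(syn.get("gain_range", (0.5, 1.5))),
    )
    coupling = p.pop("coupling")
    matrix = uniform_coupling(coupling) if np.isscalar(coupling) else np.asarray(coupling)
    return ParticipantParams(
        coupling_matrix=matrix,
        drift_step_sd=float(p.pop("drift_step_sd")),
        drift_max=float(p.pop("drift_max")),
        mimic_lag_mean_s=float(p.pop("mimic_lag_mean_s")),
        mimic_lag_sd_s=float(p.pop("mimic_lag_sd_s")),
        mirror_jitter_sd_s=float(p.pop("mirror_jitter_sd_s")),
        mimic_mag_err_mean=float(p.pop("mimic_mag_err_mean")),
        mimic_mag_err_sd=float(p.pop("mimic_mag_err_sd")),
        mirror_mag_err_sd=float(p.pop("mirror_mag_err_sd")),
        synergy_gain_pos=gpos,
        synergy_gain_neg=gneg,
        emg_baseline=np.asarray(p.pop("emg_baseline", 0.05)),
        seed=int(seed),
    )


# Between-participant heterogeneity: multiplicative lognormal factors with
# unit mean; CVs chosen to match the cohort-level spread reported for the
# label-quality metrics (coefficient of variation roughly 10-20%).
_COHORT_CV = {
    "coupling": 0.13,
    "drift": 0.13,
    "lag": 0.08,
    "mag": 0.10,
    "mirror": 0.10,
}


def sample_cohort(preset: dict | str, n: int, seed: int,
                  heterogeneity: dict | None = None) -> list[ParticipantParams]:
    """Draw ``n`` participants around a preset with lognormal heterogeneity."""
    if isinstance(preset, str):
        preset = load_preset(preset)
    cv = dict(_COHORT_CV)
    if heterogeneity is not None:
        cv.update(heterogeneity)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for i in range(n):
        f = {k: float(np.exp(rng.normal(-0.5 * v**2, v))) for k, v in cv.items()}
        p = dict(preset)
        p["coupling"] = p["coupling"] * f["coupling"]
        p["drift_step_sd"] = p["drift_step_sd"] * f["drift"]
        p["mimic_lag_mean_s"] = p["mimic_lag_mean_s"] * f["lag"]
        p["mimic_mag_err_mean"] = p["mimic_mag_err_mean"] * f["mag"]
        p["mirror_mag_err_sd"] = p["mirror_mag_err_sd"] * f["mirror"]
        out.append(make_params(p, int(seeds[i])))
    return out


def _shifted_trap(trap: np.ndarray, shift: float, n_out: int) -> np.ndarray:
    """Trapezoid delayed by ``shift`` samples via linear interpolation."""
    grid = np.arange(n_out, dtype=np.float64) - shift
    return np.interp(grid, np.arange(trap.size, dtype=np.float64), trap, left=0.0, right=0.0)


def _positive_lags(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, max(mean, 0.0))
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_participant(schedule: TrialSchedule, params: ParticipantParams,
                         compute_emg: bool = True) -> SessionData:
    """Simulate one participant-session.

    The ground-truth hand reproduces each preprogrammed trial scaled by
    ``1 + magnitude error``, delayed by a nonnegative reaction lag, with
    coupling leakage into non-target DOFs and an additive per-rest-interval
    drift offset; the mirror hand repeats the same latent trial with an
    extra two-sided jitter and magnitude noise. Both are clipped to [-1, 1]
    as the final step.
    """
    t = schedule.timing
    rate = t.kinematic_rate_hz
    n_trials = schedule.n_trials
    bounds, total = session_boundaries(schedule)
    virtual = preprogrammed_profile(schedule)

    rng = np.random.default_rng(params.seed)
    eps = rng.normal(params.mimic_mag_err_mean, params.mimic_mag_err_sd, size=n_trials)
    lags_s = _positive_lags(rng, params.mimic_lag_mean_s, params.mimic_lag_sd_s, n_trials)
    eta = rng.normal(0.0, params.mirror_mag_err_sd, size=n_trials)
    jit_s = rng.normal(0.0, params.mirror_jitter_sd_s, size=n_trials)

    if np.any(lags_s > t.intertrial_s) or np.any(np.abs(lags_s + jit_s) > t.intertrial_s):
        raise ValueError("reaction lag or mirror jitter exceeds the inter-trial interval")

    # drift offsets: one state per rest interval (interval 0 = reference, 0)
    steps = rng.normal(0.0, params.drift_step_sd, size=(n_trials + 1, N_DOF))
    drift = np.zeros((n_trials + 1, N_DOF))
    for i in range(1, n_trials + 1):
        drift[i] = np.clip(drift[i - 1] + steps[i], -params.drift_max, params.drift_max)

    trap = trapezoid(t.ramp_samples, t.hold_samples)
    truth = np.zeros((total, N_DOF))
    mirror = np.zeros((total, N_DOF))
    margin = t.rest_samples  # room for the shifted tail past the movement end
    for i, ((movement, _), (start, onset, move_end, end)) in enumerate(zip(schedule.trials, bounds)):
        n_ext = min(t.movement_samples + margin, total - onset)
        targets = movement.target_dofs
        # leakage from each target's scaled profile into non-target DOFs only
        mix = np.eye(N_DOF)
        for k in targets:
            for j in range(N_DOF):
                if j != k and j not in targets:
                    mix[j, k] = params.coupling_matrix[j, k]
        for arr, scale, shift_s in (
            (truth, 1.0 + eps[i], lags_s[i]),
            (mirror, (1.0 + eps[i]) * (1.0 + eta[i]), lags_s[i] + jit_s[i]),
        ):
            prof = np.zeros((n_ext, N_DOF))
            shifted = _shifted_trap(trap, shift_s * rate, n_ext) * scale
            for dof, sign in movement.directions.items():
                prof[:, dof] = sign * shifted
            arr[onset:onset + n_ext] += prof @ mix.T

    # additive drift offset over each trial segment and the trailing rest
    for i, (start, onset, move_end, end) in enumerate(bounds):
        truth[start:end] += drift[i]
        mirror[start:end] += drift[i]
    truth[bounds[-1][3]:] += drift[n_trials]
    mirror[bounds[-1][3]:] += drift[n_trials]

    np.clip(truth, -1.0, 1.0, out=truth)
    np.clip(mirror, -1.0, 1.0, out=mirror)

    truth_trace = KinematicTrace(truth, rate, list(bounds))
    mirror_trace = KinematicTrace(mirror, rate, list(bounds))
    emg = synthesize_emg(truth_trace, params, rng=rng, emg_rate_hz=t.emg_rate_hz) if compute_emg else None
    return SessionData(schedule=schedule, virtual=virtual, truth=truth_trace,
                       mirror=mirror_trace, emg=emg, params=params)


def synthesize_emg(trace: KinematicTrace, params: ParticipantParams,
                   rng: np.random.Generator | None = None,
                   emg_rate_hz: float = 1000.0) -> RawEMG:
    """Surrogate raw EMG: amplitude-modulated Gaussian noise.

    The per-channel envelope is ``e(t) = baseline + G+ . max(theta, 0) +
    G- . max(-theta, 0)`` evaluated on the kinematic grid and linearly
    upsampled to the EMG rate; each raw sample is the envelope times an
    independent standard-normal draw, so the expected mean-absolute-value of
    the raw signal is ``e(t) * sqrt(2/pi)``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    theta = trace.values
    env = (params.emg_baseline[None, :]
           + np.clip(theta, 0.0, None) @ params.synergy_gain_pos.T
           + np.clip(-theta, 0.0, None) @ params.synergy_gain_neg.T)
    n_emg = round(trace.n_samples / trace.rate * emg_rate_hz)
    t_kin = np.arange(trace.n_samples) / trace.rate
    t_emg = np.arange(n_emg) / emg_rate_hz
    env_up = np.empty((n_emg, env.shape[1]))
    for ch in range(env.shape[1]):
        env_up[:, ch] = np.interp(t_emg, t_kin, env[:, ch])
    raw = env_up * rng.standard_normal(env_up.shape)
    return RawEMG(values=raw, rate=emg_rate_hz)


def noise_free_params(seed: int = 0) -> ParticipantParams:
    """Convenience: the bundled all-noise-terms-zero preset."""
    return make_params("noise_free", seed)
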