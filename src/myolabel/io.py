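"""Session archives (HDF5), run configuration and manifests."""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .kinematics import KinematicTrace
from .schedule import MovementSpec, TrialSchedule, TrialTiming
from .simulate import ParticipantParams, RawEMG, SessionData

FORMAT_VERSION = 1

_TIMING_FIELDS = ("ramp_s", "hold_s", "intertrial_s", "kinematic_rate_hz", "emg_rate_hz")
_PARAM_SCALARS = ("drift_step_sd", "drift_max", "mimic_lag_mean_s", "mimic_lag_sd_s",
                  "mirror_jitter_sd_s", "mimic_mag_err_mean", "mimic_mag_err_sd",
                  "mirror_mag_err_sd")


class SchemaError(ValueError):
    """Archive does not match the session schema."""


def write_session(session: SessionData, path, compress_emg: bool = True) -> None:
    """Serialize a session to a single HDF5 archive (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["session_id"] = session.schedule.session_id
        sched = f.create_group("schedule")
        moves = [{"id": m.id, "directions": {str(k): v for k, v in m.directions.items()},
                  "is_combination": m.is_combination} for m in session.schedule.movements]
        sched.attrs["movements"] = json.dumps(moves)
        sched.create_dataset("trial_movement", data=np.array(
            [[i for i, m in enumerate(session.schedule.movements) if m.id == mv.id][0]
             for mv, _ in session.schedule.trials]))
        sched.create_dataset("trial_rep", data=np.array([r for _, r in session.schedule.trials]))
        for name in _TIMING_FIELDS:
            sched.attrs[name] = getattr(session.schedule.timing, name)
        for name in ("virtual", "truth", "mirror"):
            tr: KinematicTrace = getattr(session, name)
            g = f.create_group(name)
            g.create_dataset("values", data=tr.values)
            g.create_dataset("boundaries", data=np.array(tr.trial_boundaries, dtype=np.int64))
            g.attrs["rate"] = tr.rate
        if session.emg is not None:
            g = f.create_group("emg")
            g.create_dataset("values", data=session.emg.values,
                             compression="gzip" if compress_emg else None)
            g.attrs["rate"] = session.emg.rate
        g = f.create_group("params")
        p = session.params
        g.attrs["seed"] = p.seed
        for name in _PARAM_SCALARS:
            g.attrs[name] = getattr(p, name)
        g.create_dataset("coupling_matrix", data=p.coupling_matrix)
        g.create_dataset("synergy_gain_pos", data=p.synergy_gain_pos)
        g.create_dataset("synergy_gain_neg", data=p.synergy_gain_neg)
        g.create_dataset("emg_baseline", data=p.emg_baseline)


def read_session(path) -> SessionData:
    """Read a session archive; raises :class:`SchemaError` with a field-level
    message on version or schema violations."""
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise SchemaError(f"unreadable or truncated archive {path!r}: {err}") from err
    with f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise SchemaError(f"format_version {version!r} != supported {FORMAT_VERSION}")
        for name in ("schedule", "virtual", "truth", "mirror", "params"):
            if name not in f:
                raise SchemaError(f"missing group {name!r}")
        sched = f["schedule"]
        moves = [MovementSpec(id=m["id"],
                              directions={int(k): int(v) for k, v in m["directions"].items()},
                              is_combination=m["is_combination"])
                 for m in json.loads(sched.attrs["movements"])]
        timing = TrialTiming(**{k: float(sched.attrs[k]) for k in _TIMING_FIELDS})
        trials = tuple((moves[i], int(r)) for i, r in
                       zip(sched["trial_movement"][:], sched["trial_rep"][:]))
        schedule = TrialSchedule(trials=trials, timing=timing,
                                 session_id=str(f.attrs["session_id"]))
        traces = {}
        for name in ("virtual", "truth", "mirror"):
            g = f[name]
            rate = float(g.attrs["rate"])
            if rate != timing.kinematic_rate_hz:
                raise SchemaError(f"{name}.rate {rate} != timing.kinematic_rate_hz "
                                  f"{timing.kinematic_rate_hz}")
            traces[name] = KinematicTrace(g["values"][:], rate,
                                          [tuple(b) for b in g["boundaries"][:]])
        emg = None
        if "emg" in f:
            rate = float(f["emg"].attrs["rate"])
            if rate != timing.emg_rate_hz:
                raise SchemaError(f"emg.rate {rate} != timing.emg_rate_hz {timing.emg_rate_hz}")
            emg = RawEMG(f["emg"]["values"][:], rate)
        g = f["params"]
        params = ParticipantParams(
            coupling_matrix=g["coupling_matrix"][:],
            synergy_gain_pos=g["synergy_gain_pos"][:],
            synergy_gain_neg=g["synergy_gain_neg"][:],
            emg_baseline=g["emg_baseline"][:],
            seed=int(g.attrs["seed"]),
            **{k: float(g.attrs[k]) for k in _PARAM_SCALARS},
        )
    return SessionData(schedule=schedule, virtual=traces["virtual"], truth=traces["truth"],
                       mirror=traces["mirror"], emg=emg, params=params)


@dataclass
class RunConfig:
    """Validated configuration for a full experiment run."""

    preset: str = "paper_healthy"
    cohort_size: int = 7
    seed: int = 0
    protocol: str = "biomech"
    reps: int = 10
    n_sessions: int = 1
    sizes: list[int] = field(default_factory=list)
    algorithms: list[str] = field(default_factory=lambda: ["kf", "cnn"])
    k_folds: int = 10
    n_electrodes: int | None = None
    net: str = "default"  # "default" or "small"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.cohort_size < 1 or self.reps < 1 or self.k_folds < 1:
            raise ValueError("cohort_size, reps and k_folds must be >= 1")
        if self.net not in ("default", "small"):
            raise ValueError("net must be 'default' or 'small'")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys with a
    closest-match suggestion."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suffix}")
    return RunConfig(**raw)


def write_manifest(config: RunConfig, path, extra: dict | None = None) -> None:
    import importlib.metadata as md

    manifest = {
        "config": asdict(config),
        "format_version": FORMAT_VERSION,
        "versions": {pkg: md.version(pkg) for pkg in
                     ("myolabel", "numpy", "scipy", "scikit-learn", "statsmodels")},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))
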