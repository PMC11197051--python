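"""Training datasets: aligned feature/label streams with trial bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix, compute_mav_features
from .metrics import aligned_mimic_labels
from .simulate import SessionData


@dataclass
class TrainingDataset:
    """Per-sample EMG features, paradigm labels and ground-truth kinematics.

    ``trial_index`` is globally unique across sessions; ``movement_index``
    identifies the movement within the protocol's movement list so folds can
    stratify by movement. ``truth`` carries the ground-truth trace used as
    the test reference for decoder evaluation.
    """

    features: np.ndarray
    labels: np.ndarray
    truth: np.ndarray
    trial_index: np.ndarray
    session_index: np.ndarray
    movement_index: np.ndarray
    paradigm: str
    rate: float

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        for name in ("labels", "truth", "trial_index", "session_index", "movement_index"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match features")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    def trial_table(self) -> dict[int, tuple[int, int]]:
        """trial id -> (session index, movement index)."""
        out: dict[int, tuple[int, int]] = {}
        tid = self.trial_index
        for t in np.unique(tid):
            i = int(np.searchsorted(tid, t))
            out[int(t)] = (int(self.session_index[i]), int(self.movement_index[i]))
        return out

    def rows_for_trials(self, trials) -> np.ndarray:
        return np.flatnonzero(np.isin(self.trial_index, list(trials)))


def session_features(session: SessionData, n_electrodes: int | None = None,
                     pairs: bool = True) -> FeatureMatrix:
    """Causal MAV features for one session, optionally restricted to the
    first ``n_electrodes`` electrodes (desk-scale mode)."""
    if session.emg is None:
        raise ValueError("session has no EMG")
    raw = session.emg.values
    if n_electrodes is not None:
        raw = raw[:, :n_electrodes]
    return compute_mav_features(raw, out_rate_hz=session.virtual.rate, pairs=pairs,
                                raw_rate_hz=session.emg.rate)


def build_training_dataset(sessions: list[SessionData], paradigm: str,
                           features: list[FeatureMatrix] | None = None,
                           n_electrodes: int | None = None) -> TrainingDataset:
    """Concatenate sessions into one dataset for a training paradigm.

    Mimic labels are the lag-corrected virtual trace (cross-correlation
    alignment per session); mirror labels are the contralateral trace.
    """
    if paradigm not in ("mimic", "mirror"):
        raise ValueError("paradigm must be 'mimic' or 'mirror'")
    feats, labels, truths, tids, sids, mids = [], [], [], [], [], []
    trial_offset = 0
    movement_ids = {m.id: i for i, m in enumerate(sessions[0].schedule.movements)}
    for si, sess in enumerate(sessions):
        fm = features[si] if features is not None else session_features(sess, n_electrodes)
        if paradigm == "mimic":
            # reaction-lag correction against the zero-phase envelope, so the
            # labels stay on the kinematic clock (see metrics module)
            lab, _ = aligned_mimic_labels(sess)
        else:
            lab = sess.mirror
        n = min(fm.n_samples, lab.n_samples, sess.truth.n_samples)
        bounds = sess.truth.trial_boundaries
        starts = np.array([b[0] for b in bounds])
        per_sample_trial = np.searchsorted(starts, np.arange(n), side="right") - 1
        mv = np.array([movement_ids[m.id] for m, _ in sess.schedule.trials])
        feats.append(fm.values[:n])
        labels.append(lab.values[:n])
        truths.append(sess.truth.values[:n])
        tids.append(per_sample_trial + trial_offset)
        sids.append(np.full(n, si))
        mids.append(mv[per_sample_trial])
        trial_offset += len(bounds)
    return TrainingDataset(
        features=np.vstack(feats), labels=np.vstack(labels), truth=np.vstack(truths),
        trial_index=np.concatenate(tids), session_index=np.concatenate(sids),
        movement_index=np.concatenate(mids), paradigm=paradigm,
        rate=sessions[0].virtual.rate,
    )
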