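"""Kinematic traces and the preprogrammed virtual-hand profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import N_DOF, TrialSchedule


@dataclass
class KinematicTrace:
    """Time x 8 matrix of normalized joint angles.

    ``trial_boundaries`` holds one ``(start, onset, movement_end, end)``
    sample-index tuple per trial: the inter-trial rest spans
    ``[start, onset)`` and the movement spans ``[onset, movement_end)``;
    here ``movement_end == end``. A trailing rest segment (one inter-trial
    interval) follows the last trial and is not listed as a trial.
    """

    values: np.ndarray
    rate: float
    trial_boundaries: list[tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("trace values must be 2-D (time x DOF)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_dof(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "KinematicTrace":
        return KinematicTrace(self.values.copy(), self.rate, list(self.trial_boundaries))


def trapezoid(ramp: int, hold: int) -> np.ndarray:
    """Unit trapezoid sampled on the kinematic grid.

    Rises linearly from 0 over ``ramp`` samples, holds at 1 for ``hold``
    samples, returns linearly to 0 over ``ramp`` samples. The first and
    last samples are exactly 0 and the hold samples exactly 1.
    """
    up = np.arange(ramp) / ramp
    down = 1.0 - np.arange(1, ramp + 1) / ramp
    return np.concatenate([up, np.ones(hold), down])


def session_boundaries(schedule: TrialSchedule) -> tuple[list[tuple[int, int, int, int]], int]:
    """Trial boundary tuples and the total sample count for a schedule."""
    t = schedule.timing
    bounds = []
    pos = 0
    for _ in schedule.trials:
        start = pos
        onset = start + t.rest_samples
        end = onset + t.movement_samples
        bounds.append((start, onset, end, end))
        pos = end
    total = pos + t.rest_samples  # trailing rest
    return bounds, total


def preprogrammed_profile(schedule: TrialSchedule) -> KinematicTrace:
    """Ideal virtual-hand trace: per trial, target DOFs follow a trapezoid
    to +/-1, all other DOFs and all rest segments are exactly 0."""
    t = schedule.timing
    bounds, total = session_boundaries(schedule)
    values = np.zeros((total, N_DOF))
    trap = trapezoid(t.ramp_samples, t.hold_samples)
    for (movement, _), (start, onset, move_end, end) in zip(schedule.trials, bounds):
        for dof, sign in movement.directions.items():
            values[onset:move_end, dof] = sign * trap
    return KinematicTrace(values=values, rate=t.kinematic_rate_hz, trial_boundaries=bounds)
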