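"""Movement sets and trial schedules for the bilateral training protocols.

A session is an ordered sequence of trials. Each trial is one preprogrammed
movement of the virtual hand: a trapezoidal excursion of one or more target
degrees of freedom (DOFs) preceded by an inter-trial rest. The eight DOFs are
flexion/extension of digits D1-D5, D1 abduction/adduction, wrist
flexion/extension and wrist pronation/supination, expressed as normalized
joint angles in [-1, 1] (+1 = full flexion/pronation, -1 = full
extension/supination, 0 = rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DOF_NAMES = (
    "D1_flex",
    "D2_flex",
    "D3_flex",
    "D4_flex",
    "D5_flex",
    "D1_abd",
    "wrist_flex",
    "wrist_pro",
)
N_DOF = len(DOF_NAMES)

DIGIT_DOFS = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class MovementSpec:
    """One movement of the virtual hand.

    ``directions`` maps target DOF index -> +1 (flexion/pronation/abduction)
    or -1 (extension/supination/adduction). ``is_combination`` flags
    multi-digit grasp/open movements.
    """

    id: str
    directions: dict[int, int]
    is_combination: bool = False

    def __post_init__(self) -> None:
        if not self.directions:
            raise ValueError("movement must target at least one DOF")
        if self.is_combination and len(self.directions) < 2:
            raise ValueError("combination movements need >= 2 target DOFs")
        if not self.is_combination and len(self.directions) != 1:
            raise ValueError("individuated movements target exactly 1 DOF")
        for d, s in self.directions.items():
            if d not in range(N_DOF) or s not in (-1, 1):
                raise ValueError(f"bad target DOF/direction: {d}:{s}")

    @property
    def target_dofs(self) -> tuple[int, ...]:
        return tuple(sorted(self.directions))


def _individuated(name: str, dof: int, sign: int) -> MovementSpec:
    return MovementSpec(id=name, directions={dof: sign})


def biomech_movements() -> list[MovementSpec]:
    """The 18-movement set of the biomechanical-analysis protocol.

    Individuated flexion and extension of D1-D5 (10), wrist flex/ext, wrist
    pro/sup, D1 ab/ad (6), plus power grasp (simultaneous D1-D5 flexion) and
    hand open (simultaneous D1-D5 extension).
    """
    moves: list[MovementSpec] = []
    for i, digit in enumerate(("D1", "D2", "D3", "D4", "D5")):
        moves.append(_individuated(f"{digit}_flex", DIGIT_DOFS[i], +1))
        moves.append(_individuated(f"{digit}_ext", DIGIT_DOFS[i], -1))
    moves.append(_individuated("wrist_flex", 6, +1))
    moves.append(_individuated("wrist_ext", 6, -1))
    moves.append(_individuated("wrist_pro", 7, +1))
    moves.append(_individuated("wrist_sup", 7, -1))
    moves.append(_individuated("D1_abd", 5, +1))
    moves.append(_individuated("D1_add", 5, -1))
    moves.append(MovementSpec("power_grasp", {d: +1 for d in DIGIT_DOFS}, True))
    moves.append(MovementSpec("hand_open", {d: -1 for d in DIGIT_DOFS}, True))
    return moves


def ml_movements() -> list[MovementSpec]:
    """The 14-movement set of the machine-learning protocol.

    The virtual hand mimics the DOFs of a multi-articulate prosthetic arm:
    individuated D1-D3 flex/ext, wrist flex/ext, wrist pro/sup, D1 ab/ad,
    and open/close of the grip. The grip is a single DOF of the arm; in the
    8-joint hand space its two directions map onto simultaneous D1-D5
    flexion (close) and extension (open).
    """
    moves: list[MovementSpec] = []
    for i, digit in enumerate(("D1", "D2", "D3")):
        moves.append(_individuated(f"{digit}_flex", DIGIT_DOFS[i], +1))
        moves.append(_individuated(f"{digit}_ext", DIGIT_DOFS[i], -1))
    moves.append(_individuated("wrist_flex", 6, +1))
    moves.append(_individuated("wrist_ext", 6, -1))
    moves.append(_individuated("wrist_pro", 7, +1))
    moves.append(_individuated("wrist_sup", 7, -1))
    moves.append(_individuated("D1_abd", 5, +1))
    moves.append(_individuated("D1_add", 5, -1))
    moves.append(MovementSpec("grip_close", {d: +1 for d in DIGIT_DOFS}, True))
    moves.append(MovementSpec("grip_open", {d: -1 for d in DIGIT_DOFS}, True))
    return moves


@dataclass(frozen=True)
class TrialTiming:
    """Timing of a single trial and the sampling rates.

    The movement is a 0.7 s ramp away from rest, a 0.1 s hold at maximum
    deviation and a 0.7 s ramp back (1.5 s total), preceded by a 1 s
    inter-trial rest. Kinematics at 30 Hz, raw EMG at 1 kHz.
    """

    ramp_s: float = 0.7
    hold_s: float = 0.1
    intertrial_s: float = 1.0
    kinematic_rate_hz: float = 30.0
    emg_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("ramp_s", "hold_s", "intertrial_s", "kinematic_rate_hz", "emg_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ramp_samples(self) -> int:
        return round(self.ramp_s * self.kinematic_rate_hz)

    @property
    def hold_samples(self) -> int:
        return round(self.hold_s * self.kinematic_rate_hz)

    @property
    def rest_samples(self) -> int:
        return round(self.intertrial_s * self.kinematic_rate_hz)

    @property
    def movement_samples(self) -> int:
        return 2 * self.ramp_samples + self.hold_samples

    @property
    def trial_samples(self) -> int:
        return self.rest_samples + self.movement_samples


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered plan of (movement, repetition) trials for one session."""

    trials: tuple[tuple[MovementSpec, int], ...]
    timing: TrialTiming = field(default_factory=TrialTiming)
    session_id: str = "session"

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def movements(self) -> list[MovementSpec]:
        seen: dict[str, MovementSpec] = {}
        for m, _ in self.trials:
            seen.setdefault(m.id, m)
        return list(seen.values())


PROTOCOLS = {"biomech": biomech_movements, "ml": ml_movements}


def build_schedule(
    protocol: str,
    reps: int,
    timing: TrialTiming | None = None,
    session_id: str = "session",
) -> TrialSchedule:
    """Build a session schedule: every movement repeated ``reps`` times
    consecutively before progressing to the next movement."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {sorted(PROTOCOLS)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    moves = PROTOCOLS[protocol]()
    trials = tuple((m, r) for m in moves for r in range(reps))
    return TrialSchedule(trials=trials, timing=timing or TrialTiming(), session_id=session_id)
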