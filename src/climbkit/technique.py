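"""Rule-based detection of the six classic novice climbing errors.

Each detector is gated to the phase in which the fault is meaningful —
the same joint arrangement can be an error in one phase and sound
technique in another:

===========================  =============  ========================================
error                        phase          rule (flag when …)
===========================  =============  ========================================
decoupling                   preparation    holding-arm elbow angle φ < Kϕ or
                                            shoulder angle ϑ < Kθ (arm not straight)
reaching_hand_supports       reaching       supporting hand in motion for more than
                                            Kt seconds (reach takes too long)
weight_shift                 reaching       knee never passes in front of the
                                            supporting foot: dknee·x < Kdknee in the
                                            middle half of the phase
both_feet_set                reaching       a foot is in motion or off the wall
                                            (z beyond the contact tolerance)
hip_close_to_wall            reaching       hip farther off the wall than a
                                            reference climb by ≥ Kdhip (DTW-coupled)
shoulder_relaxing            stabilization  new holding arm stays locked:
                                            φ < Kϕ or ϑ < Kθ after gripping
===========================  =============  ========================================

Angle-based detectors suppress flagged runs shorter than a few frames
(keypoint jitter); per-phase aggregation counts at most one error of a
type per phase instance, mirroring how a coach would count them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import Coupling
from .motion import MotionIntervals, RouteLimits, _runs
from .phases import HandRoles, Phase, PhaseKind, hand_roles_series
from .skeleton import FrameInterval, JointId, SkeletonSequence, joint_angle

__all__ = [
    "ERROR_TYPES",
    "ErrorEvent",
    "Thresholds",
    "detect_decoupling",
    "detect_reaching_hand_supports",
    "detect_weight_shift",
    "detect_both_feet_set",
    "detect_hip_close_to_wall",
    "detect_shoulder_relaxing",
    "detect_all",
    "aggregate_per_phase",
]

ERROR_TYPES = (
    "decoupling",
    "reaching_hand_supports",
    "weight_shift",
    "both_feet_set",
    "hip_close_to_wall",
    "shoulder_relaxing",
)

#: Phase in which each error type is defined.
ERROR_PHASE: dict[str, PhaseKind] = {
    "decoupling": PhaseKind.PREPARATION,
    "reaching_hand_supports": PhaseKind.REACHING,
    "weight_shift": PhaseKind.REACHING,
    "both_feet_set": PhaseKind.REACHING,
    "hip_close_to_wall": PhaseKind.REACHING,
    "shoulder_relaxing": PhaseKind.STABILIZATION,
}

#: Arm chain (wrist, elbow, shoulder, hip) per holding hand, for the elbow
#: angle φ = ∡(wrist, elbow, shoulder) and shoulder angle ϑ = ∡(elbow,
#: shoulder, hip).
_ARM_CHAIN: dict[JointId, tuple[JointId, JointId, JointId, JointId]] = {
    JointId.LEFT_WRIST: (
        JointId.LEFT_WRIST,
        JointId.LEFT_ELBOW,
        JointId.LEFT_SHOULDER,
        JointId.LEFT_HIP,
    ),
    JointId.RIGHT_WRIST: (
        JointId.RIGHT_WRIST,
        JointId.RIGHT_ELBOW,
        JointId.RIGHT_SHOULDER,
        JointId.RIGHT_HIP,
    ),
}

#: Leg (knee, ankle) evaluated by the weight-shift rule per supporting hand:
#: the supporting hand's own side (pairings normalised to knee-minus-ankle).
_SUPPORT_LEG: dict[JointId, tuple[JointId, JointId]] = {
    JointId.LEFT_WRIST: (JointId.LEFT_KNEE, JointId.LEFT_ANKLE),
    JointId.RIGHT_WRIST: (JointId.RIGHT_KNEE, JointId.RIGHT_ANKLE),
}


@dataclass(frozen=True)
class ErrorEvent:
    """A detected technique error over a frame interval within one phase."""

    type: str
    interval: FrameInterval
    phase_id: int

    def to_json(self) -> dict:
        return {"type": self.type, **self.interval.to_json(), "phase_id": self.phase_id}


@dataclass
class Thresholds:
    """Tunable detection thresholds (operative defaults of the method).

    ``eps_contact`` replaces the idealised "foot z above the plane" wall
    test: feet on bolted holds always stand some centimetres off the plane,
    so contact means z within a tolerance.
    """

    k_phi: float = 130.0  # deg, open-elbow threshold
    k_theta: float = 120.0  # deg, open-shoulder threshold
    k_t: float = 1.0  # s, max supporting-hand motion while reaching
    k_dknee: float = 200.0  # mm, knee-past-foot distance
    k_dhip: float = 50.0  # mm, hip standoff excess over the reference
    k_mu: int = 30  # frames, min valid movement duration
    eps_contact: float = 150.0  # mm, foot-on-wall tolerance
    min_event_frames: int = 5  # frames, jitter suppression for flagged runs

    def __post_init__(self) -> None:
        for name in ("k_phi", "k_theta", "k_t", "k_dknee", "k_dhip", "k_mu", "eps_contact"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def _phases_of(phases: Sequence[Phase], kind: PhaseKind) -> list[Phase]:
    return [p for p in phases if p.kind is kind]


def _arm_angles(seq: SkeletonSequence, frame: int, holding: JointId) -> tuple[float, float]:
    """Elbow angle φ and shoulder angle ϑ of the holding arm at one frame."""
    wrist, elbow, shoulder, hip = _ARM_CHAIN[holding]
    pos = seq.positions[frame]
    phi = joint_angle(pos[wrist.index], pos[elbow.index], pos[shoulder.index])
    theta = joint_angle(pos[elbow.index], pos[shoulder.index], pos[hip.index])
    return phi, theta


def _flag_runs_to_events(
    flags: np.ndarray, phase: Phase, type_: str, min_event: int
) -> list[ErrorEvent]:
    """Maximal flagged runs of at least ``min_event`` frames, as events.
    ``flags`` is indexed relative to the phase start."""
    events = []
    for lo, hi in _runs(flags):
        if hi - lo >= min_event:
            events.append(
                ErrorEvent(
                    type=type_,
                    interval=FrameInterval(phase.interval.start + lo, phase.interval.start + hi),
                    phase_id=phase.id,
                )
            )
    return events


def _angle_rule_events(
    seq: SkeletonSequence,
    phases: Sequence[Phase],
    roles: dict[int, HandRoles],
    th: Thresholds,
    kind: PhaseKind,
    type_: str,
) -> list[ErrorEvent]:
    """Shared body of the decoupling / shoulder-relaxing rules: flag frames
    where the holding arm is bent (φ < Kϕ or ϑ < Kθ) within phases of
    ``kind``."""
    events: list[ErrorEvent] = []
    for phase in _phases_of(phases, kind):
        flags = np.zeros(phase.interval.length, dtype=bool)
        for k, f in enumerate(range(phase.interval.start, phase.interval.end)):
            phi, theta = _arm_angles(seq, f, roles[f].holding)
            flags[k] = phi < th.k_phi or theta < th.k_theta
        events.extend(_flag_runs_to_events(flags, phase, type_, th.min_event_frames))
    return events


def detect_decoupling(
    seq: SkeletonSequence,
    phases: Sequence[Phase],
    roles: dict[int, HandRoles],
    th: Thresholds,
) -> list[ErrorEvent]:
    """Bent holding arm while the feet are being set (preparation).

    Keeping the holding arm straight lets the skeleton, not the arm
    flexors, carry the body — the energy-saving "decoupling" technique.
    """
    return _angle_rule_events(seq, phases, roles, th, PhaseKind.PREPARATION, "decoupling")


def detect_shoulder_relaxing(
    seq: SkeletonSequence,
    phases: Sequence[Phase],
    roles: dict[int, HandRoles],
    th: Thresholds,
) -> list[ErrorEvent]:
    """New holding arm stays locked after gripping (stabilization).

    After the reach the arm of the new holding hand should stretch again;
    a closed elbow/shoulder keeps the muscles loaded.
    """
    return _angle_rule_events(
        seq, phases, roles, th, PhaseKind.STABILIZATION, "shoulder_relaxing"
    )


def detect_reaching_hand_supports(
    seq: SkeletonSequence,
    phases: Sequence[Phase],
    roles: dict[int, HandRoles],
    motion: dict[str, MotionIntervals],
    th: Thresholds,
) -> list[ErrorEvent]:
    """Supporting hand in motion for longer than Kt while reaching.

    The supporting hand should leave its hold as late as possible; within
    each reaching phase the frames where the *currently* supporting wrist
    is inside one of its motion intervals are accumulated, and if that
    time exceeds Kt seconds the whole supporting-motion span becomes one
    event.  Note the roles are per frame: once the moving hand rises past
    the other wrist it becomes the holding hand and stops counting.
    """
    wrist_motion = {JointId.LEFT_WRIST: motion["J7"], JointId.RIGHT_WRIST: motion["J4"]}
    events: list[ErrorEvent] = []
    max_frames = th.k_t * seq.fps
    for phase in _phases_of(phases, PhaseKind.REACHING):
        flags = np.zeros(phase.interval.length, dtype=bool)
        for k, f in enumerate(range(phase.interval.start, phase.interval.end)):
            flags[k] = f in wrist_motion[roles[f].supporting]
        if int(np.count_nonzero(flags)) > max_frames:
            idx = np.flatnonzero(flags)
            events.append(
                ErrorEvent(
                    type="reaching_hand_supports",
                    interval=FrameInterval(
                        phase.interval.start + int(idx[0]),
                        phase.interval.start + int(idx[-1]) + 1,
                    ),
                    phase_id=phase.id,
                )
            )
    return events


def detect_weight_shift(
    seq: SkeletonSequence,
    phases: Sequence[Phase],
    roles: dict[int, HandRoles],
    th: Thresholds,
) -> list[ErrorEvent]:
    """Knee does not pass in front of the supporting foot while standing up.

    Checked only in the middle half of each reaching phase (indices
    [¼, ¾) of its length): at the beginning and end of a reach the knee
    legitimately trails the foot.  The knee-minus-ankle x-component is
    signed toward the direction of hip travel within the phase, so
    "passing in front" is positive for either leg and either climbing
    direction.
    """
    events: list[ErrorEvent] = []
    hip_x = seq.joint(JointId.ROOT)[:, 0]
    for phase in _phases_of(phases, PhaseKind.REACHING):
        a, b = phase.interval.start, phase.interval.end
        length = b - a
        mid_lo, mid_hi = a + length // 4, a + (3 * length) // 4
        if mid_hi <= mid_lo:
            continue
        # Median over the edge frames: a single-frame keypoint artifact at a
        # phase boundary must not flip the inferred travel direction.
        edge = max(1, min(10, length // 4))
        travel = float(np.median(hip_x[b - edge : b]) - np.median(hip_x[a : a + edge]))
        direction = -1.0 if travel < 0 else 1.0
        flags = np.zeros(length, dtype=bool)
        for f in range(mid_lo, mid_hi):
            knee, ankle = _SUPPORT_LEG[roles[f].supporting]
            dknee_x = seq.positions[f, knee.index, 0] - seq.positions[f, ankle.index, 0]
            flags[f - a] = direction * dknee_x < th.k_dknee
        events.extend(_flag_runs_to_events(flags, phase, "weight_shift", th.min_event_frames))
    return events


def detect_both_feet_set(
    seq: SkeletonSequence,
    phases: Sequence[Phase],
    motion: dict[str, MotionIntervals],
    th: Thresholds,
) -> list[ErrorEvent]:
    """A foot moves or hangs off the wall while standing up (reaching).

    Both feet should press on the wall or a hold during the stand-up; a
    foot still seeking a hold or dangling (wall distance z beyond the
    contact tolerance) is flagged.
    """
    events: list[ErrorEvent] = []
    foot_z = {
        JointId.LEFT_ANKLE: seq.joint(JointId.LEFT_ANKLE)[:, 2],
        JointId.RIGHT_ANKLE: seq.joint(JointId.RIGHT_ANKLE)[:, 2],
    }
    for phase in _phases_of(phases, PhaseKind.REACHING):
        a, b = phase.interval.start, phase.interval.end
        moving = motion["J14"].mask(a, b) | motion["J11"].mask(a, b)
        off_wall = (foot_z[JointId.LEFT_ANKLE][a:b] > th.eps_contact) | (
            foot_z[JointId.RIGHT_ANKLE][a:b] > th.eps_contact
        )
        events.extend(
            _flag_runs_to_events(moving | off_wall, phase, "both_feet_set", th.min_event_frames)
        )
    return events


def detect_hip_close_to_wall(
    query: SkeletonSequence,
    reference: SkeletonSequence,
    coupling: Coupling,
    query_phases: Sequence[Phase],
    query_limits: RouteLimits,
    reference_limits: RouteLimits,
    th: Thresholds,
) -> list[ErrorEvent]:
    """Hip farther off the wall than the reference climb by ≥ Kdhip.

    For each reaching frame of the query climb the DTW coupling supplies
    the corresponding reference frame(s); the query hip z is compared with
    the *minimum* coupled reference hip z (the worst case when the
    coupling is one-to-many).  Only excess standoff is flagged — being
    closer to the wall than the reference is good technique, not an error.
    The comparison assumes climbers of similar size; see the torso-length
    warning in the pipeline layer.
    """
    ref_z = reference.joint(JointId.ROOT)[:, 2]
    query_z = query.joint(JointId.ROOT)[:, 2]
    # min reference hip-z per query route frame
    best_ref: dict[int, float] = {}
    for i_ref, j_query in coupling.pairs:
        z = ref_z[reference_limits.start + i_ref]
        if j_query not in best_ref or z < best_ref[j_query]:
            best_ref[j_query] = z
    events: list[ErrorEvent] = []
    for phase in _phases_of(query_phases, PhaseKind.REACHING):
        a, b = phase.interval.start, phase.interval.end
        flags = np.zeros(b - a, dtype=bool)
        for f in range(a, b):
            j = f - query_limits.start
            if j not in best_ref:
                raise RuntimeError(
                    f"DTW coupling is not total: no reference frame for query frame {f}"
                )
            flags[f - a] = query_z[f] - best_ref[j] >= th.k_dhip
        events.extend(
            _flag_runs_to_events(flags, phase, "hip_close_to_wall", th.min_event_frames)
        )
    return events


def detect_all(
    seq: SkeletonSequence,
    phases: Sequence[Phase],
    motion: dict[str, MotionIntervals],
    limits: RouteLimits,
    th: Thresholds | None = None,
    reference: SkeletonSequence | None = None,
    coupling: Coupling | None = None,
    reference_limits: RouteLimits | None = None,
) -> list[ErrorEvent]:
    """Run every applicable detector and return all events sorted by start.

    The hip-close-to-the-wall comparison needs a same-route reference climb
    and its DTW coupling; without one that error type is skipped (reported
    as "not evaluated" by the pipeline layer).
    """
    th = th or Thresholds()
    roles_list = hand_roles_series(seq, limits)
    roles = {limits.start + k: r for k, r in enumerate(roles_list)}
    events: list[ErrorEvent] = []
    events += detect_decoupling(seq, phases, roles, th)
    events += detect_reaching_hand_supports(seq, phases, roles, motion, th)
    events += detect_weight_shift(seq, phases, roles, th)
    events += detect_both_feet_set(seq, phases, motion, th)
    events += detect_shoulder_relaxing(seq, phases, roles, th)
    if reference is not None:
        if coupling is None or reference_limits is None:
            raise ValueError("hip comparison needs both a coupling and reference limits")
        events += detect_hip_close_to_wall(
            seq, reference, coupling, phases, limits, reference_limits, th
        )
    events.sort(key=lambda e: (e.interval.start, e.type))
    _check_phase_gates(events, phases)
    return events


def _check_phase_gates(events: Sequence[ErrorEvent], phases: Sequence[Phase]) -> None:
    """Assert every event lies inside a phase instance of its gated kind."""
    by_id = {p.id: p for p in phases}
    for e in events:
        phase = by_id[e.phase_id]
        assert phase.kind is ERROR_PHASE[e.type], (
            f"{e.type} event outside its phase gate ({phase.kind.value})"
        )
        assert (
            phase.interval.start <= e.interval.start and e.interval.end <= phase.interval.end
        ), f"{e.type} event {e.interval} escapes phase {phase.interval}"


def aggregate_per_phase(
    events: Sequence[ErrorEvent], phases: Sequence[Phase]
) -> tuple[dict[tuple[int, str], int], dict[str, int]]:
    """Per-phase and total error counts.

    Several events of one type inside one phase instance count as a single
    error for that phase — repeated flags within the same movement are one
    mistake.  Returns ``(per_phase, totals)`` where ``per_phase`` maps
    ``(phase_id, error_type)`` to 0/1 and ``totals`` sums per type.
    """
    per_phase: dict[tuple[int, str], int] = {
        (p.id, t): 0 for p in phases for t in ERROR_TYPES
    }
    for e in events:
        per_phase[(e.phase_id, e.type)] = 1
    totals = {t: sum(v for (pid, tt), v in per_phase.items() if tt == t) for t in ERROR_TYPES}
    return per_phase, totals
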