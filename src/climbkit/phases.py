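"""Climbing-phase segmentation: a finite state machine over joint motion.

A climbing route decomposes into repeating cycles of three phases:

* **preparation** — the hands hold, the feet move to their next placements;
* **reaching** — the feet hold, the climber stands up, the hip rises and
  one hand releases to grab the next hold;
* **stabilization** — hands and hip are still, the body settles before the
  next cycle.

The machine starts in stabilization (a climber hangs static at the start
hold) and walks the cycle stabilization → preparation → reaching →
stabilization.  Transitions fire on the motion state of the key joints:
foot motion starts preparation; feet at rest with the hip rising or a hand
moving starts reaching; hands and hip at rest return to stabilization.
Evaluating only the single outgoing edge of the current state resolves the
overlaps the raw per-frame definitions allow (feet and hands moving at
once) and guarantees the cyclic order.

Hand roles are resolved per frame: the *holding* hand is the higher wrist
(it bears the body weight), the other wrist is the *supporting* hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .motion import MotionIntervals, RouteLimits
from .skeleton import FrameInterval, JointId, SkeletonFrame, SkeletonSequence

__all__ = ["PhaseKind", "Phase", "HandRoles", "assign_hands", "hand_roles_series", "segment_phases"]


class PhaseKind(str, Enum):
    PREPARATION = "preparation"
    REACHING = "reaching"
    STABILIZATION = "stabilization"


#: Allowed transitions: the Fig.-1-style cycle, one outgoing edge per state.
_NEXT = {
    PhaseKind.STABILIZATION: PhaseKind.PREPARATION,
    PhaseKind.PREPARATION: PhaseKind.REACHING,
    PhaseKind.REACHING: PhaseKind.STABILIZATION,
}


@dataclass(frozen=True)
class Phase:
    """One phase instance over a frame interval; ``id`` is its ordinal."""

    kind: PhaseKind
    interval: FrameInterval
    id: int

    def to_json(self) -> dict:
        return {"kind": self.kind.value, **self.interval.to_json(), "id": self.id}


@dataclass(frozen=True)
class HandRoles:
    """Wrist roles at one frame: holding = higher wrist, supporting = other."""

    holding: JointId
    supporting: JointId


def assign_hands(frame: SkeletonFrame, previous: HandRoles | None = None) -> HandRoles:
    """Resolve holding/supporting wrists for one wall-space frame.

    The holding hand is the wrist in the higher position.  Exact ties keep
    the previous assignment (roles do not flicker while hands are level);
    with no previous assignment the left wrist holds.
    """
    ly = frame.joint(JointId.LEFT_WRIST)[1]
    ry = frame.joint(JointId.RIGHT_WRIST)[1]
    if ly > ry:
        holding = JointId.LEFT_WRIST
    elif ry > ly:
        holding = JointId.RIGHT_WRIST
    elif previous is not None:
        holding = previous.holding
    else:
        holding = JointId.LEFT_WRIST
    supporting = (
        JointId.RIGHT_WRIST if holding is JointId.LEFT_WRIST else JointId.LEFT_WRIST
    )
    return HandRoles(holding=holding, supporting=supporting)


def hand_roles_series(seq: SkeletonSequence, limits: RouteLimits | None = None) -> list[HandRoles]:
    """Per-frame hand roles over the route (or the whole sequence)."""
    lo, hi = (limits.start, limits.end) if limits is not None else (0, len(seq))
    roles: list[HandRoles] = []
    prev: HandRoles | None = None
    for i in range(lo, hi):
        prev = assign_hands(seq[i], prev)
        roles.append(prev)
    return roles


def segment_phases(
    seq: SkeletonSequence,
    motion: dict[str, MotionIntervals],
    limits: RouteLimits,
    min_phase: int = 5,
) -> list[Phase]:
    """Classify every route frame into a phase instance.

    ``motion`` is the key-joint bundle from
    :func:`climbkit.motion.compute_motion` (wrists ``J7``/``J4``, ankles
    ``J14``/``J11``, vertical hip ``J8y``), with intervals in recording
    frame coordinates.  Runs of identical state become :class:`Phase`
    instances tiling ``[rs, re)``.  A state persists for at least
    ``min_phase`` frames before it may transition, which absorbs
    single-frame flicker at motion-interval boundaries without ever
    skipping a step of the cycle.
    """
    lo, hi = limits.start, limits.end
    if hi <= lo:
        return []
    foot = motion["J14"].mask(lo, hi) | motion["J11"].mask(lo, hi)
    hand = motion["J7"].mask(lo, hi) | motion["J4"].mask(lo, hi)
    hip_y = motion["J8y"].mask(lo, hi)

    states = np.empty(hi - lo, dtype=object)
    state = PhaseKind.STABILIZATION
    dwell = min_phase  # the initial state may transition immediately
    for f in range(hi - lo):
        if dwell >= min_phase:
            if state is PhaseKind.STABILIZATION:
                if foot[f]:
                    state, dwell = PhaseKind.PREPARATION, 0
            elif state is PhaseKind.PREPARATION:
                if not foot[f] and (hip_y[f] or hand[f]):
                    state, dwell = PhaseKind.REACHING, 0
            else:  # REACHING
                if not hand[f] and not hip_y[f]:
                    state, dwell = PhaseKind.STABILIZATION, 0
        states[f] = state
        dwell += 1

    phases = [
        Phase(kind=kind, interval=FrameInterval(lo + a, lo + b), id=i)
        for i, (kind, a, b) in enumerate(_state_runs(states))
    ]
    _check_tiling(phases, limits)
    return phases


def _state_runs(states: np.ndarray) -> list[tuple[PhaseKind, int, int]]:
    runs: list[tuple[PhaseKind, int, int]] = []
    start = 0
    for f in range(1, states.size + 1):
        if f == states.size or states[f] is not states[start]:
            runs.append((states[start], start, f))
            start = f
    return runs


def _check_tiling(phases: list[Phase], limits: RouteLimits) -> None:
    """Assert the output invariants: phases tile [rs, re) and follow the cycle."""
    if not phases:
        return
    assert phases[0].interval.start == limits.start
    assert phases[-1].interval.end == limits.end
    for a, b in zip(phases, phases[1:]):
        assert a.interval.end == b.interval.start, "phases must tile the route"
        assert b.kind is _NEXT[a.kind], (
            f"illegal transition {a.kind.value} -> {b.kind.value}"
        )
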