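"""Shared fixtures: the synthetic validation suite and small builders.

The validation suite (clean climbs plus one-error climbs of every type at
two jitter levels) is expensive enough to build and analyse once per
session; most behavioural tests read from it rather than regenerating
climbs.
"""

from __future__ import annotations

import numpy as np
import pytest

from climbkit import (
    FrameInterval,
    JointId,
    PipelineConfig,
    analyze_sequence,
    make_validation_suite,
)
from climbkit.skeleton import JOINT_ORDER, SkeletonSequence

SUITE_SEED = 0


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def suite():
    """The full validation suite: 2 clean + 12 injected climbs per noise level."""
    return make_validation_suite(seed=SUITE_SEED, per_type=2)


@pytest.fixture(scope="session")
def analyzed_suite(suite, config):
    """Every suite case analysed once: list of (case, AnalysisResult)."""
    out = []
    for case in suite:
        ref = None if case.reference is None else case.reference.sequence
        out.append((case, analyze_sequence(case.climb.sequence, reference=ref, config=config)))
    return out


def make_sequence(
    n: int,
    fps: float = 60.0,
    frame_space: str = "wall",
    **tracks: np.ndarray,
) -> SkeletonSequence:
    """A static 13-joint sequence with selected joints overridden.

    ``tracks`` maps joint labels (``"J8"``) to (n, 3) or (3,) arrays.  The
    base pose spreads the joints so no two coincide.
    """
    positions = np.zeros((n, 13, 3))
    for k, jid in enumerate(JOINT_ORDER):
        positions[:, k] = (100.0 * (k + 1), 50.0 * (k + 1), 30.0)
    for label, track in tracks.items():
        jid = JointId.from_label(label)
        track = np.asarray(track, dtype=float)
        positions[:, jid.index] = track if track.ndim == 2 else np.tile(track, (n, 1))
    return SkeletonSequence(positions=positions, fps=fps, frame_space=frame_space)


def union_iou(detected: list[FrameInterval], truth: list[FrameInterval]) -> float:
    """IoU of the frame-set unions of two interval lists."""
    end = max([iv.end for iv in detected + truth], default=0)
    a = np.zeros(end, dtype=bool)
    b = np.zeros(end, dtype=bool)
    for iv in detected:
        a[iv.start : iv.end] = True
    for iv in truth:
        b[iv.start : iv.end] = True
    union = np.count_nonzero(a | b)
    return 1.0 if union == 0 else np.count_nonzero(a & b) / union


def clip_to_route(intervals, limits) -> list[FrameInterval]:
    """Ground-truth windows restricted to the delimited route."""
    out = []
    for iv in intervals:
        lo, hi = max(iv.start, limits.start), min(iv.end, limits.end)
        if hi > lo:
            out.append(FrameInterval(lo, hi))
    return out
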