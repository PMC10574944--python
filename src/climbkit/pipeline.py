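"""End-to-end analysis: calibrate → delimit → segment → phases → align →
detect → aggregate, with a JSON-first report.

Each stage consumes the previous stage's artifact, so any stage can also
be re-run from persisted intermediates via the CLI; the monolithic
:func:`run_pipeline` is simply the composition and is deterministic given
the configuration (the only randomness, RANSAC, is seeded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import alignment, motion, phases as phases_mod, technique, wall as wall_mod
from .config import PipelineConfig
from .exceptions import StageError
from .motion import MotionIntervals, RouteLimits
from .skeleton import JointId, SkeletonSequence
from .technique import ERROR_TYPES
from .wall import WallModel

__all__ = ["AnalysisResult", "run_pipeline", "analyze_sequence"]

#: One-line coaching hint per error type, included in reports.
HINTS = {
    "decoupling": "Keep the holding arm straight while you set your feet; hang from the skeleton, not the biceps.",
    "reaching_hand_supports": "Leave the supporting hand on its hold longer; reach in one decisive move of under a second.",
    "weight_shift": "Shift the hips over the supporting leg so the knee passes in front of the toe before you stand up.",
    "both_feet_set": "Place or press both feet on the wall before standing up; a dangling foot wastes the push.",
    "hip_close_to_wall": "Bring the hips closer to the wall while reaching; your weight should rest on the toe holds.",
    "shoulder_relaxing": "Stretch the new holding arm after gripping; a locked elbow keeps the muscles loaded.",
}


@dataclass
class AnalysisResult:
    """Everything one analysed climb produces, JSON-serialisable."""

    limits: RouteLimits
    motion: dict[str, MotionIntervals]
    phases: list[phases_mod.Phase]
    events: list[technique.ErrorEvent]
    per_phase: dict[tuple[int, str], int]
    totals: dict[str, int]
    evaluated_types: list[str]

    def to_json(self) -> dict:
        return {
            "route": {"start": self.limits.start, "end": self.limits.end},
            "motion": {k: v.to_json() for k, v in sorted(self.motion.items())},
            "phases": [p.to_json() for p in self.phases],
            "events": [e.to_json() for e in self.events],
            "per_phase_counts": [
                {"phase_id": pid, "type": t, "count": c}
                for (pid, t), c in sorted(self.per_phase.items())
            ],
            "totals": {t: self.totals.get(t) for t in ERROR_TYPES},
            "evaluated_types": self.evaluated_types,
            "hints": {t: HINTS[t] for t in ERROR_TYPES if self.totals.get(t)},
        }


def _to_wall(seq: SkeletonSequence, wall: WallModel | None) -> SkeletonSequence:
    if seq.frame_space == "wall":
        return seq
    if wall is None:
        raise StageError("calibration", ValueError("camera-space sequence but no wall model"))
    return wall_mod.to_wall_coords(seq, wall)


def _torso_length(seq: SkeletonSequence) -> float:
    sh = (seq.joint(JointId.LEFT_SHOULDER) + seq.joint(JointId.RIGHT_SHOULDER)) / 2.0
    return float(np.median(np.linalg.norm(sh - seq.joint(JointId.ROOT), axis=1)))


def analyze_sequence(
    seq: SkeletonSequence,
    wall: WallModel | None = None,
    reference: SkeletonSequence | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Analyse one climb; optionally compare hip standoff to a reference.

    ``seq`` (and ``reference``) may be in camera space, in which case a
    wall model is required to re-express them in wall coordinates.  When a
    reference is given its torso length is compared with the climber's and
    a warning is emitted beyond 10 % difference — the hip-standoff
    threshold assumes climbers of similar build.
    """
    cfg = config or PipelineConfig()
    seq = _to_wall(seq, wall)
    try:
        limits = motion.delimit_route(seq)
    except Exception as exc:
        raise StageError("route-delimitation", exc) from exc
    seg_kwargs = dict(
        n=cfg.n_sigma,
        window=cfg.window,
        rho=cfg.rho,
        min_len=cfg.thresholds.k_mu,
        smooth_window=cfg.smooth_window,
        spike_window=cfg.spike_window,
    )
    bundle = motion.compute_motion(seq, limits, **seg_kwargs)
    phase_list = phases_mod.segment_phases(seq, bundle, limits, min_phase=cfg.min_phase_frames)

    coupling = None
    ref_limits = None
    evaluated = [t for t in ERROR_TYPES if t != "hip_close_to_wall"]
    ref_wall = None
    if reference is not None:
        reference = _to_wall(reference, wall)
        ref_limits = motion.delimit_route(reference)
        coupling = alignment.align_climbs(reference, seq, ref_limits, limits)
        t_ref, t_query = _torso_length(reference), _torso_length(seq)
        if abs(t_ref - t_query) > 0.1 * t_ref:
            warnings.warn(
                "climber and reference torso lengths differ by more than 10%; "
                "the hip-standoff threshold may not transfer between builds",
                stacklevel=2,
            )
        evaluated = list(ERROR_TYPES)
    events = technique.detect_all(
        seq,
        phase_list,
        bundle,
        limits,
        th=cfg.thresholds,
        reference=reference,
        coupling=coupling,
        reference_limits=ref_limits,
    )
    per_phase, totals = technique.aggregate_per_phase(events, phase_list)
    if reference is None:
        totals["hip_close_to_wall"] = None  # not evaluated without a reference
    return AnalysisResult(
        limits=limits,
        motion=bundle,
        phases=phase_list,
        events=events,
        per_phase=per_phase,
        totals=totals,
        evaluated_types=evaluated,
    )


def run_pipeline(
    seq: SkeletonSequence,
    cloud: np.ndarray | None = None,
    reference: SkeletonSequence | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Full pipeline from raw inputs to the JSON report.

    When a calibration cloud is given the wall model is fitted first and
    camera-space sequences are re-expressed in wall coordinates.
    Deterministic: rerunning with the same inputs and config yields a
    byte-identical report.
    """
    cfg = config or PipelineConfig()
    wall = None
    if cloud is not None:
        try:
            wall = wall_mod.build_wall_model(
                cloud,
                iterations=cfg.ransac_iterations,
                inlier_tol=cfg.ransac_inlier_tol,
                seed=cfg.seed,
            )
        except Exception as exc:
            raise StageError("calibration", exc) from exc
    result = analyze_sequence(seq, wall=wall, reference=reference, config=cfg)
    report = {"config": cfg.to_json(), **result.to_json()}
    if wall is not None:
        report["wall"] = wall.to_json()
    return report
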