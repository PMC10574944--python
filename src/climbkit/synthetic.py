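"""Scripted synthetic climbs with exact ground truth.

No public dataset of labelled climbing recordings exists, so the test bed
is generated: a keyframe-animated 13-joint climber executes repeating
phase cycles on a parameterised wall —

* **preparation**: hands hold, each foot steps up to its next placement
  (two overlapping constant-velocity moves);
* **reaching**: feet hold, the lower (supporting) hand reaches past the
  other wrist to the next hold while the hip rises;
* **stabilization**: everything at rest, holding arm stretched.

Clean scripts satisfy every technique rule with a wide margin (holding
arm ≈ 172°, supporting-hand motion well under 1 s, knee 300 mm past the
foot, feet 30 mm off the wall, hip standoff equal to the reference).
An injected error violates exactly one rule by a parameterised margin
inside a known frame window, which becomes the ground-truth label.
Measurement noise is modelled as i.i.d. Gaussian keypoint jitter plus
occasional 5-frame spike artifacts, the two failure modes of video-based
pose estimation that the segmentation thresholds exist to absorb.

Everything is deterministic given the script seed; the geometry is
identical across seeds and only the noise differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .evaluation import LabeledError
from .exceptions import ScriptError
from .phases import Phase, PhaseKind
from .skeleton import FrameInterval, JointId, SkeletonSequence
from .wall import WallModel

__all__ = [
    "WallSpec",
    "BodyProportions",
    "ErrorInjection",
    "ClimbScript",
    "SyntheticClimb",
    "generate_climb",
    "generate_wall_cloud",
    "SuiteCase",
    "make_validation_suite",
]


@dataclass(frozen=True)
class WallSpec:
    """Rectangular climbing wall with an optional backward tilt."""

    width: float = 3000.0  # mm
    height: float = 4000.0  # mm
    tilt_deg: float = 8.0  # rotation of the wall about its horizontal axis
    distance: float = 4200.0  # camera-to-wall standoff, mm
    origin_cam: tuple[float, float, float] = (1500.0, 1900.0, 4200.0)

    def wall_model(self) -> WallModel:
        """Ground-truth wall model: axes of the wall frame expressed in the
        camera frame, origin at the upper reference corner.

        With y up the wall and z along the normal toward the camera, the
        right-handed x-axis (x × y = z) points camera-left — the wall's own
        rightward direction for someone standing at the wall."""
        tau = np.radians(self.tilt_deg)
        x_w = np.array([-1.0, 0.0, 0.0])
        y_w = np.array([0.0, np.cos(tau), np.sin(tau)])
        n_w = np.array([0.0, np.sin(tau), -np.cos(tau)])  # toward the camera
        o = np.asarray(self.origin_cam, dtype=float)
        R = np.vstack([x_w, y_w, n_w])
        corners = np.array(
            [o, o + self.width * x_w, o + self.width * x_w - self.height * y_w, o - self.height * y_w]
        )
        return WallModel(
            normal=n_w,
            origin=o,
            rotation=R,
            translation=-R @ o,
            width=self.width,
            height=self.height,
            corners=corners,
        )


@dataclass(frozen=True)
class BodyProportions:
    """Climber proportions, millimetres.  Defaults describe an average
    adult; they are parameters because the hip-standoff comparison is only
    meaningful between climbers of similar build."""

    shoulder_width: float = 400.0
    hip_width: float = 300.0
    torso: float = 500.0  # hip centre to shoulder line
    hand_dx: float = 150.0  # wrist lateral offset from the body midline
    foot_dx: float = 120.0
    knee_forward: float = 300.0  # knee x-lead over the ankle while standing up
    knee_up: float = 250.0
    knee_z: float = 70.0
    hip_z: float = 200.0  # hip standoff from the wall
    hand_z: float = 30.0
    foot_z: float = 30.0
    elbow_angle: float = 172.0  # scripted elbow angle of a stretched arm, deg


@dataclass(frozen=True)
class ErrorInjection:
    """One deliberately executed technique error in one cycle.

    ``magnitude`` overrides the type-specific default: bent-arm angle in
    degrees for the angle rules, knee x-lead in mm for weight_shift, foot
    lift in mm for both_feet_set, hip standoff excess in mm for
    hip_close_to_wall, and the slowed reach duration in frames for
    reaching_hand_supports.
    """

    type: str
    cycle: int
    magnitude: float | None = None


_INJECTION_DEFAULTS = {
    "decoupling": 110.0,  # deg
    "shoulder_relaxing": 110.0,  # deg
    "weight_shift": 100.0,  # mm knee lead (threshold 200)
    "both_feet_set": 300.0,  # mm foot lift (tolerance 150)
    "hip_close_to_wall": 100.0,  # mm excess standoff (threshold 50)
    "reaching_hand_supports": 150.0,  # frames of slowed reach (Kt = 60 frames)
}


@dataclass(frozen=True)
class ClimbScript:
    """Full specification of one synthetic climb."""

    wall: WallSpec = WallSpec()
    body: BodyProportions = BodyProportions()
    n_cycles: int = 3
    prep_frames: int = 150
    reach_frames: int = 100
    stab_frames: int = 90
    hand_move_frames: int = 90
    foot_move_frames: int = 100
    pre_roll: int = 60
    post_roll: int = 90
    fps: float = 60.0
    hip_rise: float = 500.0  # per cycle, mm
    hand_rise: float = 1000.0  # per reach, mm (ends 500 above the other wrist)
    foot_rise: float = 500.0  # per step, mm
    hip_x_drift: float = 30.0  # lateral hip travel per reach, mm
    jitter_sigma: float = 5.0  # mm
    spike_prob: float = 0.01  # per joint per frame
    spike_mm: float = 40.0
    spike_frames: int = 5
    injections: tuple[ErrorInjection, ...] = ()
    has_reference: bool = False  # a same-route reference climb will be supplied
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cycles",
            "prep_frames",
            "reach_frames",
            "stab_frames",
            "hand_move_frames",
            "foot_move_frames",
        ):
            if getattr(self, name) < 1:
                raise ScriptError(f"{name} must be >= 1")
        if self.hand_move_frames > self.reach_frames:
            raise ScriptError("hand_move_frames cannot exceed reach_frames")
        if 2 * self.foot_move_frames < self.prep_frames:
            raise ScriptError("foot moves must cover the preparation phase")
        for inj in self.injections:
            if inj.type not in _INJECTION_DEFAULTS:
                raise ScriptError(f"unknown injection type {inj.type!r}")
            if not (0 <= inj.cycle < self.n_cycles):
                raise ScriptError(f"injection cycle {inj.cycle} out of range")
        if (
            any(i.type == "hip_close_to_wall" for i in self.injections)
            and not self.has_reference
        ):
            raise ScriptError(
                "hip_close_to_wall injection requires a same-route reference climb "
                "(set has_reference=True and analyse against the clean counterpart)"
            )

    def clean(self) -> "ClimbScript":
        """The noiseless, error-free counterpart (used as reference climb)."""
        return replace(
            self, injections=(), jitter_sigma=0.0, spike_prob=0.0, has_reference=False
        )


@dataclass
class SyntheticClimb:
    """A generated climb with exact ground truth."""

    sequence: SkeletonSequence
    wall: WallModel
    gt_phases: list[Phase]
    labels: list[LabeledError]
    script: ClimbScript

    def gt_phase_of(self, frame: int) -> PhaseKind:
        for p in self.gt_phases:
            if frame in p.interval:
                return p.kind
        raise IndexError(f"frame {frame} outside the scripted timeline")

    def gt_motion_windows(self) -> dict[str, list[FrameInterval]]:
        """Scripted motion windows per key joint (recording frames)."""
        return dict(self._motion_windows)

    _motion_windows: dict[str, list[FrameInterval]] = field(default_factory=dict)


class _Track:
    """Piecewise constant-velocity 3-D track over n frames."""

    def __init__(self, n: int, start: np.ndarray):
        self.n = n
        self.values = np.empty((n, 3), dtype=float)
        self.cur = np.asarray(start, dtype=float).copy()
        self.t = 0

    def hold_until(self, t: int) -> None:
        if t > self.t:
            self.values[self.t : t] = self.cur
            self.t = t

    def move(self, t0: int, t1: int, target: np.ndarray) -> None:
        """Constant-velocity move over [t0, t1); at rest at ``target`` after."""
        self.hold_until(t0)
        m = t1 - t0
        target = np.asarray(target, dtype=float)
        steps = (np.arange(1, m + 1) / m)[:, None]
        self.values[t0:t1] = self.cur + steps * (target - self.cur)
        self.cur = target.copy()
        self.t = t1

    def finish(self) -> np.ndarray:
        self.hold_until(self.n)
        return self.values


def _elbows(shoulder: np.ndarray, wrist: np.ndarray, angle_deg: np.ndarray, side: float) -> np.ndarray:
    """Elbow positions realising a target interior elbow angle per frame.

    The elbow sits at the shoulder–wrist midpoint plus a horizontal
    in-plane offset h = (d/2)·cot(φ/2), which yields exactly the angle φ
    at the elbow; ``side`` (±1) points the offset away from the body."""
    u = wrist - shoulder
    d = np.linalg.norm(u, axis=1)
    z = np.array([0.0, 0.0, 1.0])
    p = np.cross(u, z)
    p_norm = np.linalg.norm(p, axis=1)
    p_norm = np.where(p_norm < 1e-9, 1.0, p_norm)
    p = p / p_norm[:, None]
    p = p * np.where(p[:, 0] * side >= 0, 1.0, -1.0)[:, None]
    h = (d / 2.0) / np.tan(np.radians(angle_deg) / 2.0)
    return (shoulder + wrist) / 2.0 + h[:, None] * p


def generate_climb(
    script: ClimbScript, space: Literal["wall", "camera"] = "wall"
) -> SyntheticClimb:
    """Generate a climb from a script; deterministic given ``script.seed``.

    Returns the skeleton sequence (wall or camera coordinates), the
    ground-truth wall model, the scripted phase timeline, and one
    ground-truth label per injected error.
    """
    b = script.body
    wall = script.wall.wall_model()
    xc = script.wall.width / 2.0
    y0 = -script.wall.height + 1000.0  # starting hip height above the wall base

    # --- cycle timing (a slowed reach stretches its cycle) -----------------
    reach_len = {c: script.reach_frames for c in range(script.n_cycles)}
    hand_len = {c: script.hand_move_frames for c in range(script.n_cycles)}
    inj_by_cycle: dict[tuple[str, int], ErrorInjection] = {}
    for inj in script.injections:
        inj_by_cycle[(inj.type, inj.cycle)] = inj
        if inj.type == "reaching_hand_supports":
            slow = int(inj.magnitude or _INJECTION_DEFAULTS["reaching_hand_supports"])
            reach_len[inj.cycle] = slow
            hand_len[inj.cycle] = slow

    starts: list[tuple[int, int, int, int]] = []  # (prep0, reach0, stab0, stab_end)
    t = script.pre_roll
    for c in range(script.n_cycles):
        p0 = t
        r0 = p0 + script.prep_frames
        s0 = r0 + reach_len[c]
        t = s0 + script.stab_frames
        starts.append((p0, r0, s0, t))
    n = t + script.post_roll

    # --- driver tracks -----------------------------------------------------
    # The hip starts 40 mm low and rises as the climber pulls onto the wall,
    # so the route-start frame (lowest hip) is pinned near frame 0 even
    # under jitter rather than wandering over a flat plateau.
    hip = _Track(n, np.array([xc, y0 - 40.0, b.hip_z]))
    hip.move(10, 40, np.array([xc, y0, b.hip_z]))
    hand_l = _Track(n, np.array([xc - b.hand_dx, y0 + 800.0, b.hand_z]))
    hand_r = _Track(n, np.array([xc + b.hand_dx, y0 + 300.0, b.hand_z]))
    foot_l = _Track(n, np.array([xc - b.foot_dx, y0 - 600.0, b.foot_z]))
    foot_r = _Track(n, np.array([xc + b.foot_dx, y0 - 700.0, b.foot_z]))

    movers = [JointId.RIGHT_WRIST if c % 2 == 0 else JointId.LEFT_WRIST for c in range(script.n_cycles)]
    motion_windows: dict[str, list[FrameInterval]] = {k: [] for k in ("J7", "J4", "J8", "J14", "J11", "J8y")}

    for c, (p0, r0, s0, _) in enumerate(starts):
        # preparation: two overlapping foot steps, staggered by half a move
        f2 = p0 + script.prep_frames - script.foot_move_frames
        foot_l.move(p0, p0 + script.foot_move_frames, foot_l.cur + [0.0, script.foot_rise, 0.0])
        foot_r.move(f2, f2 + script.foot_move_frames, foot_r.cur + [0.0, script.foot_rise, 0.0])
        motion_windows["J14"].append(FrameInterval(p0, p0 + script.foot_move_frames))
        motion_windows["J11"].append(FrameInterval(f2, f2 + script.foot_move_frames))
        # reaching: the lower hand reaches past the other wrist; the hip
        # rises at its normal pace even in a slowed (injected) reach — the
        # body arrives while the hand lags.  A slowed reach starts with a
        # quick downward regrip, deepening the height deficit the slow hand
        # must climb back.  The final reach ends with a 30 mm deadpoint
        # overshoot and settle, which pins the route-end frame (wrist
        # maximum) to a single scripted frame.
        mover = hand_r if movers[c] is JointId.RIGHT_WRIST else hand_l
        hl = hand_len[c]
        slow = ("reaching_hand_supports", c) in inj_by_cycle
        last = c == script.n_cycles - 1
        rise = script.hand_rise
        t0 = r0
        if slow:
            mover.move(t0, t0 + 10, mover.cur + [0.0, -150.0, 0.0])
            t0 += 10
            rise += 150.0
        if last:
            mover.move(t0, r0 + hl - 10, mover.cur + [0.0, rise + 30.0, 0.0])
            mover.move(r0 + hl - 10, r0 + hl, mover.cur + [0.0, -30.0, 0.0])
        else:
            mover.move(t0, r0 + hl, mover.cur + [0.0, rise, 0.0])
        hip.move(r0, r0 + script.reach_frames, hip.cur + [script.hip_x_drift, script.hip_rise, 0.0])
        key = "J4" if movers[c] is JointId.RIGHT_WRIST else "J7"
        # The scripted window covers the reach proper; the 10-frame
        # deadpoint settle, like the sag and pull-on, is sub-threshold by
        # design and not a recorded movement.
        motion_windows[key].append(FrameInterval(r0, r0 + (hl - 10 if last else hl)))
        motion_windows["J8"].append(FrameInterval(r0, r0 + script.reach_frames))
        motion_windows["J8y"].append(FrameInterval(r0, r0 + script.reach_frames))

    # Both wrists sag 20 mm through the final stabilization: a slow
    # relaxation well below the motion-detection floor that makes every
    # wrist's height maximum a scripted event, bounding the route end.
    sag_start = starts[-1][2]
    for hand in (hand_l, hand_r):
        hand.move(max(sag_start, hand.t), n, hand.cur + [0.0, -20.0, 0.0])

    hip_v = hip.finish()
    hand_lv = hand_l.finish()
    hand_rv = hand_r.finish()
    foot_lv = foot_l.finish()
    foot_rv = foot_r.finish()

    # --- per-frame modifier arrays and injection windows -------------------
    angle_l = np.full(n, b.elbow_angle)
    angle_r = np.full(n, b.elbow_angle)
    knee_lead = np.full(n, b.knee_forward)
    labels: list[LabeledError] = []

    def holding_arm_of_prep(c: int) -> JointId:
        return JointId.LEFT_WRIST if c == 0 else movers[c - 1]

    for (etype, c), inj in inj_by_cycle.items():
        p0, r0, s0, c_end = starts[c]
        mag = inj.magnitude if inj.magnitude is not None else _INJECTION_DEFAULTS[etype]
        # Angle windows sit 25 frames inside their phase so that detected
        # phase boundaries (a few frames off under jitter) cannot push
        # bent-arm frames into the neighbouring phase.
        if etype == "decoupling":
            w = FrameInterval(p0 + 25, r0 - 25)
            arm = angle_l if holding_arm_of_prep(c) is JointId.LEFT_WRIST else angle_r
            arm[w.start : w.end] = mag
        elif etype == "shoulder_relaxing":
            w = FrameInterval(s0 + 25, c_end - 25)
            arm = angle_l if movers[c] is JointId.LEFT_WRIST else angle_r
            arm[w.start : w.end] = mag
        elif etype == "weight_shift":
            length = s0 - r0
            w = FrameInterval(r0 + length // 4, r0 + (3 * length) // 4)
            knee_lead[w.start : w.end] = mag
        elif etype == "both_feet_set":
            w = FrameInterval(r0 + 5, s0 - 5)
            foot_lv[w.start : w.end, 2] = mag
        elif etype == "hip_close_to_wall":
            w = FrameInterval(r0 + 5, s0 - 5)
            hip_v[w.start : w.end, 2] += mag
        else:  # reaching_hand_supports: the slowed reach itself is the error.
            # The label covers the span in which the moving hand is still
            # the lower (supporting) one, read off the scripted geometry:
            # from the reach start until it passes the other wrist.
            if movers[c] is JointId.RIGHT_WRIST:
                mover_y, other_y = hand_rv[:, 1], hand_lv[:, 1]
            else:
                mover_y, other_y = hand_lv[:, 1], hand_rv[:, 1]
            below = mover_y[r0 : r0 + hand_len[c]] < other_y[r0 : r0 + hand_len[c]]
            w = FrameInterval(r0, r0 + int(np.count_nonzero(below)))
        labels.append(LabeledError(type=etype, interval=w))

    # --- assemble the 13 joints -------------------------------------------
    pos = np.empty((n, 13, 3), dtype=float)
    half_sh = np.array([b.shoulder_width / 2.0, 0.0, 0.0])
    half_hip = np.array([b.hip_width / 2.0, 0.0, 0.0])
    up = np.array([0.0, b.torso, 0.0])
    sh_l = hip_v + up - half_sh
    sh_r = hip_v + up + half_sh
    knee_off = np.column_stack([knee_lead, np.full(n, b.knee_up), np.full(n, b.knee_z)])

    pos[:, JointId.ROOT.index] = hip_v
    pos[:, JointId.LEFT_HIP.index] = hip_v - half_hip
    pos[:, JointId.RIGHT_HIP.index] = hip_v + half_hip
    pos[:, JointId.LEFT_SHOULDER.index] = sh_l
    pos[:, JointId.RIGHT_SHOULDER.index] = sh_r
    pos[:, JointId.LEFT_WRIST.index] = hand_lv
    pos[:, JointId.RIGHT_WRIST.index] = hand_rv
    pos[:, JointId.LEFT_ELBOW.index] = _elbows(sh_l, hand_lv, angle_l, side=-1.0)
    pos[:, JointId.RIGHT_ELBOW.index] = _elbows(sh_r, hand_rv, angle_r, side=1.0)
    pos[:, JointId.LEFT_ANKLE.index] = foot_lv
    pos[:, JointId.RIGHT_ANKLE.index] = foot_rv
    pos[:, JointId.LEFT_KNEE.index] = foot_lv + knee_off
    pos[:, JointId.RIGHT_KNEE.index] = foot_rv + knee_off

    # --- measurement noise -------------------------------------------------
    rng = np.random.default_rng(script.seed)
    if script.jitter_sigma > 0:
        pos = pos + rng.normal(0.0, script.jitter_sigma, size=pos.shape)
    if script.spike_prob > 0:
        for j in range(13):
            for s in np.flatnonzero(rng.random(n) < script.spike_prob):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos[s : s + script.spike_frames, j] += script.spike_mm * direction

    # --- ground-truth phase timeline ---------------------------------------
    gt: list[tuple[PhaseKind, int, int]] = [(PhaseKind.STABILIZATION, 0, starts[0][0])]
    for c, (p0, r0, s0, c_end) in enumerate(starts):
        gt.append((PhaseKind.PREPARATION, p0, r0))
        gt.append((PhaseKind.REACHING, r0, s0))
        end = n if c == script.n_cycles - 1 else c_end  # last stab absorbs post-roll
        gt.append((PhaseKind.STABILIZATION, s0, end))
    gt_phases = [
        Phase(kind=k, interval=FrameInterval(a, bnd), id=i) for i, (k, a, bnd) in enumerate(gt)
    ]

    if space == "camera":
        seq = SkeletonSequence(
            positions=wall.inverse_transform_points(pos), fps=script.fps, frame_space="camera"
        )
    else:
        seq = SkeletonSequence(positions=pos, fps=script.fps, frame_space="wall")
    climb = SyntheticClimb(
        sequence=seq, wall=wall, gt_phases=gt_phases, labels=labels, script=script
    )
    climb._motion_windows = motion_windows
    return climb


def generate_wall_cloud(
    wall: WallSpec,
    n_points: int = 5000,
    noise_sigma: float = 5.0,
    outlier_fraction: float = 0.1,
    seed: int | None = None,
) -> tuple[np.ndarray, WallModel]:
    """Synthetic calibration point cloud in camera coordinates.

    ``n_points`` samples uniformly cover the wall rectangle with Gaussian
    noise of ``noise_sigma`` mm along the wall normal.  Outliers
    (``outlier_fraction`` · n_points of them) model scene clutter between
    the camera and the wall: uniform over the wall footprint but 100–2000
    mm in front of the plane.  Returns the cloud and the ground-truth
    wall model.
    """
    if n_points < 100:
        raise ScriptError(f"n_points must be >= 100, got {n_points}")
    rng = np.random.default_rng(seed)
    model = wall.wall_model()
    xy = rng.uniform([0.0, -wall.height], [wall.width, 0.0], size=(n_points, 2))
    z = rng.normal(0.0, noise_sigma, size=n_points) if noise_sigma > 0 else np.zeros(n_points)
    pts_wall = np.column_stack([xy, z])
    n_out = int(round(outlier_fraction * n_points))
    if n_out:
        out_xy = rng.uniform([0.0, -wall.height], [wall.width, 0.0], size=(n_out, 2))
        out_z = rng.uniform(100.0, 2000.0, size=n_out)
        pts_wall = np.vstack([pts_wall, np.column_stack([out_xy, out_z])])
    cloud = model.inverse_transform_points(pts_wall)
    return cloud, model


# ---------------------------------------------------------------------------
# The validation suite: the standing set of study conditions
# ---------------------------------------------------------------------------


@dataclass
class SuiteCase:
    name: str
    climb: SyntheticClimb
    reference: SyntheticClimb | None
    injected: str | None  # error type, or None for a clean climb
    sigma: float


#: Cycles eligible for injection per type.  The route trimmer may cut into
#: the first preparation (the hip is still at its minimum there) and into
#: the final stabilization (the wrist maximum is reached just before it),
#: so windows that could be truncated are avoided by construction.
_INJECTION_CYCLES: dict[str, tuple[int, ...]] = {
    "decoupling": (1, 2),
    "shoulder_relaxing": (0, 1),
    "reaching_hand_supports": (1, 2),
    "weight_shift": (1, 2),
    "both_feet_set": (1, 2),
    "hip_close_to_wall": (1, 2),
}


def make_validation_suite(
    seed: int = 0,
    sigmas: tuple[float, ...] = (0.0, 5.0),
    per_type: int = 2,
    n_clean: int = 2,
    n_cycles: int = 3,
) -> list[SuiteCase]:
    """The scripted evaluation suite: clean climbs plus one-error climbs of
    every type, at each jitter level.  Hip-standoff cases carry their
    noiseless clean counterpart as the reference climb."""
    from .technique import ERROR_TYPES

    cases: list[SuiteCase] = []
    base = int(seed) % (2**31 - 1)
    for sigma in sigmas:
        spikes = 0.01 if sigma > 0 else 0.0
        for k in range(n_clean):
            script = ClimbScript(
                n_cycles=n_cycles, jitter_sigma=sigma, spike_prob=spikes, seed=base + 1000 + k
            )
            cases.append(
                SuiteCase(
                    name=f"clean-{k}-s{sigma:g}",
                    climb=generate_climb(script),
                    reference=None,
                    injected=None,
                    sigma=sigma,
                )
            )
        for t_idx, etype in enumerate(ERROR_TYPES):
            for k in range(per_type):
                cycle = _INJECTION_CYCLES[etype][k % len(_INJECTION_CYCLES[etype])]
                script = ClimbScript(
                    n_cycles=n_cycles,
                    jitter_sigma=sigma,
                    spike_prob=spikes,
                    injections=(ErrorInjection(type=etype, cycle=cycle),),
                    has_reference=(etype == "hip_close_to_wall"),
                    seed=base + 2000 + 100 * t_idx + k,
                )
                reference = (
                    generate_climb(script.clean()) if etype == "hip_close_to_wall" else None
                )
                cases.append(
                    SuiteCase(
                        name=f"{etype}-{k}-s{sigma:g}",
                        climb=generate_climb(script),
                        reference=reference,
                        injected=etype,
                        sigma=sigma,
                    )
                )
    return cases
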