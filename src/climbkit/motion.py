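"""Per-joint speed signals, standard-score motion segmentation, and
automatic route delimitation.

Phase transitions are driven by *which joints move when*.  A joint's
in-plane speed is turned into a smooth envelope (rolling mean plus ``n``
rolling standard deviations of the speed — the "n-σ graph"), and frames
where the envelope exceeds half of its global maximum Ok are declared
motion.  Candidate movements shorter than ``Kμ`` frames are discarded as
keypoint jitter: frame-to-frame noise in estimated joint positions
masquerades as motion, and Kμ is the guard against it.

Route delimitation finds the analysed portion of a recording: the climber
may walk in, chalk up, and after topping out jump off or down-climb, so
the route runs from the frame where the hip is lowest (first half of the
video) to the last frame where either wrist reaches its highest point
(second half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

from .exceptions import ConstantSignalError, DelimitationError, TooShortError
from .skeleton import FrameInterval, JointId, SkeletonSequence

__all__ = [
    "Axis",
    "SpeedSeries",
    "MotionIntervals",
    "RouteLimits",
    "joint_speed",
    "zscore_series",
    "segment_motion",
    "delimit_route",
    "compute_motion",
]

Axis = Literal["xy", "y", "z"]

_AXIS_COLUMNS: dict[str, tuple[int, ...]] = {"xy": (0, 1), "y": (1,), "z": (2,)}


@dataclass
class SpeedSeries:
    """Per-frame speed magnitude of one joint along an axis selection, mm/s."""

    values: np.ndarray
    joint: JointId
    axis: Axis
    fps: float = 60.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SpeedSeries values must be 1-D")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class MotionIntervals:
    """Disjoint, sorted frame intervals during which one joint is in motion."""

    joint: JointId
    axis: Axis
    intervals: list[FrameInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping motion intervals {a} and {b}")

    def __contains__(self, frame: int) -> bool:
        return any(frame in iv for iv in self.intervals)

    def mask(self, start: int, end: int) -> np.ndarray:
        """Boolean in-motion mask over the frame range [start, end)."""
        m = np.zeros(end - start, dtype=bool)
        for iv in self.intervals:
            lo, hi = max(iv.start, start), min(iv.end, end)
            if lo < hi:
                m[lo - start : hi - start] = True
        return m

    def total_frames(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def to_json(self) -> dict:
        return {
            "joint": self.joint.label,
            "axis": self.axis,
            "intervals": [iv.to_json() for iv in self.intervals],
        }


@dataclass(frozen=True)
class RouteLimits:
    """Frame range [start, end) of the climbing route within the recording."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DelimitationError(f"invalid route limits [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Speed and standard score
# ---------------------------------------------------------------------------


def joint_speed(
    seq: SkeletonSequence,
    joint: JointId,
    axis: Axis = "xy",
    smooth_window: int = 15,
    spike_window: int = 7,
) -> SpeedSeries:
    """Speed of one joint projected onto an axis selection, mm/s.

    The velocity is a centred finite difference of the projected position
    (endpoints handled by edge replication) scaled by the frame rate.  Two
    denoising steps act on the velocity *components* before the magnitude
    is taken:

    * a centred median filter of width ``spike_window`` rejects the short
      velocity impulses that isolated keypoint-spike artifacts produce,
      without displacing step edges;
    * a centred moving average of width ``smooth_window`` lets zero-mean
      keypoint jitter cancel.  (Smoothing the rectified magnitude instead
      would leave a spurious noise floor proportional to the jitter
      amplitude, which is why the vector is smoothed.)

    ``axis='xy'`` projects onto the wall plane (the projection used for
    phase logic), ``'y'`` keeps only vertical motion (hip rise), ``'z'``
    only motion off the wall.
    """
    if len(seq) < 3:
        raise TooShortError(f"need at least 3 frames to estimate speed, got {len(seq)}")
    for name, value in (("smooth_window", smooth_window), ("spike_window", spike_window)):
        if value < 1 or value % 2 == 0:
            raise ValueError(f"{name} must be odd and >= 1, got {value}")
    cols = _AXIS_COLUMNS[axis]
    pos = seq.joint(joint)[:, cols]
    padded = np.concatenate([pos[:1], pos, pos[-1:]], axis=0)
    vel = (padded[2:] - padded[:-2]) * (seq.fps / 2.0)
    if spike_window > 1:
        vel = median_filter(vel, size=(spike_window, 1), mode="nearest")
    if smooth_window > 1:
        vel = uniform_filter1d(vel, size=smooth_window, axis=0, mode="nearest")
    speed = np.linalg.norm(vel, axis=1)
    return SpeedSeries(values=speed, joint=joint, axis=axis, fps=seq.fps)


def zscore_series(speed: SpeedSeries) -> np.ndarray:
    """Standard score of a speed series: z = (v − μ)/σ.

    μ and σ are taken over the whole series with the population (ddof=0)
    standard deviation, so the result is reproducible regardless of series
    length.  A constant series has no scale and raises
    :class:`ConstantSignalError`, which callers treat as "no motion".
    """
    v = speed.values
    if v.size < 2:
        raise TooShortError("z-score needs at least 2 samples")
    mu = float(np.mean(v))
    sigma = float(np.std(v))  # population
    if sigma == 0.0:
        raise ConstantSignalError("constant speed series: standard score undefined")
    return (v - mu) / sigma


# ---------------------------------------------------------------------------
# Motion segmentation
# ---------------------------------------------------------------------------


def segment_motion(
    speed: SpeedSeries,
    n: float = 2.0,
    window: int = 3,
    rho: float = 0.5,
    min_len: int = 30,
    offset: int = 0,
) -> MotionIntervals:
    """Motion intervals of one joint from its speed signal.

    Builds the n-σ envelope ``g(f) = rolling_mean(v, window) + n ·
    rolling_std(v, window)`` (centred, population std), takes its global
    maximum Ok, and declares motion where ``g ≥ rho · Ok`` — equivalently,
    where g crosses above its complement ``Ok − g`` for the default
    rho = 0.5.  Maximal runs shorter than ``min_len`` (the Kμ jitter
    threshold) are discarded.  A constant signal yields no intervals.

    ``offset`` shifts the reported frame indices, so intervals computed on
    a route-trimmed subsequence can be reported in recording coordinates.
    """
    if window < 3:
        raise ValueError(f"window must be >= 3, got {window}")
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must lie in (0, 1), got {rho}")
    v = speed.values
    result = MotionIntervals(joint=speed.joint, axis=speed.axis, intervals=[])
    if v.size == 0 or np.ptp(v) == 0.0:
        return result  # constant signal: no motion
    s = pd.Series(v)
    roll = s.rolling(window, center=True, min_periods=1)
    g = (roll.mean() + n * roll.std(ddof=0)).to_numpy()
    ok = float(np.max(g))
    if ok <= 0.0:
        return result
    mask = g >= rho * ok
    intervals: list[FrameInterval] = []
    runs = _runs(mask)
    for lo, hi in runs:
        if hi - lo >= min_len:
            intervals.append(FrameInterval(lo + offset, hi + offset))
    result.intervals = intervals
    _warn_uneven_segments(v, intervals, offset, speed.joint)
    return result


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _warn_uneven_segments(
    v: np.ndarray, intervals: list[FrameInterval], offset: int, joint: JointId
) -> None:
    """Warn when detected segments differ in peak speed by more than 4×.

    The 50 %-of-global-maximum rule can miss low-amplitude moves when one
    movement is much faster than the rest of the route."""
    if len(intervals) < 2:
        return
    peaks = [float(np.max(v[iv.start - offset : iv.end - offset])) for iv in intervals]
    if max(peaks) > 4.0 * min(peaks):
        warnings.warn(
            f"{joint.label}: motion segment peak speeds differ by more than 4x; "
            "low-amplitude movements may be missed (consider lowering rho)",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# Route delimitation
# ---------------------------------------------------------------------------


def delimit_route(seq: SkeletonSequence) -> RouteLimits:
    """Start and end frame of the climbing route within a wall-space recording.

    The start ``rs`` is the first frame in the first half of the video at
    which the hip centre is lowest; the end ``re`` is the last frame in the
    second half at which either wrist attains its maximum height.  Frames
    outside [rs, re) — walking in, jumping off, down-climbing — are
    excluded from all downstream analysis.
    """
    n = len(seq)
    if n < 2:
        raise TooShortError("route delimitation needs at least 2 frames")
    hip_y = seq.joint(JointId.ROOT)[:, 1]
    half = n // 2
    rs = int(np.argmin(hip_y[:half])) if half > 0 else 0
    wrists_y = np.stack(
        [seq.joint(JointId.LEFT_WRIST)[:, 1], seq.joint(JointId.RIGHT_WRIST)[:, 1]]
    )
    second = wrists_y[:, half:]
    maxima = second.max(axis=1)
    at_max = (second[0] == maxima[0]) | (second[1] == maxima[1])
    re = half + int(np.flatnonzero(at_max)[-1])
    if rs >= re:
        raise DelimitationError(f"no ascent found: rs={rs} >= re={re}")
    if hip_y[re] - hip_y[rs] <= 0.0:
        raise DelimitationError("no ascent found: hip does not rise over the route")
    return RouteLimits(start=rs, end=re)


# ---------------------------------------------------------------------------
# Convenience: all motion series a route analysis needs
# ---------------------------------------------------------------------------

#: Keys of the motion bundle consumed by the phase machine and detectors.
MOTION_KEYS = ("J7", "J4", "J8", "J14", "J11", "J8y")


def compute_motion(
    seq: SkeletonSequence,
    limits: RouteLimits,
    *,
    n: float = 2.0,
    window: int = 3,
    rho: float = 0.5,
    min_len: int = 30,
    smooth_window: int = 15,
    spike_window: int = 7,
) -> dict[str, MotionIntervals]:
    """Motion intervals for the key joints over the delimited route.

    Segments the wall-plane speed of both wrists, the hip centre and both
    ankles, plus the vertical-only hip series ``J8y`` required by the
    reaching-phase rule.  All intervals are reported in recording frame
    coordinates (offset by the route start).
    """
    sub = seq.subsequence(limits.start, limits.end)
    specs: list[tuple[str, JointId, Axis]] = [
        ("J7", JointId.LEFT_WRIST, "xy"),
        ("J4", JointId.RIGHT_WRIST, "xy"),
        ("J8", JointId.ROOT, "xy"),
        ("J14", JointId.LEFT_ANKLE, "xy"),
        ("J11", JointId.RIGHT_ANKLE, "xy"),
        ("J8y", JointId.ROOT, "y"),
    ]
    out: dict[str, MotionIntervals] = {}
    for key, jid, axis in specs:
        speed = joint_speed(
            sub, jid, axis=axis, smooth_window=smooth_window, spike_window=spike_window
        )
        out[key] = segment_motion(
            speed, n=n, window=window, rho=rho, min_len=min_len, offset=limits.start
        )
    return out
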