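"""Domain types, skeleton stream I/O and joint geometry primitives.

A climbing recording is modelled as a fixed-rate stream of 13-joint 3-D
poses.  Joints carry the conventional ``J2`` … ``J14`` identifiers used in
climbing motion analysis: wrists ``J7``/``J4``, elbows ``J6``/``J3``,
shoulders ``J5``/``J2`` (left/right), hips ``J12``/``J9``, knees
``J13``/``J10``, ankles ``J14``/``J11`` and the hip-centre root ``J8``.
Positions are millimetres, either in the camera frame of the recording
device or in the wall frame produced by extrinsic calibration.

The module also provides the 2-D→3-D lifting step used when poses come from
a 2-D keypoint detector plus a sparse depth grid, and the interior-angle
primitive on which the posture checks are built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateGeometryError,
    InsufficientDepthError,
    OutOfBoundsError,
    ParseError,
    SchemaError,
)

__all__ = [
    "JointId",
    "KEY_JOINTS",
    "FrameInterval",
    "SkeletonFrame",
    "SkeletonSequence",
    "DepthGrid",
    "read_sequence",
    "write_sequence",
    "lift_joint_depth",
    "joint_angle",
]


class JointId(IntEnum):
    """The 13 body joints used in climbing analysis, numbered J2–J14."""

    RIGHT_SHOULDER = 2
    RIGHT_ELBOW = 3
    RIGHT_WRIST = 4
    LEFT_SHOULDER = 5
    LEFT_ELBOW = 6
    LEFT_WRIST = 7
    ROOT = 8  # hip centre; proxy for the centre of mass
    RIGHT_HIP = 9
    RIGHT_KNEE = 10
    RIGHT_ANKLE = 11
    LEFT_HIP = 12
    LEFT_KNEE = 13
    LEFT_ANKLE = 14

    @property
    def label(self) -> str:
        """The ``J<k>`` label used in file formats, e.g. ``"J8"``."""
        return f"J{self.value}"

    @property
    def index(self) -> int:
        """Zero-based position of this joint in the storage order J2..J14."""
        return self.value - 2

    @classmethod
    def from_label(cls, label: str) -> "JointId":
        if not label.startswith("J"):
            raise SchemaError(f"unknown joint label {label!r}")
        try:
            return cls(int(label[1:]))
        except ValueError as exc:
            raise SchemaError(f"unknown joint label {label!r}") from exc


JOINT_ORDER: tuple[JointId, ...] = tuple(sorted(JointId, key=int))
JOINT_LABELS: tuple[str, ...] = tuple(j.label for j in JOINT_ORDER)

#: Joints whose movement drives phase transitions: both wrists, the hip
#: centre and both ankles.
KEY_JOINTS: frozenset[JointId] = frozenset(
    {
        JointId.LEFT_WRIST,
        JointId.RIGHT_WRIST,
        JointId.ROOT,
        JointId.LEFT_ANKLE,
        JointId.RIGHT_ANKLE,
    }
)


@dataclass(frozen=True, order=True)
class FrameInterval:
    """Half-open frame interval ``[start, end)``, 0-based.

    The half-open convention makes lengths additive and lets adjacent
    phases tile a route without sharing frames.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def __contains__(self, frame: int) -> bool:
        return self.start <= frame < self.end

    def intersection_length(self, other: "FrameInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shift(self, offset: int) -> "FrameInterval":
        return FrameInterval(self.start + offset, self.end + offset)

    def to_json(self) -> dict:
        return {"start": int(self.start), "end": int(self.end)}


@dataclass
class SkeletonFrame:
    """A single 13-joint pose.  ``positions`` has shape (13, 3), millimetres."""

    index: int
    positions: np.ndarray
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (13, 3):
            raise SchemaError(
                f"frame {self.index}: expected (13, 3) positions, got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise SchemaError(f"frame {self.index}: non-finite joint position")

    def joint(self, jid: JointId) -> np.ndarray:
        return self.positions[jid.index]


@dataclass
class SkeletonSequence:
    """Fixed-rate stream of 13-joint 3-D poses.

    ``positions`` has shape (n_frames, 13, 3) in millimetres; joints are
    stored in J2..J14 order.  ``frame_space`` tags whether coordinates are
    raw camera coordinates or wall coordinates (origin at the wall's upper
    reference corner, y up the wall, z off the wall toward the climber).
    Confidence scores are carried when present but not consumed by the
    analysis stages.
    """

    positions: np.ndarray
    fps: float = 60.0
    frame_space: str = "camera"
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (13, 3):
            raise SchemaError(
                f"expected positions of shape (n, 13, 3), got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise SchemaError("non-finite joint position in sequence")
        if self.fps <= 0:
            raise SchemaError(f"fps must be positive, got {self.fps}")
        if self.frame_space not in ("camera", "wall"):
            raise SchemaError(f"frame_space must be 'camera' or 'wall', got {self.frame_space!r}")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.positions.shape[:2]:
                raise SchemaError("confidence must have shape (n_frames, 13)")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __iter__(self) -> Iterator[SkeletonFrame]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, index: int) -> SkeletonFrame:
        conf = None if self.confidence is None else self.confidence[index]
        return SkeletonFrame(index=index, positions=self.positions[index], confidence=conf)

    def joint(self, jid: JointId) -> np.ndarray:
        """Trajectory of one joint as an (n_frames, 3) array."""
        return self.positions[:, jid.index, :]

    def subsequence(self, start: int, end: int) -> "SkeletonSequence":
        """View of frames ``[start, end)`` with the same rate and space."""
        if not (0 <= start < end <= len(self)):
            raise ValueError(f"invalid subsequence [{start}, {end}) of {len(self)} frames")
        conf = None if self.confidence is None else self.confidence[start:end]
        return SkeletonSequence(
            positions=self.positions[start:end],
            fps=self.fps,
            frame_space=self.frame_space,
            confidence=conf,
        )


# ---------------------------------------------------------------------------
# Skeleton stream I/O
#
# JSON schema:
#   {"fps": 60.0, "space": "camera"|"wall",
#    "frames": [{"i": 0, "J2": [x, y, z], ..., "J14": [x, y, z]}, ...]}
# CSV dialect: one row per frame, columns J{k}_{x|y|z}; fps and space are
# not representable in the CSV body and are supplied by the caller.
# ---------------------------------------------------------------------------


def read_sequence(
    path: str | Path,
    format: str | None = None,
    *,
    fps: float = 60.0,
    frame_space: str = "camera",
) -> SkeletonSequence:
    """Read a skeleton sequence from a JSON or CSV file.

    ``format`` defaults to the file suffix.  For CSV files, which carry no
    header metadata, ``fps`` and ``frame_space`` supply the missing fields;
    for JSON they are read from the file.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv":
        return _read_csv(path, fps=fps, frame_space=frame_space)
    raise ParseError(f"unsupported skeleton format {fmt!r} (expected json or csv)")


def _read_json(path: Path) -> SkeletonSequence:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    for key in ("fps", "space", "frames"):
        if key not in doc:
            raise SchemaError(f"{path}: missing top-level key {key!r}")
    frames = doc["frames"]
    if not frames:
        raise SchemaError(f"{path}: empty frame list")
    n = len(frames)
    positions = np.empty((n, 13, 3), dtype=float)
    for rec_no, rec in enumerate(frames):
        if "i" not in rec:
            raise SchemaError(f"{path}: frame record {rec_no} missing index 'i'")
        if int(rec["i"]) != rec_no:
            raise SchemaError(
                f"{path}: frame indices must be contiguous from 0; "
                f"record {rec_no} has i={rec['i']}"
            )
        unknown = set(rec) - set(JOINT_LABELS) - {"i", "confidence"}
        if unknown:
            raise SchemaError(f"{path}: frame {rec_no}: unknown joints {sorted(unknown)}")
        missing = [lab for lab in JOINT_LABELS if lab not in rec]
        if missing:
            raise SchemaError(f"{path}: frame {rec_no}: missing joints {missing}")
        for j, lab in enumerate(JOINT_LABELS):
            xyz = rec[lab]
            if len(xyz) != 3:
                raise ParseError(f"{path}: frame {rec_no}, joint {lab}: expected [x, y, z]")
            positions[rec_no, j] = xyz
    return SkeletonSequence(positions=positions, fps=float(doc["fps"]), frame_space=doc["space"])


def _read_csv(path: Path, fps: float, frame_space: str) -> SkeletonSequence:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    cols = [f"{lab}_{ax}" for lab in JOINT_LABELS for ax in "xyz"]
    missing_joints = sorted(
        {lab for lab in JOINT_LABELS if any(f"{lab}_{ax}" not in df.columns for ax in "xyz")},
        key=lambda lab: int(lab[1:]),
    )
    if missing_joints:
        raise SchemaError(f"{path}: missing joint columns for {missing_joints}")
    positions = df[cols].to_numpy(dtype=float).reshape(len(df), 13, 3)
    return SkeletonSequence(positions=positions, fps=fps, frame_space=frame_space)


def write_sequence(seq: SkeletonSequence, path: str | Path, format: str | None = None) -> None:
    """Write a sequence so that :func:`read_sequence` inverts it losslessly."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        frames = []
        for i in range(len(seq)):
            rec: dict = {"i": i}
            for j, lab in enumerate(JOINT_LABELS):
                rec[lab] = [float(v) for v in seq.positions[i, j]]
            frames.append(rec)
        doc = {"fps": seq.fps, "space": seq.frame_space, "frames": frames}
        path.write_text(json.dumps(doc))
    elif fmt == "csv":
        cols = [f"{lab}_{ax}" for lab in JOINT_LABELS for ax in "xyz"]
        df = pd.DataFrame(seq.positions.reshape(len(seq), 39), columns=cols)
        df.to_csv(path, index=False, float_format="%.9g")
    else:
        raise ParseError(f"unsupported skeleton format {fmt!r} (expected json or csv)")


# ---------------------------------------------------------------------------
# Depth grid and 2-D → 3-D lifting
# ---------------------------------------------------------------------------


@dataclass
class DepthGrid:
    """Rectangular lattice of sparse depth samples over the image plane.

    ``pixel_x`` (cols,) and ``pixel_y`` (rows,) give the node pixel
    coordinates; ``depth`` (rows, cols) the depth in millimetres.  Nodes
    with non-positive or non-finite depth are treated as invalid, which
    happens where the sensor returned no measurement.
    """

    pixel_x: np.ndarray
    pixel_y: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.pixel_x = np.asarray(self.pixel_x, dtype=float)
        self.pixel_y = np.asarray(self.pixel_y, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.pixel_x.ndim != 1 or self.pixel_y.ndim != 1:
            raise SchemaError("pixel_x and pixel_y must be 1-D node coordinate arrays")
        if self.depth.shape != (self.pixel_y.size, self.pixel_x.size):
            raise SchemaError(
                f"depth shape {self.depth.shape} does not match lattice "
                f"({self.pixel_y.size}, {self.pixel_x.size})"
            )

    @property
    def dims(self) -> tuple[int, int]:
        return self.depth.shape

    @classmethod
    def regular(cls, rows: int, cols: int, spacing: float, depth: np.ndarray) -> "DepthGrid":
        return cls(
            pixel_x=np.arange(cols) * spacing,
            pixel_y=np.arange(rows) * spacing,
            depth=depth,
        )

    def to_json(self) -> dict:
        return {
            "pixel_x": self.pixel_x.tolist(),
            "pixel_y": self.pixel_y.tolist(),
            "depth": self.depth.tolist(),
        }

    @classmethod
    def from_json(cls, doc: dict) -> "DepthGrid":
        return cls(
            pixel_x=np.asarray(doc["pixel_x"]),
            pixel_y=np.asarray(doc["pixel_y"]),
            depth=np.asarray(doc["depth"]),
        )


def lift_joint_depth(joint2d: Sequence[float], grid: DepthGrid) -> float:
    """Depth of a 2-D keypoint from the sparse grid, in millimetres.

    The keypoint falls inside one lattice cell; its depth is taken as the
    mean depth of the three nodes nearest in pixel distance among the 3×3
    node neighbourhood surrounding the point.  Averaging three nodes keeps
    the estimate robust against a single missing or noisy depth sample.
    """
    x, y = float(joint2d[0]), float(joint2d[1])
    gx, gy = grid.pixel_x, grid.pixel_y
    if not (gx[0] <= x <= gx[-1] and gy[0] <= y <= gy[-1]):
        raise OutOfBoundsError(
            f"keypoint ({x}, {y}) outside grid extent "
            f"x∈[{gx[0]}, {gx[-1]}], y∈[{gy[0]}, {gy[-1]}]"
        )
    # 3x3 neighbourhood centred on the nearest node, clipped at the border.
    ci = int(np.argmin(np.abs(gx - x)))
    ri = int(np.argmin(np.abs(gy - y)))
    c_lo, c_hi = max(ci - 1, 0), min(ci + 2, gx.size)
    r_lo, r_hi = max(ri - 1, 0), min(ri + 2, gy.size)
    nx, ny = np.meshgrid(gx[c_lo:c_hi], gy[r_lo:r_hi])
    nd = grid.depth[r_lo:r_hi, c_lo:c_hi]
    valid = np.isfinite(nd) & (nd > 0)
    if np.count_nonzero(valid) < 3:
        raise InsufficientDepthError(
            f"only {np.count_nonzero(valid)} valid depth nodes around ({x}, {y})"
        )
    d2 = (nx[valid] - x) ** 2 + (ny[valid] - y) ** 2
    nearest3 = np.argsort(d2, kind="stable")[:3]
    return float(np.mean(nd[valid][nearest3]))


# ---------------------------------------------------------------------------
# Joint geometry
# ---------------------------------------------------------------------------


def joint_angle(a: Sequence[float], b: Sequence[float], c: Sequence[float]) -> float:
    """Interior angle at ``b`` between rays ``b→a`` and ``b→c``, in degrees.

    This is the primitive behind the elbow angle (wrist–elbow–shoulder) and
    the shoulder angle (elbow–shoulder–hip).  The result lies in [0°, 180°];
    a straight limb reads 180°.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length ray in joint_angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
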