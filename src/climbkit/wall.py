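"""Wall-plane calibration and the camera→wall rigid transform.

The climbing wall is modelled as a rectangular plane with an optional tilt.
From a point cloud of the empty scene the plane is fitted with seeded
RANSAC, the wall rectangle is recovered as the minimum-area enclosing
rectangle of the in-plane inlier hull, and a rigid transform is assembled
that re-expresses skeletons in *wall coordinates*:

* origin at the wall's upper reference corner (upper-left as seen looking
  at the wall, so interior points have negative y),
* x along the top edge, y up the wall, z along the wall normal pointing
  away from the wall toward the climber/camera.

Anchoring every recording to the same physical frame is what makes climbs
captured with different camera poses comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import (
    ExtractionError,
    FitError,
    SingularConfigurationError,
)
from .skeleton import SkeletonSequence

__all__ = [
    "WallModel",
    "fit_wall_plane",
    "extract_wall_rectangle",
    "rotation_from_normal",
    "build_wall_model",
    "to_wall_coords",
    "load_point_cloud",
    "save_point_cloud",
]

_ORTHO_TOL = 1e-9


@dataclass
class WallModel:
    """Fitted wall plane, rectangle corners, and camera→wall rigid transform.

    ``rotation`` (R) and ``translation`` (t) map camera points into wall
    coordinates as ``p_wall = R @ p_cam + t``; ``origin`` is the wall
    reference corner in camera coordinates and maps to (0, 0, 0).
    """

    normal: np.ndarray  # unit, camera frame, oriented toward the camera
    origin: np.ndarray  # reference corner, camera frame
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    width: float  # mm, along the top edge
    height: float  # mm, up the wall
    corners: np.ndarray  # (4, 3) camera frame: origin, top-right, bottom-right, bottom-left

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.corners = np.asarray(self.corners, dtype=float)
        R = self.rotation
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-6:
            raise FitError("wall normal must be unit length")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise FitError("wall rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise FitError("wall rotation must be proper (det = +1)")

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Apply the camera→wall transform to an (..., 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse_transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.translation) @ self.rotation

    def to_json(self) -> dict:
        return {
            "normal": self.normal.tolist(),
            "origin": self.origin.tolist(),
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "width": float(self.width),
            "height": float(self.height),
            "corners": self.corners.tolist(),
        }

    @classmethod
    def from_json(cls, doc: dict) -> "WallModel":
        return cls(
            normal=np.asarray(doc["normal"]),
            origin=np.asarray(doc["origin"]),
            rotation=np.asarray(doc["rotation"]),
            translation=np.asarray(doc["translation"]),
            width=float(doc["width"]),
            height=float(doc["height"]),
            corners=np.asarray(doc["corners"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "WallModel":
        return cls.from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Plane fitting
# ---------------------------------------------------------------------------


def _lsq_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares plane through ``points``: unit normal n and offset d
    with n·x = d.  Uses the smallest principal direction of the centred
    cloud, the standard total-least-squares fit."""
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    if s.size < 3 or s[1] < 1e-12:
        raise FitError("degenerate point cloud: points are collinear")
    normal = vt[2]
    return normal, float(normal @ centroid)


def fit_wall_plane(
    cloud: np.ndarray,
    iterations: int = 500,
    inlier_tol: float = 20.0,
    seed: int | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """RANSAC plane fit of the wall from a scene point cloud.

    Draws ``iterations`` random 3-point hypotheses, keeps the plane with
    the most points within ``inlier_tol`` mm, and refines it by a
    total-least-squares fit on the inliers.  The returned unit normal is
    oriented toward the camera origin (the camera always faces the wall),
    and the offset ``d`` satisfies ``normal · x = d`` for plane points.

    Returns ``(normal, offset, inlier_mask)``.  Deterministic given
    ``seed``.
    """
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise FitError(f"need at least 3 points with 3 coordinates, got {pts.shape}")
    rng = np.random.default_rng(seed)
    n_pts = pts.shape[0]
    best_count = -1
    best_normal: np.ndarray | None = None
    best_d = 0.0
    for _ in range(iterations):
        idx = rng.choice(n_pts, size=3, replace=False)
        p0, p1, p2 = pts[idx]
        normal = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(normal)
        if norm < 1e-9:
            continue  # collinear sample
        normal = normal / norm
        d = normal @ p0
        count = int(np.count_nonzero(np.abs(pts @ normal - d) <= inlier_tol))
        if count > best_count:
            best_count, best_normal, best_d = count, normal, d
    if best_normal is None:
        raise FitError("degenerate point cloud: no valid plane hypothesis found")
    mask = np.abs(pts @ best_normal - best_d) <= inlier_tol
    # Refine on the consensus set, then recompute the inlier set once.
    normal, d = _lsq_plane(pts[mask])
    mask = np.abs(pts @ normal - d) <= inlier_tol
    normal, d = _lsq_plane(pts[mask])
    # Orient toward the camera origin: the camera sits on the +normal side.
    if (normal @ pts[mask].mean(axis=0)) > 0:
        normal, d = -normal, -d
    return normal, float(d), mask


# ---------------------------------------------------------------------------
# Rectangle extraction
# ---------------------------------------------------------------------------


def _min_area_rectangle(xy: np.ndarray) -> np.ndarray:
    """Minimum-area enclosing rectangle of 2-D points via rotating calipers
    over the convex-hull edges.  Returns the 4 rectangle corners (4, 2)."""
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise ExtractionError(f"cannot build hull of wall inliers: {exc}") from exc
    hp = xy[hull.vertices]
    if hp.shape[0] < 4:
        raise ExtractionError(f"only {hp.shape[0]} boundary points; rectangle needs 4")
    best_area = np.inf
    best: np.ndarray | None = None
    edges = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    for edge in edges:
        norm = np.linalg.norm(edge)
        if norm < 1e-12:
            continue
        ux = edge / norm
        uy = np.array([-ux[1], ux[0]])
        proj = hp @ np.column_stack([ux, uy])
        lo = proj.min(axis=0)
        hi = proj.max(axis=0)
        area = (hi[0] - lo[0]) * (hi[1] - lo[1])
        if area < best_area:
            best_area = area
            rect = np.array(
                [[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]]
            )
            best = rect @ np.vstack([ux, uy])
    if best is None:
        raise ExtractionError("degenerate hull: all edges zero-length")
    return best


def extract_wall_rectangle(
    inliers: np.ndarray, up_hint: np.ndarray | None = None
) -> np.ndarray:
    """Corner points of the wall rectangle from approximately planar inliers.

    Projects the inliers into their best-fit plane, takes the minimum-area
    enclosing rectangle of the convex hull, and lifts the corners back to
    3-D.  Corners are ordered ``[origin, top-right, bottom-right,
    bottom-left]`` where the origin corner is the upper-left one in a
    gravity-aligned in-plane frame (``up_hint``, default camera +y).
    """
    pts = np.asarray(inliers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ExtractionError(f"need at least 4 planar points, got {pts.shape}")
    up = np.array([0.0, 1.0, 0.0]) if up_hint is None else np.asarray(up_hint, dtype=float)
    try:
        normal, d = _lsq_plane(pts)
    except FitError as exc:
        raise ExtractionError(str(exc)) from exc
    centroid = pts.mean(axis=0)
    # The SVD normal has an arbitrary sign; orient it toward the camera
    # origin (the camera always faces the wall) so the in-plane rightward
    # direction is well defined.
    if normal @ centroid > 0:
        normal = -normal
    # In-plane orthonormal basis, roughly gravity-aligned.
    e_up = up - (up @ normal) * normal
    if np.linalg.norm(e_up) < 1e-9:
        raise ExtractionError("up_hint is parallel to the wall normal")
    e_up = e_up / np.linalg.norm(e_up)
    e_rt = np.cross(e_up, normal)
    basis = np.column_stack([e_rt, e_up])  # (3, 2)
    xy = (pts - centroid) @ basis
    rect2d = _min_area_rectangle(xy)
    corners = centroid + rect2d @ basis.T

    # Order the corners.  The origin corner maximises (up − right), which
    # selects the upper-left corner robustly even when the two top corners
    # tie in height up to noise; the walk then starts along the more
    # horizontal of the two incident edges — the top edge, rightward.
    c2d = (corners - centroid) @ basis
    origin_idx = int(np.argmax(c2d[:, 1] - c2d[:, 0]))
    d_fwd = c2d[(origin_idx + 1) % 4] - c2d[origin_idx]
    d_bwd = c2d[(origin_idx - 1) % 4] - c2d[origin_idx]
    if abs(d_fwd[0]) >= abs(d_bwd[0]):
        idx = [(origin_idx + k) % 4 for k in range(4)]
    else:
        idx = [(origin_idx - k) % 4 for k in range(4)]
    return corners[idx]


# ---------------------------------------------------------------------------
# Rotation from normal, full model assembly, and the transform
# ---------------------------------------------------------------------------


def rotation_from_normal(n: np.ndarray) -> np.ndarray:
    """Rotation taking the camera z-axis onto the unit normal ``n``.

    Implements the rank-one form of Rodrigues' formula for the half-angle
    axis ``z + n``::

        R = 2 (z+n)(z+n)ᵀ / ((z+n)ᵀ(z+n)) − I

    which is a rotation by π about the bisector of z and n, hence
    ``R @ z = n`` with ``RᵀR = I`` and ``det R = +1``.  Singular when n is
    antiparallel to z (the bisector vanishes); the caller must then supply
    a pre-rotation.
    """
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise FitError("rotation_from_normal requires a unit vector")
    z = np.array([0.0, 0.0, 1.0])
    w = z + n
    denom = w @ w
    if denom < 1e-12:
        raise SingularConfigurationError(
            "normal antiparallel to z: supply a pre-rotation before calling"
        )
    return 2.0 * np.outer(w, w) / denom - np.eye(3)


def build_wall_model(
    cloud: np.ndarray,
    iterations: int = 500,
    inlier_tol: float = 20.0,
    seed: int | None = None,
    up_hint: np.ndarray | None = None,
) -> WallModel:
    """Full extrinsic calibration: plane → rectangle → rigid transform.

    The wall z-axis is the RANSAC normal (toward the camera).  The in-plane
    rotation is fixed from the rectangle: the wall y-axis is the rectangle
    edge direction closest to ``up_hint`` and the x-axis completes the
    right-handed frame along the top edge, so ``x × y = z``.
    """
    normal, d, mask = fit_wall_plane(cloud, iterations=iterations, inlier_tol=inlier_tol, seed=seed)
    pts = np.asarray(cloud, dtype=float)[mask]
    corners = extract_wall_rectangle(pts, up_hint=up_hint)
    origin = corners[0]
    top = corners[1] - corners[0]  # along the top edge
    left = corners[3] - corners[0]  # down the left edge
    width = float(np.linalg.norm(top))
    height = float(np.linalg.norm(left))
    y_axis = -left / height  # up the wall
    # Re-orthogonalise against the fitted normal (rectangle lies in-plane
    # only up to noise) and complete the right-handed frame.
    y_axis = y_axis - (y_axis @ normal) * normal
    y_axis = y_axis / np.linalg.norm(y_axis)
    x_axis = np.cross(y_axis, normal)
    R = np.vstack([x_axis, y_axis, normal])
    t = -R @ origin
    return WallModel(
        normal=normal,
        origin=origin,
        rotation=R,
        translation=t,
        width=width,
        height=height,
        corners=corners,
    )


def to_wall_coords(seq: SkeletonSequence, wall: WallModel) -> SkeletonSequence:
    """Re-express a camera-space skeleton sequence in wall coordinates.

    Rigid, so all inter-joint distances are preserved; wall-plane points
    map to z ≈ 0 and the origin corner to (0, 0, 0).  Applying it to a
    sequence already in wall space is a warned no-op.
    """
    if seq.frame_space == "wall":
        import warnings

        warnings.warn("sequence already in wall coordinates; returning unchanged", stacklevel=2)
        return seq
    positions = wall.transform_points(seq.positions)
    return SkeletonSequence(
        positions=positions,
        fps=seq.fps,
        frame_space="wall",
        confidence=seq.confidence,
    )


# ---------------------------------------------------------------------------
# Point-cloud I/O (PLY via trimesh)
# ---------------------------------------------------------------------------


def load_point_cloud(path: str | Path) -> np.ndarray:
    """Load an (n, 3) point cloud from a PLY file (ascii or binary)."""
    import trimesh

    obj = trimesh.load(str(path), process=False)
    vertices = np.asarray(obj.vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 3 or vertices.shape[0] == 0:
        raise FitError(f"{path}: no 3-D vertices found")
    return vertices


def save_point_cloud(points: np.ndarray, path: str | Path) -> None:
    import trimesh

    cloud = trimesh.PointCloud(np.asarray(points, dtype=float))
    Path(path).write_bytes(cloud.export(file_type="ply"))
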