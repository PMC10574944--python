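"""Skeleton types, I/O round-trips, depth lifting and the angle primitive."""

import json

import numpy as np
import pytest

from climbkit import (
    DepthGrid,
    FrameInterval,
    JointId,
    SkeletonSequence,
    joint_angle,
    lift_joint_depth,
    read_sequence,
    write_sequence,
)
from climbkit.exceptions import (
    DegenerateGeometryError,
    InsufficientDepthError,
    OutOfBoundsError,
    SchemaError,
)
from climbkit.skeleton import JOINT_LABELS

from .conftest import make_sequence


class TestJointIds:
    def test_thirteen_joints_with_fixed_roles(self):
        assert len(JointId) == 13
        assert JointId.LEFT_WRIST.label == "J7"
        assert JointId.ROOT.label == "J8"
        assert JointId.from_label("J14") is JointId.LEFT_ANKLE

    def test_key_joint_subset(self):
        from climbkit import KEY_JOINTS

        assert {j.label for j in KEY_JOINTS} == {"J7", "J4", "J8", "J14", "J11"}


class TestFrameInterval:
    def test_half_open_length_and_membership(self):
        iv = FrameInterval(3, 7)
        assert iv.length == 4
        assert 3 in iv and 6 in iv and 7 not in iv

    @pytest.mark.parametrize("start,end", [(5, 5), (7, 3), (-1, 4)])
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            FrameInterval(start, end)


class TestSequenceIO:
    def test_json_round_trip_preserves_positions(self, tmp_path):
        seq = make_sequence(5)
        seq.positions += np.random.default_rng(0).normal(0, 100, seq.positions.shape)
        seq = SkeletonSequence(seq.positions, fps=30.0, frame_space="wall")
        path = tmp_path / "seq.json"
        write_sequence(seq, path)
        back = read_sequence(path)
        assert back.fps == 30.0 and back.frame_space == "wall"
        np.testing.assert_allclose(back.positions, seq.positions, atol=1e-6)

    def test_csv_round_trip_preserves_positions(self, tmp_path):
        seq = make_sequence(4)
        path = tmp_path / "seq.csv"
        write_sequence(seq, path)
        back = read_sequence(path, fps=60.0, frame_space="wall")
        np.testing.assert_allclose(back.positions, seq.positions, atol=1e-6)

    def test_missing_joint_names_offender(self, tmp_path):
        doc = {
            "fps": 60.0,
            "space": "wall",
            "frames": [
                {"i": 0, **{lab: [0.0, 0.0, 0.0] for lab in JOINT_LABELS if lab != "J8"}}
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="J8"):
            read_sequence(path)

    def test_unknown_joint_rejected(self, tmp_path):
        doc = {
            "fps": 60.0,
            "space": "wall",
            "frames": [
                {"i": 0, "J99": [0, 0, 0], **{lab: [0.0, 0.0, 0.0] for lab in JOINT_LABELS}}
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="J99"):
            read_sequence(path)

    def test_non_contiguous_frames_rejected(self, tmp_path):
        frame = {lab: [0.0, 0.0, 0.0] for lab in JOINT_LABELS}
        doc = {"fps": 60.0, "space": "wall", "frames": [{"i": 0, **frame}, {"i": 2, **frame}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="contiguous"):
            read_sequence(path)


class TestLiftJointDepth:
    def test_uniform_grid_returns_constant_depth(self):
        grid = DepthGrid.regular(5, 5, 10.0, np.full((5, 5), 2000.0))
        assert lift_joint_depth((20.0, 20.0), grid) == pytest.approx(2000.0)

    def test_mean_of_three_nearest_nodes(self):
        # Node depths laid out so the three nodes nearest the query are
        # 1000, 1100, 1200 -> mean 1100 (verified by the exhaustive check).
        depth = np.array([[1000.0, 1100.0, 9000.0], [1200.0, 8000.0, 9000.0], [7000.0, 8000.0, 9000.0]])
        grid = DepthGrid.regular(3, 3, 10.0, depth)
        assert lift_joint_depth((3.0, 3.0), grid) == pytest.approx(1100.0)

    def test_out_of_bounds_rejected(self):
        grid = DepthGrid.regular(3, 3, 10.0, np.full((3, 3), 2000.0))
        with pytest.raises(OutOfBoundsError):
            lift_joint_depth((-1.0, -1.0), grid)

    def test_insufficient_valid_nodes_rejected(self):
        depth = np.full((3, 3), np.nan)
        depth[0, 0] = depth[0, 1] = 2000.0
        grid = DepthGrid.regular(3, 3, 10.0, depth)
        with pytest.raises(InsufficientDepthError):
            lift_joint_depth((5.0, 5.0), grid)

    def test_matches_exhaustive_nearest3_search(self):
        """When the 3 global nearest nodes lie inside the 3x3 neighbourhood,
        the windowed selection equals a whole-grid search."""
        rng = np.random.default_rng(42)
        grid = DepthGrid.regular(8, 8, 10.0, rng.uniform(500, 4000, (8, 8)))
        gx, gy = np.meshgrid(grid.pixel_x, grid.pixel_y)
        for _ in range(50):
            q = rng.uniform(0, 70, size=2)
            d2 = (gx - q[0]) ** 2 + (gy - q[1]) ** 2
            order = np.argsort(d2.ravel(), kind="stable")[:3]
            rows, cols = np.unravel_index(order, d2.shape)
            ci = int(np.argmin(np.abs(grid.pixel_x - q[0])))
            ri = int(np.argmin(np.abs(grid.pixel_y - q[1])))
            if np.all(np.abs(rows - ri) <= 1) and np.all(np.abs(cols - ci) <= 1):
                expected = grid.depth[rows, cols].mean()
                assert lift_joint_depth(q, grid) == pytest.approx(expected)


class TestJointAngle:
    @pytest.mark.parametrize(
        "a,b,c,expected",
        [
            ((1, 0, 0), (0, 0, 0), (-1, 0, 0), 180.0),  # straight limb
            ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (0, 0, 0), (1, 1, 0), 45.0),
        ],
    )
    def test_reference_angles(self, a, b, c, expected):
        assert joint_angle(a, b, c) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_ray_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            joint_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_invariant_under_rigid_transforms(self):
        """The interior angle must not change under rotation + translation."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        for _ in range(100):
            pts = rng.normal(0, 100, (3, 3))
            if min(np.linalg.norm(pts[0] - pts[1]), np.linalg.norm(pts[2] - pts[1])) < 1e-3:
                continue
            base = joint_angle(*pts)
            quat = rng.normal(size=4)
            R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            t = rng.normal(0, 1000, 3)
            moved = pts @ R.T + t
            assert joint_angle(*moved) == pytest.approx(base, abs=1e-9)
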