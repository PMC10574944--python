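"""Wall calibration: plane RANSAC, rectangle extraction, rigid transform."""

import numpy as np
import pytest

from climbkit import (
    WallSpec,
    build_wall_model,
    extract_wall_rectangle,
    fit_wall_plane,
    generate_wall_cloud,
    rotation_from_normal,
    to_wall_coords,
)
from climbkit.exceptions import ExtractionError, FitError, SingularConfigurationError

from .conftest import make_sequence


def _grid_rectangle(width=3000.0, height=4000.0, z=2000.0, step=50.0):
    xs = np.arange(0.0, width + step / 2, step)
    ys = np.arange(0.0, height + step / 2, step)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])


class TestRotationFromNormal:
    def test_identity_direction_gives_flip_about_z(self):
        # The half-angle form yields 2zz^T - I for n = z: a pi-rotation
        # about z that still maps z onto itself.
        R = rotation_from_normal(np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(R, np.diag([-1.0, -1.0, 1.0]), atol=1e-12)

    def test_x_axis_normal_hand_evaluated(self):
        R = rotation_from_normal(np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(
            R, np.array([[0.0, 0.0, 1.0], [0.0, -1.0, 0.0], [1.0, 0.0, 0.0]]), atol=1e-12
        )
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_maps_z_to_n_for_random_normals(self):
        rng = np.random.default_rng(11)
        z = np.array([0.0, 0.0, 1.0])
        for _ in range(200):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            R = rotation_from_normal(n)
            assert np.linalg.norm(R @ z - n) < 1e-12
            assert np.max(np.abs(R.T @ R - np.eye(3))) < 1e-12

    def test_antiparallel_normal_is_singular(self):
        with pytest.raises(SingularConfigurationError):
            rotation_from_normal(np.array([0.0, 0.0, -1.0]))


class TestFitWallPlane:
    def test_noiseless_plane_recovered_exactly(self):
        pts = _grid_rectangle(step=150.0)  # z = 2000 plane
        normal, offset, mask = fit_wall_plane(pts, seed=0)
        assert mask.all()
        # Orientation rule: normal points toward the camera origin, so for a
        # wall in front of the camera the plane equation is n.x = -2000.
        np.testing.assert_allclose(np.abs(normal), [0, 0, 1], atol=1e-9)
        assert abs(offset) == pytest.approx(2000.0)
        assert normal @ pts[0] == pytest.approx(offset)

    def test_outliers_rejected(self):
        rng = np.random.default_rng(1)
        plane = _grid_rectangle(step=120.0)
        outliers = rng.uniform([0, 0, 100], [3000, 4000, 1900], size=(50, 3))
        normal, offset, mask = fit_wall_plane(np.vstack([plane, outliers]), seed=2)
        assert mask[: len(plane)].sum() == len(plane)
        assert np.abs(normal @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_wall_plane(np.zeros((2, 3)), seed=0)

    def test_collinear_cloud_rejected(self):
        pts = np.column_stack([np.arange(100.0), np.zeros(100), np.zeros(100)])
        with pytest.raises(FitError):
            fit_wall_plane(pts, seed=0)


class TestExtractWallRectangle:
    def test_axis_aligned_rectangle_corners(self):
        pts = _grid_rectangle(width=3000, height=4000, step=50.0)
        corners = extract_wall_rectangle(pts)
        # origin = upper-left in the camera-up frame, then clockwise as seen
        expected = np.array(
            [[0, 4000, 2000], [3000, 4000, 2000], [3000, 0, 2000], [0, 0, 2000]],
            dtype=float,
        )
        # The rightward direction is the wall's own right (camera-left), so
        # the top edge may run either way in camera x; compare as sets with
        # the origin fixed to a top corner.
        assert corners[0, 1] == pytest.approx(4000, abs=10)
        dists = np.abs(corners[:, None, :] - expected[None, :, :]).max(axis=2).min(axis=1)
        assert dists.max() < 10.0

    def test_in_plane_rotation_recovers_same_corners(self):
        pts = _grid_rectangle(width=2000, height=3000, step=50.0)
        theta = np.radians(30.0)
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1.0],
            ]
        )
        rotated = pts @ R.T
        corners = extract_wall_rectangle(rotated)
        true_rotated = (
            np.array([[0, 0], [2000, 0], [2000, 3000], [0, 3000]], dtype=float) @ R[:2, :2].T
        )
        true_rotated = np.column_stack([true_rotated, np.full(4, 2000.0)])
        dists = np.abs(corners[:, None, :] - true_rotated[None, :, :]).max(axis=2).min(axis=1)
        assert dists.max() < 10.0

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(50.0), np.arange(50.0), np.zeros(50)])
        with pytest.raises(ExtractionError):
            extract_wall_rectangle(pts)


class TestWallTransform:
    @pytest.fixture()
    def model(self):
        cloud, _ = generate_wall_cloud(WallSpec(tilt_deg=10.0), 4000, 0.0, 0.0, seed=3)
        return build_wall_model(cloud, seed=3)

    def test_origin_corner_maps_to_zero(self, model):
        np.testing.assert_allclose(model.transform_points(model.origin), np.zeros(3), atol=1e-6)

    def test_wall_plane_maps_to_small_z(self, model):
        probe = model.origin + 1000.0 * (model.corners[1] - model.corners[0]) / model.width
        assert abs(model.transform_points(probe)[2]) < 20.0

    def test_round_trip_is_identity(self, model):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 2000, (50, 3))
        back = model.inverse_transform_points(model.transform_points(pts))
        np.testing.assert_allclose(back, pts, atol=1e-6)

    def test_pairwise_joint_distances_preserved(self, model):
        seq = make_sequence(8, frame_space="camera")
        seq.positions += np.random.default_rng(9).normal(0, 300, seq.positions.shape)
        wall_seq = to_wall_coords(seq, model)
        assert wall_seq.frame_space == "wall"
        for f in range(len(seq)):
            d0 = np.linalg.norm(seq.positions[f][:, None] - seq.positions[f][None], axis=2)
            d1 = np.linalg.norm(
                wall_seq.positions[f][:, None] - wall_seq.positions[f][None], axis=2
            )
            np.testing.assert_allclose(d1, d0, atol=1e-6)

    def test_wall_space_input_is_warned_noop(self, model):
        seq = make_sequence(3, frame_space="wall")
        with pytest.warns(UserWarning, match="already in wall"):
            out = to_wall_coords(seq, model)
        assert out is seq


class TestFullCalibration:
    def test_tilted_wall_recovered_under_noise_and_outliers(self):
        spec = WallSpec(tilt_deg=12.0)
        cloud, truth = generate_wall_cloud(spec, 5000, 5.0, 0.10, seed=21)
        model = build_wall_model(cloud, seed=21)
        angle = np.degrees(np.arccos(np.clip(abs(model.normal @ truth.normal), -1, 1)))
        assert angle < 0.5
        assert np.abs(model.corners - truth.corners).max() < 10.0
        assert model.width == pytest.approx(spec.width, abs=10)
        assert model.height == pytest.approx(spec.height, abs=10)
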