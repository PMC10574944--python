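"""Speed signals, the n-σ motion envelope, and route delimitation."""

import numpy as np
import pytest

from climbkit import (
    JointId,
    SpeedSeries,
    delimit_route,
    joint_speed,
    segment_motion,
    zscore_series,
)
from climbkit.exceptions import ConstantSignalError, DelimitationError, TooShortError

from .conftest import make_sequence


def _speed(values, fps=60.0):
    return SpeedSeries(values=np.asarray(values, dtype=float), joint=JointId.ROOT, axis="xy", fps=fps)


class TestJointSpeed:
    def test_static_joint_has_zero_speed(self):
        seq = make_sequence(50)
        assert np.all(joint_speed(seq, JointId.ROOT).values == 0.0)

    def test_constant_velocity_magnitude(self):
        track = np.column_stack([10.0 * np.arange(60), np.zeros(60), np.zeros(60)])
        seq = make_sequence(60, J8=track)
        speed = joint_speed(seq, JointId.ROOT, smooth_window=1, spike_window=1)
        # 10 mm/frame at 60 fps = 600 mm/s away from the replicated edges
        np.testing.assert_allclose(speed.values[1:-1], 600.0, atol=1e-9)

    def test_xy_projection_discards_z_motion(self):
        track = np.column_stack([np.zeros(60), np.zeros(60), 10.0 * np.arange(60)])
        seq = make_sequence(60, J8=track)
        assert np.all(joint_speed(seq, JointId.ROOT, axis="xy").values == 0.0)
        assert joint_speed(seq, JointId.ROOT, axis="z").values[30] == pytest.approx(600.0)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(TooShortError):
            joint_speed(make_sequence(2), JointId.ROOT)


class TestZScore:
    def test_population_standard_score(self):
        z = zscore_series(_speed([0, 0, 10, 10]))
        np.testing.assert_allclose(z, [-1, -1, 1, 1])

    def test_constant_series_rejected(self):
        with pytest.raises(ConstantSignalError):
            zscore_series(_speed([5, 5, 5, 5]))

    def test_zero_mean_identity(self):
        rng = np.random.default_rng(3)
        z = zscore_series(_speed(rng.uniform(0, 100, 500)))
        assert abs(z.mean()) < 1e-9


class TestSegmentMotion:
    def test_zero_speed_yields_no_intervals(self):
        assert segment_motion(_speed(np.zeros(200))).intervals == []

    def test_constant_speed_yields_no_intervals(self):
        assert segment_motion(_speed(np.full(200, 7.0))).intervals == []

    def test_rectangular_pulse_recovered_within_half_window(self):
        v = np.zeros(600)
        v[200:290] = 500.0
        window = 3
        ivs = segment_motion(_speed(v), window=window).intervals
        assert len(ivs) == 1
        assert abs(ivs[0].start - 200) <= window / 2
        assert abs(ivs[0].end - 290) <= window / 2

    def test_short_pulses_below_k_mu_discarded(self):
        v = np.zeros(400)
        v[100:110] = 800.0
        v[300:310] = 800.0
        assert segment_motion(_speed(v), min_len=30).intervals == []

    def test_intervals_disjoint_sorted_and_long_enough(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = np.abs(rng.normal(100, 80, 700))
            v[rng.integers(0, 300) : rng.integers(300, 700)] += 600.0
            result = segment_motion(_speed(v), min_len=30)
            ivs = result.intervals
            assert all(iv.length >= 30 for iv in ivs)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_spikes_on_static_joint_yield_no_intervals(self):
        """Isolated 5-frame keypoint spikes are jitter, not movement."""
        n = 600
        track = np.tile([1500.0, -2000.0, 200.0], (n, 1))
        rng = np.random.default_rng(4)
        for s in (80, 230, 400, 520):
            direction = rng.normal(size=3)
            track[s : s + 5] += 40.0 * direction / np.linalg.norm(direction)
        seq = make_sequence(n, J8=track)
        speed = joint_speed(seq, JointId.ROOT)
        assert segment_motion(speed, min_len=30).intervals == []


class TestDelimitRoute:
    def test_monotone_climb_spans_whole_recording(self):
        n = 400
        y = np.linspace(-3000, -1000, n)
        seq = make_sequence(
            n,
            J8=np.column_stack([np.full(n, 1500.0), y, np.full(n, 200.0)]),
            J7=np.column_stack([np.full(n, 1400.0), y + 800, np.full(n, 30.0)]),
            J4=np.column_stack([np.full(n, 1600.0), y + 700, np.full(n, 30.0)]),
        )
        limits = delimit_route(seq)
        assert limits.start == 0
        assert limits.end == n - 1

    def test_hip_dip_and_repeated_wrist_maximum(self):
        """The start is the first frame of the lowest hip; the end is the
        *last* frame at which a wrist attains its maximum height."""
        n = 500
        hip_y = np.full(n, -3000.0)
        hip_y[30] = -3100.0  # lowest hip at frame 30
        hip_y[200:] = np.linspace(-3000, -1500, n - 200)
        w = np.linspace(-2500, -1000, n)
        w[400] = w[410] = -900.0  # wrist maximum attained twice
        w[411:] = -1200.0
        seq = make_sequence(
            n,
            J8=np.column_stack([np.full(n, 1500.0), hip_y, np.full(n, 200.0)]),
            J7=np.column_stack([np.full(n, 1400.0), w, np.full(n, 30.0)]),
            J4=np.column_stack([np.full(n, 1600.0), w - 400, np.full(n, 30.0)]),
        )
        limits = delimit_route(seq)
        assert limits.start == 30
        assert limits.end == 410

    def test_flat_recording_has_no_route(self):
        seq = make_sequence(100)
        with pytest.raises(DelimitationError):
            delimit_route(seq)
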