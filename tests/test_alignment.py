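"""DTW coupling: exhaustive-oracle agreement and metric properties."""

import numpy as np
import pytest

from climbkit import ClimbScript, align_climbs, dtw_align, generate_climb, hip_distance_series
from climbkit.exceptions import TooShortError
from climbkit.motion import RouteLimits, delimit_route

from .conftest import make_sequence


def brute_force_dtw(a, b):
    """Minimum total |a_i - b_j| over ALL legal couplings, by explicit
    enumeration of monotone boundary-complete paths (independent of the
    dynamic programme under test)."""
    n, m = len(a), len(b)
    best = [np.inf]

    def rec(i, j, acc):
        acc = acc + abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                rec(ni, nj, acc)

    rec(0, 0, 0.0)
    return best[0]


class TestHipDistanceSeries:
    def test_hip_at_origin_gives_zeros(self):
        seq = make_sequence(10, J8=np.zeros(3))
        assert np.all(hip_distance_series(seq, RouteLimits(0, 10)) == 0.0)

    def test_z_component_ignored(self):
        seq = make_sequence(5, J8=np.array([300.0, 400.0, 500.0]))
        np.testing.assert_allclose(hip_distance_series(seq, RouteLimits(0, 5)), 500.0)

    def test_monotone_ascent_gives_monotone_series(self):
        n = 100
        track = np.column_stack([np.zeros(n), -np.linspace(3000, 1000, n), np.full(n, 200.0)])
        seq = make_sequence(n, J8=track)
        d = hip_distance_series(seq, RouteLimits(0, n))
        assert np.all(np.diff(d) <= 0) or np.all(np.diff(d) >= 0)


class TestDtwAlign:
    def test_identical_series_couple_diagonally(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 100, 40)
        c = dtw_align(a, a)
        assert c.distance == 0.0
        assert c.pairs == [(i, i) for i in range(40)]

    def test_hand_checked_example(self):
        c = dtw_align([1.0, 2.0, 3.0], [1.0, 3.0])
        assert c.distance == pytest.approx(1.0)
        assert c.pairs[0] == (0, 0) and c.pairs[-1] == (2, 1)

    def test_one_to_many_boundary_rule(self):
        c = dtw_align([0.0], [0.0, 0.0, 0.0])
        assert c.pairs == [(0, 0), (0, 1), (0, 2)]
        assert c.distance == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(TooShortError):
            dtw_align([], [1.0])

    def test_matches_exhaustive_enumeration_on_short_series(self):
        rng = np.random.default_rng(13)
        for _ in range(80):
            a = rng.uniform(0, 10, rng.integers(1, 7))
            b = rng.uniform(0, 10, rng.integers(1, 7))
            coupling = dtw_align(a, b)
            assert coupling.distance == pytest.approx(brute_force_dtw(a, b))

    def test_metric_style_properties(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            a = rng.uniform(0, 50, 30)
            b = rng.uniform(0, 50, 25)
            assert dtw_align(a, a).distance == 0.0
            d_ab = dtw_align(a, b).distance
            assert d_ab >= 0.0
            assert dtw_align(b, a).distance == pytest.approx(d_ab)


@pytest.fixture(scope="module")
def climb():
    return generate_climb(ClimbScript(jitter_sigma=0.0, spike_prob=0.0, seed=30))


class TestAlignClimbs:
    def test_self_alignment_is_identity(self, climb):
        limits = delimit_route(climb.sequence)
        c = align_climbs(climb.sequence, climb.sequence, limits, limits)
        assert c.distance == 0.0
        assert all(i == j for i, j in c.pairs)

    def test_time_stretched_query_couples_with_fanout(self, climb):
        limits = delimit_route(climb.sequence)
        ref = hip_distance_series(climb.sequence, limits)
        stretched = np.repeat(ref, 2)
        c = dtw_align(ref, stretched)
        assert c.distance == pytest.approx(0.0, abs=1e-9)
        fanout = len(c.pairs) / len(ref)
        assert 1.9 <= fanout <= 2.1

    def test_constant_offset_on_flat_series_costs_offset_per_pair(self):
        """On a flat series warping cannot dodge a constant offset: every
        legal pair costs exactly the offset, so the optimum is offset x
        coupling length (here the shortest coupling, the diagonal)."""
        ref = np.full(50, 800.0)
        c = dtw_align(ref, ref + 100.0)
        assert len(c.pairs) == 50
        assert c.distance == pytest.approx(100.0 * 50)

    def test_offset_query_still_couples_monotonically(self, climb):
        """On a real (rising) hip series DTW legitimately warps around a
        constant offset; the result must still be a valid coupling with
        cost no worse than the diagonal pairing."""
        limits = delimit_route(climb.sequence)
        ref = hip_distance_series(climb.sequence, limits)
        c = dtw_align(ref, ref + 100.0)
        assert c.distance <= 100.0 * len(ref)
        assert c.pairs[0] == (0, 0) and c.pairs[-1] == (len(ref) - 1, len(ref) - 1)
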