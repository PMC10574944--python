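"""Dynamic-time-warping alignment of two climbs of the same route.

Two recordings of the same route differ in pace, so frames cannot be
compared index-by-index.  Both climbs are reduced to a scalar series — the
Euclidean distance of the wall-plane-projected hip centre from the wall
origin — and aligned with DTW.  The resulting *coupling* is a monotone,
boundary-complete, one-to-many frame correspondence: the first frames pair,
the last frames pair, both index streams are non-decreasing, and every
step advances at least one stream by exactly one frame.  The hip-to-wall
distance comparison (the "hip close to the wall" check) reads the
reference climb through this coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import TooShortError
from .motion import RouteLimits
from .skeleton import JointId, SkeletonSequence

__all__ = ["Coupling", "hip_distance_series", "dtw_align", "align_climbs"]


@dataclass
class Coupling:
    """An optimal DTW coupling: ordered (frame in A, frame in B) pairs and
    the accumulated alignment cost."""

    pairs: list[tuple[int, int]]
    distance: float

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        pairs = self.pairs
        assert pairs, "coupling cannot be empty"
        assert pairs[0] == (0, 0), "coupling must start at (0, 0)"
        for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
            di, dj = i1 - i0, j1 - j0
            assert di in (0, 1) and dj in (0, 1) and di + dj >= 1, (
                f"illegal coupling step ({i0},{j0}) -> ({i1},{j1})"
            )

    def pairs_for_b(self) -> dict[int, list[int]]:
        """Frames of A coupled to each frame of B."""
        out: dict[int, list[int]] = {}
        for i, j in self.pairs:
            out.setdefault(j, []).append(i)
        return out

    def to_json(self) -> dict:
        return {"pairs": [[int(i), int(j)] for i, j in self.pairs], "distance": float(self.distance)}


def hip_distance_series(seq: SkeletonSequence, limits: RouteLimits) -> np.ndarray:
    """Hip-to-origin distance over the route, mm.

    The hip-centre trajectory is projected onto the wall x–y plane and its
    Euclidean distance from the wall origin taken per frame; motion off the
    wall (z) is deliberately ignored so that the series captures progress
    *along* the route.
    """
    hip = seq.joint(JointId.ROOT)[limits.start : limits.end, :2]
    return np.linalg.norm(hip, axis=1)


def dtw_align(a: np.ndarray, b: np.ndarray) -> Coupling:
    """Optimal DTW coupling of two scalar series under |·| frame cost.

    Classic O(n·m) dynamic programme; ties during traceback prefer the
    diagonal step, so of several optimal couplings the most nearly
    synchronous one is returned.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise TooShortError("dtw_align requires two non-empty series")
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    # Row-wise DP; the horizontal dependency serialises the inner loop.
    for i in range(1, n + 1):
        ci = cost[i - 1]
        prev_row = acc[i - 1]
        row = acc[i]
        left = np.inf
        for j in range(1, m + 1):
            left = ci[j - 1] + min(prev_row[j - 1], prev_row[j], left)
            row[j] = left
    # Traceback from (n-1, m-1) to (0, 0), diagonal preferred on ties.
    pairs: list[tuple[int, int]] = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        moves = (
            (acc[i - 1, j - 1], i - 1, j - 1),  # diagonal first: tie preference
            (acc[i - 1, j], i - 1, j),
            (acc[i, j - 1], i, j - 1),
        )
        _, i, j = min(moves, key=lambda t: t[0])
        pairs.append((i - 1, j - 1))
    pairs.reverse()
    return Coupling(pairs=pairs, distance=float(acc[n, m]))


def align_climbs(
    reference: SkeletonSequence,
    query: SkeletonSequence,
    reference_limits: RouteLimits,
    query_limits: RouteLimits,
) -> Coupling:
    """DTW coupling of two delimited, wall-space climbs of the same route.

    Pairs are route-relative frame indices ``(reference frame, query
    frame)``.  Calibration to the shared wall frame is what makes the two
    hip series comparable even when the recordings used different camera
    poses.
    """
    ref_series = hip_distance_series(reference, reference_limits)
    query_series = hip_distance_series(query, query_limits)
    return dtw_align(ref_series, query_series)
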