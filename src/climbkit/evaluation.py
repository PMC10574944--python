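"""Temporal-IoU matching of detections against ground truth and
precision–recall sweeps.

Detected error intervals are compared with manually labelled frame ranges
using the 1-D intersection-over-union.  A detection that overlaps no label
at all is a false positive; a matched detection is a true positive when
its IoU clears the threshold τ and otherwise leaves its label counted as a
false negative (the detection is consumed, not double-counted as an FP —
FPs are reserved for zero-overlap detections, which differs from common
object-detection practice and is deliberate here).  Sweeping τ yields the
precision–recall curve; the operating point maximising F1 is reported as
optimal.  Error detection is a rare-event problem with heavily unbalanced
frames, which is why precision–recall is used rather than ROC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .skeleton import FrameInterval
from .technique import ErrorEvent

__all__ = [
    "LabeledError",
    "PRPoint",
    "PRCurve",
    "interval_iou",
    "match_detections",
    "pr_curve",
]


@dataclass(frozen=True)
class LabeledError:
    """A ground-truth error label: type and frame interval."""

    type: str
    interval: FrameInterval

    def to_json(self) -> dict:
        return {"type": self.type, **self.interval.to_json()}

    @classmethod
    def from_json(cls, doc: dict) -> "LabeledError":
        return cls(type=doc["type"], interval=FrameInterval(doc["start"], doc["end"]))


@dataclass(frozen=True)
class PRPoint:
    iou_threshold: float
    precision: float | None  # None when TP+FP == 0
    recall: float | None  # None when TP+FN == 0
    tp: int
    fp: int
    fn: int

    @property
    def f1(self) -> float:
        p = self.precision or 0.0
        r = self.recall or 0.0
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    def to_json(self) -> dict:
        return {
            "iou_threshold": self.iou_threshold,
            "precision": self.precision,
            "recall": self.recall,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


@dataclass
class PRCurve:
    """Precision–recall sweep over IoU thresholds, with the max-F1 point."""

    points: list[PRPoint]
    optimal: PRPoint | None

    def __post_init__(self) -> None:
        taus = [p.iou_threshold for p in self.points]
        assert taus == sorted(set(taus)), "thresholds must be strictly increasing"

    def to_json(self) -> dict:
        return {
            "points": [p.to_json() for p in self.points],
            "optimal": None if self.optimal is None else self.optimal.to_json(),
        }


def interval_iou(a: FrameInterval, b: FrameInterval) -> float:
    """1-D intersection over union of two frame intervals, in [0, 1].

    Frames are counted under the half-open convention; the union of
    disjoint intervals is the sum of their lengths.
    """
    inter = a.intersection_length(b)
    union = a.length + b.length - inter
    return inter / union


def match_detections(
    detections: Sequence[ErrorEvent | LabeledError],
    labels: Sequence[LabeledError],
    tau: float,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to labels of one type.

    Pairs are matched in order of descending IoU.  A matched pair with
    IoU ≥ τ is a TP; with 0 < IoU < τ the label counts as an FN and the
    detection is consumed.  A detection with zero overlap against every
    label is an FP; every unmatched label is an FN.  Hence TP + FN always
    equals the number of labels.

    Returns ``(tp, fp, fn)``.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    n_det, n_lab = len(detections), len(labels)
    iou = np.zeros((n_det, n_lab))
    for d, det in enumerate(detections):
        for l, lab in enumerate(labels):
            iou[d, l] = interval_iou(det.interval, lab.interval)
    order = sorted(
        ((iou[d, l], d, l) for d in range(n_det) for l in range(n_lab) if iou[d, l] > 0),
        key=lambda t: -t[0],
    )
    det_used = [False] * n_det
    lab_used = [False] * n_lab
    tp = fn_matched = 0
    for score, d, l in order:
        if det_used[d] or lab_used[l]:
            continue
        det_used[d] = True
        lab_used[l] = True
        if score >= tau:
            tp += 1
        else:
            fn_matched += 1  # below threshold: label missed, detection consumed
    # Detections with zero overlap against every label are false positives.
    fp = sum(
        1 for d in range(n_det) if not det_used[d] and (n_lab == 0 or np.all(iou[d] == 0))
    )
    fn = fn_matched + sum(1 for l in range(n_lab) if not lab_used[l])
    return tp, fp, fn


def pr_curve(
    detections: Sequence[ErrorEvent | LabeledError],
    labels: Sequence[LabeledError],
    n_thresholds: int = 20,
) -> PRCurve:
    """Precision–recall sweep over equispaced IoU thresholds in (0, 1].

    precision = TP/(TP+FP), recall = TP/(TP+FN) at each τ; undefined
    ratios (empty denominators) are reported as None.  The optimal point
    maximises F1, with ties resolved toward the higher threshold so the
    strictest equally-good operating point is reported.
    """
    if n_thresholds < 2:
        raise ValueError(f"n_thresholds must be >= 2, got {n_thresholds}")
    taus = [(k + 1) / n_thresholds for k in range(n_thresholds)]
    points: list[PRPoint] = []
    for tau in taus:
        tp, fp, fn = match_detections(detections, labels, tau)
        precision = None if tp + fp == 0 else tp / (tp + fp)
        recall = None if tp + fn == 0 else tp / (tp + fn)
        points.append(
            PRPoint(iou_threshold=tau, precision=precision, recall=recall, tp=tp, fp=fp, fn=fn)
        )
    if not detections and not labels:
        return PRCurve(points=points, optimal=None)
    optimal = max(points, key=lambda p: (p.f1, p.iou_threshold))
    return PRCurve(points=points, optimal=optimal)
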