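"""Detection matching, confusion counts, P/R/accuracy/F1 and average precision.

Two reporting framings are supported.  The per-kernel classification framing
counts a matched fluorescent truth as TP, a missed fluorescent truth as FN,
an unmatched (or wrongly matched) detection as FP and an untouched
non-fluorescent truth as TN.  Pure-detection reports simply omit TN.

Matching is greedy in descending detection score (PASCAL style): each
detection takes the unmatched truth of maximal IoU when that IoU reaches the
threshold.  Score ties are broken by input order; the result is invariant to
permutations of the truth list.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Protocol, Sequence

from .losses import BBox, iou

__all__ = [
    "Detection",
    "TruthBox",
    "ConfusionCounts",
    "PRCurve",
    "match_detections",
    "precision",
    "recall",
    "accuracy",
    "f1",
    "pr_curve",
    "average_precision",
]


class _Truth(Protocol):
    bbox: BBox

    @property
    def is_fluorescent(self) -> bool: ...


@dataclass(frozen=True)
class Detection:
    """One detector output box."""

    bbox: BBox
    score: float
    predicted_class: str = "fluorescent"

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class TruthBox:
    """Minimal ground-truth object for evaluation without a full scene."""

    bbox: BBox
    fluorescent: bool = True

    @property
    def is_fluorescent(self) -> bool:
        return self.fluorescent


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall at every distinct score threshold, descending."""

    thresholds: tuple[float, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.thresholds) == len(self.precision) == len(self.recall)):
            raise ValueError("curve arrays must have equal length")
        if any(b < a for a, b in zip(self.recall, self.recall[1:])):
            raise ValueError("recall must be non-decreasing")


def _greedy_match(
    dets: Sequence[Detection],
    truths: Sequence[_Truth],
    iou_thresh: float,
    matchable: Sequence[bool],
) -> list[int | None]:
    """For each detection (input order) the matched truth index or None."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    taken = [False] * len(truths)
    assignment: list[int | None] = [None] * len(dets)
    for i in order:
        best_j, best_iou = None, 0.0
        for j, truth in enumerate(truths):
            if taken[j] or not matchable[j]:
                continue
            overlap = iou(dets[i].bbox, truth.bbox)
            if overlap >= iou_thresh and overlap > best_iou:
                best_j, best_iou = j, overlap
        if best_j is not None:
            taken[best_j] = True
            assignment[i] = best_j
    return assignment


def match_detections(
    dets: Sequence[Detection],
    truths: Sequence[_Truth],
    iou_thresh: float = 0.5,
) -> ConfusionCounts:
    """Per-kernel confusion counts from greedy IoU matching.

    All truths are matchable; a detection landing on a non-fluorescent truth
    is a false positive (it wrongly claims fluorescence) and consumes that
    truth, so it is not also counted as a true negative.
    """
    if not (0.0 < iou_thresh < 1.0):
        raise ValueError("iou_thresh must be in (0, 1)")
    assignment = _greedy_match(dets, truths, iou_thresh, [True] * len(truths))
    tp = fp = 0
    matched = set()
    for i, j in enumerate(assignment):
        if j is None:
            fp += 1
        else:
            matched.add(j)
            if truths[j].is_fluorescent:
                tp += 1
            else:
                fp += 1
    fn = sum(
        1 for j, t in enumerate(truths) if t.is_fluorescent and j not in matched
    )
    tn = sum(
        1 for j, t in enumerate(truths) if not t.is_fluorescent and j not in matched
    )
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        raise ZeroDivisionError(f"{what} undefined: zero denominator")
    return float(Fraction(num, den))


def precision(cc: ConfusionCounts) -> float:
    return _ratio(cc.tp, cc.tp + cc.fp, "precision")


def recall(cc: ConfusionCounts) -> float:
    return _ratio(cc.tp, cc.tp + cc.fn, "recall")


def accuracy(cc: ConfusionCounts) -> float:
    return _ratio(cc.tp + cc.tn, cc.total, "accuracy")


def f1(cc: ConfusionCounts) -> float:
    p, r = precision(cc), recall(cc)
    if p + r == 0:
        raise ZeroDivisionError("f1 undefined: precision + recall is zero")
    return 2.0 * p * r / (p + r)


def pr_curve(
    dets: Sequence[Detection],
    truths: Sequence[_Truth],
    iou_thresh: float = 0.5,
) -> PRCurve:
    """Precision/recall swept over every distinct detection score.

    Only fluorescent truths are matchable here (the detector's task is to
    find fluorescent kernels); recall is over the fluorescent truth count.
    """
    if not (0.0 < iou_thresh < 1.0):
        raise ValueError("iou_thresh must be in (0, 1)")
    n_positive = sum(1 for t in truths if t.is_fluorescent)
    if n_positive == 0:
        raise ValueError("pr_curve needs at least one fluorescent truth")
    matchable = [t.is_fluorescent for t in truths]
    assignment = _greedy_match(dets, truths, iou_thresh, matchable)
    is_tp = [assignment[i] is not None for i in range(len(dets))]

    scored = sorted(zip((d.score for d in dets), is_tp), key=lambda t: -t[0])
    thresholds: list[float] = []
    precisions: list[float] = []
    recalls: list[float] = []
    tp = fp = 0
    i = 0
    while i < len(scored):
        threshold = scored[i][0]
        while i < len(scored) and scored[i][0] == threshold:
            if scored[i][1]:
                tp += 1
            else:
                fp += 1
            i += 1
        thresholds.append(threshold)
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_positive)
    return PRCurve(tuple(thresholds), tuple(precisions), tuple(recalls))


def average_precision(curve: PRCurve) -> float:
    """Area under the P-R curve with the all-points precision envelope."""
    if not curve.thresholds:
        return 0.0
    recalls = list(curve.recall)
    # envelope: max precision at any recall >= r
    envelope = list(curve.precision)
    for i in range(len(envelope) - 2, -1, -1):
        envelope[i] = max(envelope[i], envelope[i + 1])
    ap = 0.0
    prev_recall = 0.0
    for r, p in zip(recalls, envelope):
        ap += (r - prev_recall) * p
        prev_recall = r
    return ap
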