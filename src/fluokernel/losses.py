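"""Axis-aligned bounding boxes and IoU-family regression losses.

Boxes are stored in corner format (``x_min, y_min, x_max, y_max``) in pixel
units with the half-open convention ``[min, max)``.  Centre, width and height
are always derived, never stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "BBox",
    "CIOUTerms",
    "iou",
    "giou",
    "ciou_terms",
    "ciou_loss",
    "rank_candidates",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box with strictly positive width and height."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def translate(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def scale(self, factor: float) -> "BBox":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return BBox(
            self.x_min * factor, self.y_min * factor,
            self.x_max * factor, self.y_max * factor,
        )


@dataclass(frozen=True)
class CIOUTerms:
    """All intermediate quantities of the complete-IoU loss."""

    iou: float
    rho2: float        # squared centre-point distance
    c_diag2: float     # squared diagonal of the smallest enclosing box
    v: float           # aspect-ratio consistency penalty
    alpha: float       # trade-off weight for v
    loss: float
    w: float
    h: float
    w_gt: float
    h_gt: float


def _intersection_area(a: BBox, b: BBox) -> float:
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    return iw * ih


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union; 0 for disjoint boxes, 1 for identical."""
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union


def giou(a: BBox, b: BBox) -> float:
    """Generalized IoU: IoU minus the normalized empty share of the hull."""
    hull_w = max(a.x_max, b.x_max) - min(a.x_min, b.x_min)
    hull_h = max(a.y_max, b.y_max) - min(a.y_min, b.y_min)
    hull_area = hull_w * hull_h
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union - (hull_area - union) / hull_area


def ciou_terms(pred: BBox, target: BBox) -> CIOUTerms:
    """Complete-IoU decomposition of ``pred`` against ``target``.

    loss = 1 - IoU + rho^2 / c^2 + alpha * v, where rho is the distance
    between the two box centres, c the diagonal of the smallest enclosing
    box, v = (4/pi^2) * (arctan(w_gt/h_gt) - arctan(w/h))^2 and
    alpha = v / ((1 - IoU) + v), with alpha defined as 0 when v = 0 so
    that a perfect match yields exactly zero loss.
    """
    i = iou(pred, target)

    (cx_p, cy_p), (cx_t, cy_t) = pred.center, target.center
    rho2 = (cx_p - cx_t) ** 2 + (cy_p - cy_t) ** 2

    hull_w = max(pred.x_max, target.x_max) - min(pred.x_min, target.x_min)
    hull_h = max(pred.y_max, target.y_max) - min(pred.y_min, target.y_min)
    c_diag2 = hull_w**2 + hull_h**2

    v = (4.0 / math.pi**2) * (
        math.atan(target.width / target.height) - math.atan(pred.width / pred.height)
    ) ** 2
    alpha = 0.0 if v == 0.0 else v / ((1.0 - i) + v)

    loss = 1.0 - i + rho2 / c_diag2 + alpha * v
    return CIOUTerms(
        iou=i, rho2=rho2, c_diag2=c_diag2, v=v, alpha=alpha, loss=loss,
        w=pred.width, h=pred.height, w_gt=target.width, h_gt=target.height,
    )


def ciou_loss(pred: BBox, target: BBox) -> float:
    return ciou_terms(pred, target).loss


def rank_candidates(cands: Sequence[BBox], target: BBox) -> list[int]:
    """Indices of ``cands`` ordered best-first by CIoU loss against ``target``.

    Ties are broken by lower squared centre distance, then lower aspect
    penalty, then original input order.
    """
    if not cands:
        raise ValueError("need at least one candidate box")
    terms = [ciou_terms(c, target) for c in cands]
    return sorted(
        range(len(cands)),
        key=lambda k: (terms[k].loss, terms[k].rho2, terms[k].v, k),
    )
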