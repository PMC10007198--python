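"""Image augmentation: gamma transform, HSV jitter, mosaic composition.

The gamma transform is the power law ``s = c * r**gamma`` applied to
[0, 1]-normalized intensities, so ``c = 1`` keeps the range closed; gamma
below 1 brightens and above 1 darkens.  The jitter and mosaic operators are
YOLO-style training-time augmentations, deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize as _sk_resize

from .losses import BBox

__all__ = [
    "GammaParams",
    "JitterParams",
    "gamma_transform",
    "hsv_jitter",
    "mosaic",
]

_MOSAIC_MIN_AREA_FRACTION = 0.2  # drop boxes keeping < 20% of their area


@dataclass(frozen=True)
class GammaParams:
    """Power-law parameters: output = c * input**gamma."""

    gamma: float = 0.7
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")


@dataclass(frozen=True)
class JitterParams:
    """Random HSV gains; hue shifts mod 1, S and V scale multiplicatively."""

    h_gain: float = 0.0138
    s_gain: float = 0.664
    v_gain: float = 0.464

    def __post_init__(self) -> None:
        if min(self.h_gain, self.s_gain, self.v_gain) < 0:
            raise ValueError("jitter gains must be >= 0")


def gamma_transform(
    img: np.ndarray, p: GammaParams, on_v_only: bool = False
) -> np.ndarray:
    """Apply the power law per pixel (per channel for RGB input).

    With ``on_v_only`` an RGB image is transformed only in its V channel,
    matching the grey-value reading of the transform.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("input values must lie in [0, 1]")
    if on_v_only:
        if img.ndim != 3 or img.shape[-1] != 3:
            raise ValueError("on_v_only requires an RGB image")
        hsv = rgb2hsv(img)
        hsv[..., 2] = np.clip(p.c * hsv[..., 2] ** p.gamma, 0.0, 1.0)
        return hsv2rgb(hsv)
    return np.clip(p.c * img**p.gamma, 0.0, 1.0)


def hsv_jitter(img: np.ndarray, p: JitterParams, seed: int) -> np.ndarray:
    """Randomly jitter hue/saturation/value, deterministic given ``seed``.

    One uniform draw u ~ U(-1, 1) per channel: H shifts by u*h_gain mod 1,
    S and V are scaled by (1 + u*gain) and clipped to [0, 1].
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 image")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0, size=3)
    hsv = rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] + u[0] * p.h_gain) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + u[1] * p.s_gain), 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1.0 + u[2] * p.v_gain), 0.0, 1.0)
    return np.clip(hsv2rgb(hsv), 0.0, 1.0)


def _transform_boxes(
    boxes: Sequence[tuple[int, BBox]],
    src_w: int,
    src_h: int,
    out_size: int,
    offset: tuple[float, float],
    clip_rect: tuple[float, float, float, float],
) -> list[tuple[int, BBox]]:
    sx = out_size / src_w
    sy = out_size / src_h
    ox, oy = offset
    cx0, cy0, cx1, cy1 = clip_rect
    out: list[tuple[int, BBox]] = []
    for class_index, box in boxes:
        x0 = box.x_min * sx + ox
        y0 = box.y_min * sy + oy
        x1 = box.x_max * sx + ox
        y1 = box.y_max * sy + oy
        full = (x1 - x0) * (y1 - y0)
        kx0, ky0 = max(x0, cx0), max(y0, cy0)
        kx1, ky1 = min(x1, cx1), min(y1, cy1)
        if kx1 <= kx0 or ky1 <= ky0:
            continue
        if (kx1 - kx0) * (ky1 - ky0) < _MOSAIC_MIN_AREA_FRACTION * full:
            continue
        out.append((class_index, BBox(kx0, ky0, kx1, ky1)))
    return out


def mosaic(
    imgs: Sequence[np.ndarray],
    labels: Sequence[Sequence[tuple[int, BBox]]],
    out_size: int,
    seed: int,
    center: tuple[int, int] | None = None,
) -> tuple[np.ndarray, list[tuple[int, BBox]]]:
    """Compose four images into one canvas split at a random centre point.

    Each input is bilinearly resized to ``out_size`` square, then the part
    adjoining the centre is cropped into its quadrant (top-left, top-right,
    bottom-left, bottom-right in input order).  ``labels`` are per-image
    lists of ``(class_index, BBox)`` in source pixel coordinates; output
    boxes are clipped to their quadrant and dropped when less than 20% of
    their transformed area survives.  ``center`` overrides the random centre
    (used in tests).
    """
    if len(imgs) != 4 or len(labels) != 4:
        raise ValueError("mosaic requires exactly 4 images and 4 label lists")
    rng = np.random.default_rng(seed)
    if center is None:
        cx = int(rng.uniform(0.25, 0.75) * out_size)
        cy = int(rng.uniform(0.25, 0.75) * out_size)
    else:
        cx, cy = center
    if not (0 < cx < out_size and 0 < cy < out_size):
        raise ValueError("mosaic centre must lie strictly inside the canvas")

    canvas = np.zeros((out_size, out_size, 3), dtype=np.float64)
    # (row slice, col slice, resized row slice, resized col slice, offset)
    placements = [
        (slice(0, cy), slice(0, cx),
         slice(out_size - cy, out_size), slice(out_size - cx, out_size),
         (cx - out_size, cy - out_size)),
        (slice(0, cy), slice(cx, out_size),
         slice(out_size - cy, out_size), slice(0, out_size - cx),
         (cx, cy - out_size)),
        (slice(cy, out_size), slice(0, cx),
         slice(0, out_size - cy), slice(out_size - cx, out_size),
         (cx - out_size, cy)),
        (slice(cy, out_size), slice(cx, out_size),
         slice(0, out_size - cy), slice(0, out_size - cx),
         (cx, cy)),
    ]
    quadrants = [
        (0.0, 0.0, float(cx), float(cy)),
        (float(cx), 0.0, float(out_size), float(cy)),
        (0.0, float(cy), float(cx), float(out_size)),
        (float(cx), float(cy), float(out_size), float(out_size)),
    ]

    out_boxes: list[tuple[int, BBox]] = []
    for img, boxes, placement, quad in zip(imgs, labels, placements, quadrants):
        img = np.asarray(img, dtype=np.float64)
        if img.ndim != 3 or img.shape[-1] != 3:
            raise ValueError("expected H x W x 3 images")
        src_h, src_w = img.shape[:2]
        resized = _sk_resize(
            img, (out_size, out_size), order=1, mode="reflect",
            anti_aliasing=False, preserve_range=True,
        )
        rows, cols, src_rows, src_cols, offset = placement
        canvas[rows, cols] = resized[src_rows, src_cols]
        out_boxes.extend(
            _transform_boxes(boxes, src_w, src_h, out_size, offset, quad)
        )
    return np.clip(canvas, 0.0, 1.0), out_boxes
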