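"""Synthetic fluorescent-seed scene generator.

Renders elliptical kernels with a radial brightness falloff on a near-black
background, mimicking dark-box fluorescence imaging.  Three kernel classes
are supported: a bright red-magenta emitter, a dim red emitter and a
non-fluorescent near-background class.  Every scene comes with full ground
truth (per-kernel mask, tight box, class, centroid, mean emission) so the
segmentation, feature and evaluation stages can be tested without a camera.

Output is a pure function of (config, seed): the per-scene RNG stream is
split deterministically per kernel so identical configs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .labels import CLASS_NAMES, LabelRecord, YOLO_TXT, VOC_XML
from .losses import BBox

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_BRIGHTNESS",
    "SceneConfig",
    "KernelTruth",
    "PlacementError",
    "generate_scene",
    "scene_to_labels",
]

#: Mean RGB emission per class, chosen so that (a) mean R strictly orders the
#: classes bright > dim > non-fluorescent, (b) Otsu separates every class from
#: the default 0.02 background, and (c) hue cleanly splits fluorescent
#: (red-magenta, H near 1) from non-fluorescent (yellowish, H near 0.1).
DEFAULT_BRIGHTNESS: Mapping[str, tuple[float, float, float]] = {
    "mCherry-1": (0.45, 0.12, 0.22),
    "DsRed-2": (0.30, 0.07, 0.12),
    "Non-3": (0.15, 0.13, 0.07),
}

_MAX_ATTEMPTS = 1000  # rejection-sampling cap per kernel
_FALLOFF = 0.25       # radial brightness falloff at the ellipse edge


class PlacementError(RuntimeError):
    """Raised when a kernel cannot be placed without violating the gap."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene."""

    width_px: int = 640
    height_px: int = 640
    n_kernels: int = 12
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    kernel_axis_px: tuple[float, float] = (10.0, 16.0)
    min_gap_px: int = 5
    brightness: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BRIGHTNESS)
    )
    background: float = 0.02
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_kernels < 0:
            raise ValueError("n_kernels must be non-negative")
        if len(self.class_mix) != 3 or any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix must be three non-negative proportions")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        lo, hi = self.kernel_axis_px
        if not (0 < lo <= hi):
            raise ValueError("kernel_axis_px must be a positive (lo, hi) range")
        if 2 * hi >= min(self.width_px, self.height_px):
            raise ValueError("largest kernel does not fit inside the frame")
        if self.min_gap_px < 0:
            raise ValueError("min_gap_px must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.background < 1.0):
            raise ValueError("background must be in [0, 1)")
        for name in CLASS_NAMES:
            if name not in self.brightness:
                raise ValueError(f"brightness missing class {name!r}")


@dataclass(frozen=True)
class KernelTruth:
    """Ground truth for one rendered kernel."""

    mask: np.ndarray            # full-frame boolean raster
    bbox: BBox                  # tight box of mask, half-open pixel coords
    class_label: str
    centroid: tuple[float, float]   # (row, col)
    mean_emission: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("kernel mask is empty")
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_label!r}")

    @property
    def is_fluorescent(self) -> bool:
        return self.class_label != "Non-3"


def _tight_bbox(mask: np.ndarray) -> BBox:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return BBox(float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1))


def _ellipse_patch(
    a: float, b: float, theta: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Boolean ellipse mask and squared normalized radius on a local grid.

    Returns (mask, d2, half) where the patch spans ``[-half, half]`` in both
    directions around the ellipse centre.
    """
    half = int(np.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx * ct + yy * st) / a
    w = (-xx * st + yy * ct) / b
    d2 = u * u + w * w
    return d2 <= 1.0, d2, half


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, list[KernelTruth]]:
    """Render one scene; returns (H x W x 3 float image in [0,1], truths).

    Raises :class:`PlacementError` when a kernel cannot be placed after the
    rejection-sampling cap while honouring ``min_gap_px``.
    """
    h, w = config.height_px, config.width_px
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_kernels + 1)
    scene_rng = np.random.default_rng(streams[0])

    emission = np.zeros((h, w, 3), dtype=np.float64)
    occupancy = np.zeros((h, w), dtype=bool)
    # distance from each free pixel to the nearest occupied pixel
    free_dist = np.full((h, w), np.inf)
    truths: list[KernelTruth] = []
    lo, hi = config.kernel_axis_px

    for k in range(config.n_kernels):
        rng = np.random.default_rng(streams[k + 1])
        label = CLASS_NAMES[int(rng.choice(3, p=np.asarray(config.class_mix)))]
        placed = False
        for attempt in range(_MAX_ATTEMPTS):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            theta = rng.uniform(0.0, np.pi)
            patch, d2, half = _ellipse_patch(a, b, theta)
            if 2 * half + 1 > min(h, w):
                continue
            row = int(rng.integers(half, h - half))
            col = int(rng.integers(half, w - half))
            rows = slice(row - half, row + half + 1)
            cols = slice(col - half, col + half + 1)
            window = free_dist[rows, cols][patch]
            if config.min_gap_px > 0:
                ok = bool(np.all(window >= config.min_gap_px))
            else:
                ok = bool(np.all(window > 0))  # disjoint, touching allowed
            if not ok:
                continue

            base = np.asarray(config.brightness[label], dtype=np.float64)
            profile = 1.0 - _FALLOFF * d2[patch]
            region = emission[rows, cols]  # view into the full frame
            region[patch] = base[None, :] * profile[:, None]

            full_mask = np.zeros((h, w), dtype=bool)
            full_mask[rows, cols] = patch
            occupancy |= full_mask
            free_dist = ndi.distance_transform_edt(~occupancy)

            rr, cc = np.nonzero(full_mask)
            truths.append(
                KernelTruth(
                    mask=full_mask,
                    bbox=_tight_bbox(full_mask),
                    class_label=label,
                    centroid=(float(rr.mean()), float(cc.mean())),
                    mean_emission=tuple(emission[full_mask].mean(axis=0)),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place kernel {k + 1}/{config.n_kernels} after "
                f"{_MAX_ATTEMPTS} attempts with min_gap_px={config.min_gap_px}"
            )

    image = np.where(occupancy[..., None], emission, config.background)
    if config.noise_sd > 0:
        image = image + scene_rng.normal(0.0, config.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 1.0), truths


def scene_to_labels(
    truths: Sequence[KernelTruth],
    format: str = YOLO_TXT,
    image_size: tuple[int, int] | None = None,
) -> list[LabelRecord]:
    """Convert ground truth to label records (one per truth).

    ``image_size`` (width, height) is inferred from the truth masks when
    omitted; it is only required for an empty truth list.
    """
    if format not in (YOLO_TXT, VOC_XML):
        raise ValueError(f"unknown label format {format!r}")
    if not truths:
        return []
    if image_size is None:
        h, w = truths[0].mask.shape
        image_size = (w, h)
    width, height = image_size
    return [
        LabelRecord.from_bbox(
            CLASS_NAMES.index(t.class_label), t.bbox, width, height,
            source_format=format,
        )
        for t in truths
    ]
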