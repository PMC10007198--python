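"""Colour-moment features per kernel and a two-threshold fluorescence rule.

For each of the six channels R, G, B, H, S, V over the masked pixels we
report the mean, the second moment (standard deviation) and the third moment
(signed cube root of the third central moment) — the classic compact colour
descriptor.  Channels are on the [0, 1] scale by default; ``scale=255``
rescales for comparability experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "CHANNELS",
    "FLUORESCENT",
    "NON_FLUORESCENT",
    "ColorMomentVector",
    "ThresholdRule",
    "rgb_to_hsv",
    "color_moments",
    "moment_classify",
    "fit_threshold_rule",
    "moments_table",
]

CHANNELS = ("r", "g", "b", "h", "s", "v")
FLUORESCENT = "fluorescent"
NON_FLUORESCENT = "non-fluorescent"


@dataclass(frozen=True)
class ColorMomentVector:
    """18 colour moments: {R,G,B,H,S,V} x {mean, second, third}."""

    r_mean: float
    r_second: float
    r_third: float
    g_mean: float
    g_second: float
    g_third: float
    b_mean: float
    b_second: float
    b_third: float
    h_mean: float
    h_second: float
    h_third: float
    s_mean: float
    s_second: float
    s_third: float
    v_mean: float
    v_second: float
    v_third: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value):
                raise ValueError(f"{f.name} is not finite: {value}")
            if f.name.endswith("_second") and value < 0:
                raise ValueError(f"{f.name} must be >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


@dataclass(frozen=True)
class ThresholdRule:
    """Fluorescent iff (H mean > theta_h) or (V mean > theta_v), strictly."""

    theta_h: float
    theta_v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta_h) and np.isfinite(self.theta_v)):
            raise ValueError("thresholds must be finite")


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Hexcone RGB->HSV; H in [0, 1), S and V in [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 image")
    hsv = rgb2hsv(img)
    hsv[..., 0] = np.where(hsv[..., 0] >= 1.0, hsv[..., 0] - 1.0, hsv[..., 0])
    return hsv


def _channel_moments(x: np.ndarray) -> tuple[float, float, float]:
    mu = float(x.mean())
    centered = x - mu
    second = float(np.sqrt(np.mean(centered**2)))
    third = float(np.cbrt(np.mean(centered**3)))
    return mu, second, third


def color_moments(
    img: np.ndarray, mask: np.ndarray, scale: float = 1.0
) -> ColorMomentVector:
    """Colour moments over the masked pixels of ``img``.

    ``scale`` multiplies all six channels before the moments are taken
    (use 255 for byte-scale comparability).
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("empty mask")
    rgb = img[mask] * scale
    hsv = rgb_to_hsv(img)[mask] * scale
    values: list[float] = []
    for channel in range(3):
        values.extend(_channel_moments(rgb[:, channel]))
    for channel in range(3):
        values.extend(_channel_moments(hsv[:, channel]))
    return ColorMomentVector(*values)


def moment_classify(v: ColorMomentVector, rule: ThresholdRule) -> str:
    """Classify a moment vector; ties at the threshold are non-fluorescent."""
    if v.h_mean > rule.theta_h or v.v_mean > rule.theta_v:
        return FLUORESCENT
    return NON_FLUORESCENT


def fit_threshold_rule(
    vectors: Sequence[ColorMomentVector], labels: Iterable[str]
) -> ThresholdRule:
    """Midpoint-of-class-means thresholds on H mean and V mean.

    ``labels`` holds :data:`FLUORESCENT` / :data:`NON_FLUORESCENT` per vector.
    """
    labels = list(labels)
    if len(labels) != len(vectors):
        raise ValueError("labels and vectors differ in length")
    fluor = [v for v, l in zip(vectors, labels) if l == FLUORESCENT]
    non = [v for v, l in zip(vectors, labels) if l == NON_FLUORESCENT]
    if not fluor or not non:
        raise ValueError("need at least one vector of each class")
    theta_h = (np.mean([v.h_mean for v in fluor]) + np.mean([v.h_mean for v in non])) / 2
    theta_v = (np.mean([v.v_mean for v in fluor]) + np.mean([v.v_mean for v in non])) / 2
    return ThresholdRule(float(theta_h), float(theta_v))


def moments_table(vectors: Sequence[ColorMomentVector], index: Sequence | None = None):
    """Per-kernel 18-feature table as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame([v.as_dict() for v in vectors], index=index)
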