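"""Forward pass of a convolutional block attention module on plain arrays.

Channel attention first: sigmoid of a shared two-layer MLP applied to both
the average-pooled and the max-pooled channel descriptors, summed.  The
resulting per-channel weights scale the input; spatial attention (sigmoid of
a convolution over the channel-mean and channel-max maps of the intermediate
feature) then scales the result.  Both weight stages live strictly in (0, 1),
so the module can only attenuate.  No gradients, no training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "CBAMParams",
    "init_cbam_params",
    "channel_attention",
    "spatial_attention",
    "cbam_forward",
]


@dataclass(frozen=True)
class CBAMParams:
    """Weights of the module.

    ``w_reduce`` maps C -> C/r, ``w_expand`` maps C/r -> C (shared MLP, no
    biases); ``spatial_conv_weights`` has shape (2, k, k) with odd k, one
    slice for the mean map and one for the max map.
    """

    reduction_ratio: int
    w_reduce: np.ndarray
    w_expand: np.ndarray
    spatial_conv_weights: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        hidden, channels = self.w_reduce.shape
        if self.w_expand.shape != (channels, hidden):
            raise ValueError(
                f"w_expand shape {self.w_expand.shape} does not mirror "
                f"w_reduce shape {self.w_reduce.shape}"
            )
        if channels % self.reduction_ratio != 0:
            raise ValueError("channel count must be divisible by reduction_ratio")
        if self.spatial_conv_weights.ndim != 3 or self.spatial_conv_weights.shape[0] != 2:
            raise ValueError("spatial_conv_weights must have shape (2, k, k)")
        k = self.spatial_conv_weights.shape[1]
        if self.spatial_conv_weights.shape[2] != k or k % 2 == 0:
            raise ValueError("spatial kernel must be square with odd size")

    @property
    def channels(self) -> int:
        return self.w_reduce.shape[1]


def init_cbam_params(
    channels: int,
    reduction_ratio: int = 16,
    kernel_size: int = 7,
    seed: int = 0,
) -> CBAMParams:
    """Random Gaussian initialization, bit-identical for a fixed seed."""
    if channels % reduction_ratio != 0:
        raise ValueError("channels must be divisible by reduction_ratio")
    rng = np.random.default_rng(seed)
    hidden = channels // reduction_ratio
    scale = 1.0 / np.sqrt(channels)
    return CBAMParams(
        reduction_ratio=reduction_ratio,
        w_reduce=rng.normal(0.0, scale, size=(hidden, channels)),
        w_expand=rng.normal(0.0, scale, size=(channels, hidden)),
        spatial_conv_weights=rng.normal(0.0, scale, size=(2, kernel_size, kernel_size)),
        seed=seed,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _mlp(p: CBAMParams, pooled: np.ndarray) -> np.ndarray:
    hidden = np.maximum(p.w_reduce @ pooled, 0.0)  # ReLU
    return p.w_expand @ hidden


def _check_input(x: np.ndarray, p: CBAMParams) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected a C x H x W feature map")
    if x.shape[0] != p.channels:
        raise ValueError(
            f"feature map has {x.shape[0]} channels, params expect {p.channels}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map must be finite")
    return x


def channel_attention(x: np.ndarray, p: CBAMParams) -> np.ndarray:
    """Per-channel weights: sigmoid(MLP(avgpool) + MLP(maxpool)), in (0, 1)."""
    x = _check_input(x, p)
    avg = x.mean(axis=(1, 2))
    mx = x.max(axis=(1, 2))
    return _sigmoid(_mlp(p, avg) + _mlp(p, mx))


def spatial_attention(x: np.ndarray, p: CBAMParams) -> np.ndarray:
    """H x W weight map: sigmoid(conv([channel-mean; channel-max]))."""
    x = _check_input(x, p)
    mean_map = x.mean(axis=0)
    max_map = x.max(axis=0)
    response = (
        ndi.correlate(mean_map, p.spatial_conv_weights[0], mode="reflect")
        + ndi.correlate(max_map, p.spatial_conv_weights[1], mode="reflect")
    )
    return _sigmoid(response)


def cbam_forward(x: np.ndarray, p: CBAMParams) -> np.ndarray:
    """Channel attention, then spatial attention on the intermediate feature."""
    x = _check_input(x, p)
    cw = channel_attention(x, p)
    intermediate = cw[:, None, None] * x
    sw = spatial_attention(intermediate, p)
    return sw[None, :, :] * intermediate
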