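"""Classical pre-processing and instance segmentation chain.

grayscale -> median filter -> Laplacian sharpening -> Otsu + morphology ->
distance-transform-seeded watershed -> per-kernel crops.  Fully
deterministic; 0-based row-major coordinates, boxes half-open [min, max).
All filters use reflect padding to avoid dark-border artifacts.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening
from skimage.segmentation import watershed

from .losses import BBox

__all__ = [
    "LUMA_WEIGHTS",
    "to_gray",
    "median_filter",
    "laplacian_sharpen",
    "binarize_morph",
    "watershed_split",
    "crop_instances",
    "segment_scene",
]

LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luma grayscale with weights 0.299 / 0.587 / 0.114."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 image")
    return img @ np.asarray(LUMA_WEIGHTS)


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median of the window x window neighbourhood (reflect edges)."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    img = np.asarray(img, dtype=np.float64)
    if window == 1:
        return img.copy()
    return ndi.median_filter(img, size=window, mode="reflect")


def laplacian_sharpen(img: np.ndarray, strength: float = 1.0) -> np.ndarray:
    """out = clip(img - strength * laplacian(img), 0, 1).

    Uses the 4-neighbour Laplacian stencil; strength 0 is the identity.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    img = np.asarray(img, dtype=np.float64)
    lap = ndi.convolve(img, _LAPLACIAN, mode="reflect")
    return np.clip(img - strength * lap, 0.0, 1.0)


def binarize_morph(
    img: np.ndarray, open_radius: int = 2, close_radius: int = 2
) -> np.ndarray:
    """Otsu threshold followed by binary opening then closing with disks."""
    if open_radius < 0 or close_radius < 0:
        raise ValueError("morphology radii must be >= 0")
    img = np.asarray(img, dtype=np.float64)
    if np.ptp(img) == 0.0:
        raise ValueError("no foreground: image has zero variance")
    binary = img > threshold_otsu(img)
    if open_radius > 0:
        binary = opening(binary, disk(open_radius))
    if close_radius > 0:
        binary = closing(binary, disk(close_radius))
    return binary.astype(bool)


def watershed_split(binary: np.ndarray, min_marker_distance: int = 10) -> np.ndarray:
    """Split a foreground mask into instances via seeded watershed.

    Markers are local maxima of the (smoothed) Euclidean distance transform
    with a minimum separation of ``min_marker_distance`` — the smallest
    expected kernel radius.  The watershed floods the negated distance
    transform constrained to the foreground.  Labels are renumbered 1..K in
    raster order of first occurrence.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise ValueError("empty foreground")
    dist = ndi.distance_transform_edt(binary)
    components, n_components = ndi.label(binary)
    # smoothing collapses the flat ridge of an elongated ellipse to one peak
    smooth = ndi.gaussian_filter(dist, sigma=2.0)
    coords = peak_local_max(
        smooth,
        min_distance=max(1, int(min_marker_distance)),
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    seeded = set()
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
        seeded.add(int(components[r, c]))
    next_id = len(coords) + 1
    for comp in range(1, n_components + 1):  # never lose a component
        if comp not in seeded:
            flat = np.where(components == comp, dist, -1.0).argmax()
            markers.flat[flat] = next_id
            next_id += 1
    labels = watershed(-dist, markers, mask=binary)
    return _relabel_raster_order(labels)


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    flat = labels.ravel()
    values, first = np.unique(flat, return_index=True)
    order = [int(v) for _, v in sorted(zip(first, values)) if v != 0]
    mapping = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    for new, old in enumerate(order, start=1):
        mapping[old] = new
    return mapping[labels]


def crop_instances(
    img: np.ndarray, labels: np.ndarray, pad_px: int = 0
) -> list[tuple[np.ndarray, BBox, np.ndarray]]:
    """One (crop, frame-coordinate box, mask crop) per instance label.

    The box is the tight box of the instance mask grown by ``pad_px`` and
    clipped to the frame.
    """
    if pad_px < 0:
        raise ValueError("pad_px must be >= 0")
    img = np.asarray(img, dtype=np.float64)
    labels = np.asarray(labels)
    h, w = labels.shape
    out: list[tuple[np.ndarray, BBox, np.ndarray]] = []
    for k in range(1, int(labels.max()) + 1):
        mask = labels == k
        if not mask.any():
            continue
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        y0 = max(0, int(rows[0]) - pad_px)
        y1 = min(h, int(rows[-1]) + 1 + pad_px)
        x0 = max(0, int(cols[0]) - pad_px)
        x1 = min(w, int(cols[-1]) + 1 + pad_px)
        bbox = BBox(float(x0), float(y0), float(x1), float(y1))
        out.append((img[y0:y1, x0:x1].copy(), bbox, mask[y0:y1, x0:x1].copy()))
    return out


def segment_scene(
    img: np.ndarray,
    median_window: int = 3,
    sharpen_strength: float = 0.5,
    open_radius: int = 2,
    close_radius: int = 2,
    min_marker_distance: int = 10,
) -> np.ndarray:
    """Full chain from an RGB scene to an instance label map."""
    gray = to_gray(img)
    gray = median_filter(gray, median_window)
    gray = laplacian_sharpen(gray, sharpen_strength)
    binary = binarize_morph(gray, open_radius, close_radius)
    return watershed_split(binary, min_marker_distance)
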