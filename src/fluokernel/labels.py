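"""Label and image I/O: YOLO-txt and Pascal-VOC XML readers/writers.

YOLO-txt is the canonical internal format: one object per line, five
space-separated fields ``class_index x_center y_center width height``, all
normalized to [0, 1].  VOC XML stores pixel corner coordinates; both formats
round-trip through :class:`LabelRecord` losslessly to within 1e-6.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .losses import BBox

__all__ = [
    "YOLO_TXT",
    "VOC_XML",
    "CLASS_NAMES",
    "LabelRecord",
    "LabelFormatError",
    "read_labels",
    "write_labels",
    "read_image",
    "write_image",
    "read_label_map",
    "write_label_map",
    "resize_image",
]

YOLO_TXT = "yolo-txt"
VOC_XML = "voc-xml"
_FORMATS = (YOLO_TXT, VOC_XML)

#: Class order shared by the scene generator and both label formats.
CLASS_NAMES = ("mCherry-1", "DsRed-2", "Non-3")


class LabelFormatError(ValueError):
    """Raised for malformed or out-of-range label data."""


@dataclass(frozen=True)
class LabelRecord:
    """One labelled object in normalized centre format."""

    class_index: int
    x_center: float
    y_center: float
    width: float
    height: float
    source_format: str = YOLO_TXT

    def __post_init__(self) -> None:
        if self.class_index < 0:
            raise LabelFormatError(f"negative class index {self.class_index}")
        for name in ("x_center", "y_center", "width", "height"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise LabelFormatError(f"{name}={value} outside [0, 1]")

    def to_bbox(self, image_width: int, image_height: int) -> BBox:
        """Denormalize to pixel corner coordinates."""
        w = self.width * image_width
        h = self.height * image_height
        cx = self.x_center * image_width
        cy = self.y_center * image_height
        return BBox(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)

    @classmethod
    def from_bbox(
        cls,
        class_index: int,
        bbox: BBox,
        image_width: int,
        image_height: int,
        source_format: str = YOLO_TXT,
    ) -> "LabelRecord":
        cx, cy = bbox.center
        return cls(
            class_index=class_index,
            x_center=cx / image_width,
            y_center=cy / image_height,
            width=bbox.width / image_width,
            height=bbox.height / image_height,
            source_format=source_format,
        )


def _check_format(fmt: str) -> None:
    if fmt not in _FORMATS:
        raise LabelFormatError(f"unknown label format {fmt!r}; expected one of {_FORMATS}")


def read_labels(
    path: str | Path,
    format: str = YOLO_TXT,
    image_size: tuple[int, int] | None = None,
) -> list[LabelRecord]:
    """Read labels from ``path``.

    For VOC XML the image size stored in the file is used for normalization;
    ``image_size`` (width, height) overrides it if given.
    """
    _check_format(format)
    path = Path(path)
    if format == YOLO_TXT:
        return _read_yolo(path)
    return _read_voc(path, image_size)


def _read_yolo(path: Path) -> list[LabelRecord]:
    records: list[LabelRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 5:
            raise LabelFormatError(
                f"{path}:{lineno}: expected 5 fields, got {len(fields)}"
            )
        try:
            class_index = int(fields[0])
            values = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise LabelFormatError(f"{path}:{lineno}: {exc}") from exc
        try:
            records.append(
                LabelRecord(class_index, *values, source_format=YOLO_TXT)
            )
        except LabelFormatError as exc:
            raise LabelFormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def _read_voc(path: Path, image_size: tuple[int, int] | None) -> list[LabelRecord]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise LabelFormatError(f"{path}: malformed XML: {exc}") from exc
    if image_size is not None:
        width, height = image_size
    else:
        size = root.find("size")
        if size is None:
            raise LabelFormatError(f"{path}: missing <size> element")
        width = float(size.findtext("width", ""))
        height = float(size.findtext("height", ""))
    records: list[LabelRecord] = []
    for obj in root.iter("object"):
        name = obj.findtext("name", "")
        try:
            class_index = CLASS_NAMES.index(name)
        except ValueError:
            try:
                class_index = int(name)
            except ValueError as exc:
                raise LabelFormatError(f"{path}: unknown object name {name!r}") from exc
        box = obj.find("bndbox")
        if box is None:
            raise LabelFormatError(f"{path}: <object> without <bndbox>")
        try:
            coords = [float(box.findtext(tag, "")) for tag in ("xmin", "ymin", "xmax", "ymax")]
        except ValueError as exc:
            raise LabelFormatError(f"{path}: bad <bndbox> coordinates: {exc}") from exc
        bbox = BBox(*coords)
        records.append(
            LabelRecord.from_bbox(class_index, bbox, int(round(width)), int(round(height)),
                                  source_format=VOC_XML)
        )
    return records


def write_labels(
    records: Sequence[LabelRecord],
    path: str | Path,
    format: str = YOLO_TXT,
    image_size: tuple[int, int] = (640, 640),
) -> None:
    """Write ``records`` to ``path``; ``image_size`` is (width, height),
    required for the pixel-coordinate VOC format."""
    _check_format(format)
    path = Path(path)
    if format == YOLO_TXT:
        lines = [
            f"{r.class_index} {r.x_center:.6f} {r.y_center:.6f} "
            f"{r.width:.6f} {r.height:.6f}"
            for r in records
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return

    width, height = image_size
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = path.stem
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(width)
    ET.SubElement(size, "height").text = str(height)
    ET.SubElement(size, "depth").text = "3"
    for r in records:
        bbox = r.to_bbox(width, height)
        obj = ET.SubElement(root, "object")
        name = CLASS_NAMES[r.class_index] if r.class_index < len(CLASS_NAMES) else str(r.class_index)
        ET.SubElement(obj, "name").text = name
        box = ET.SubElement(obj, "bndbox")
        ET.SubElement(box, "xmin").text = f"{bbox.x_min:.6f}"
        ET.SubElement(box, "ymin").text = f"{bbox.y_min:.6f}"
        ET.SubElement(box, "xmax").text = f"{bbox.x_max:.6f}"
        ET.SubElement(box, "ymax").text = f"{bbox.y_max:.6f}"
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode")


# ---------------------------------------------------------------------------
# image I/O


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG into an H x W x 3 float array in [0, 1]."""
    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[-1] == 4:
        raw = raw[..., :3]
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    return np.clip(raw.astype(np.float64), 0.0, 1.0)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a float image in [0, 1] as 8-bit PNG/JPEG."""
    import imageio.v3 as iio

    data = np.clip(np.asarray(img), 0.0, 1.0)
    iio.imwrite(path, (data * 255.0 + 0.5).astype(np.uint8))


def read_label_map(path: str | Path) -> np.ndarray:
    """Read an instance label map stored as 16-bit PNG."""
    import imageio.v3 as iio

    return iio.imread(path).astype(np.int64)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map out of uint16 range")
    import imageio.v3 as iio

    iio.imwrite(path, labels.astype(np.uint16))


def resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize to ``size x size``; normalized labels are unaffected."""
    if size < 1:
        raise ValueError("size must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    if img.shape[0] == size and img.shape[1] == size:
        return img.copy()
    from skimage.transform import resize as _resize

    out = _resize(img, (size, size), order=1, mode="reflect",
                  anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)
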