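"""Image loading, cropping and annotated overlay rendering.

Every downstream module consumes the :class:`GrayImage` container defined
here: an 8-bit single-channel raster with a provenance label.  Colour
inputs are reduced to luminance on load.  Geometry is 0-based and
row-major throughout the package, with half-open rectangles
``[top, bottom) x [left, right)`` (row 0 is the top of the image).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from PIL import Image, ImageDraw, ImageOps, UnidentifiedImageError

from .errors import BoundsError, ConsistencyError, FormatError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .detection import DetectionResult

SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

#: BT.601 luminance weights used to collapse RGB to a single channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

# Overlay palette: detection status -> RGB outline colour.
STATUS_COLOURS = {
    "confident": (0, 190, 0),   # green: accepted as exactly one egg
    "uncertain": (220, 0, 0),   # red: flagged for human review
    "rejected": (0, 80, 230),   # blue: discarded as sub-egg noise
}


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle ``[top, bottom) x [left, right)``."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (0 <= self.top < self.bottom):
            raise BoundsError(
                f"invalid rectangle rows [{self.top}, {self.bottom})"
            )
        if not (0 <= self.left < self.right):
            raise BoundsError(
                f"invalid rectangle cols [{self.left}, {self.right})"
            )

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def area(self) -> int:
        """Bounding-box area in pixels (height x width)."""
        return self.height * self.width


@dataclass
class GrayImage:
    """A 2-D grid of 8-bit intensities plus a provenance label.

    ``pixels`` is a ``uint8`` array in row-major order; row 0 is the top
    of the image.  ``source_id`` records where the image came from (file
    name for loaded images, generator id for synthetic ones).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise FormatError(
                f"GrayImage requires a non-empty 2-D array, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            if not np.issubdtype(arr.dtype, np.integer):
                raise FormatError("GrayImage intensities must be integers")
            if arr.min() < 0 or arr.max() > 255:
                raise FormatError("GrayImage intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def full_frame(self) -> Rect:
        """The rectangle covering the whole image."""
        return Rect(0, 0, self.height, self.width)


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Collapse an H x W x 3 array to luminance, rounding half-up."""
    w = np.asarray(LUMA_WEIGHTS)
    luma = np.tensordot(rgb[..., :3].astype(float), w, axes=([-1], [0]))
    return _round_half_up(luma).astype(np.uint8)


def load_image(path: str | Path) -> GrayImage:
    """Load a raster image as grayscale.

    Colour inputs are converted by BT.601 luminance (0.299 R + 0.587 G +
    0.114 B, rounded half-up); single-channel inputs pass through
    unchanged.  EXIF orientation tags are honoured, then discarded.

    Raises
    ------
    FormatError
        If the file is missing, unreadable, or not PNG/TIFF/JPEG/BMP.
    """
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise FormatError(
            f"unsupported image format {path.suffix!r} for {path}; "
            f"expected one of {sorted(SUPPORTED_SUFFIXES)}"
        )
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            if im.mode == "L":
                arr = np.asarray(im, dtype=np.uint8)
            elif im.mode in ("1", "I", "I;16", "I;16B", "P", "LA"):
                arr = np.asarray(im.convert("L"), dtype=np.uint8)
            else:
                arr = rgb_to_gray(np.asarray(im.convert("RGB"), dtype=np.uint8))
    except FileNotFoundError as exc:
        raise FormatError(f"image file not found: {path}") from exc
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    return GrayImage(arr, source_id=path.name)


def trim(image: GrayImage, region: Rect) -> GrayImage:
    """Crop ``image`` to ``region`` (the explicit stand-in for trimming
    camera photographs to the substrate before counting).

    Returns a new image; the input is unchanged.
    """
    if region.bottom > image.height or region.right > image.width:
        raise BoundsError(
            f"crop region {region} exceeds image shape {image.shape}"
        )
    sub = image.pixels[region.top : region.bottom, region.left : region.right]
    return GrayImage(sub.copy(), source_id=image.source_id)


def _draw_box(rgb: np.ndarray, bbox: Rect, colour: tuple[int, int, int]) -> None:
    # 1-px outline on the border pixels of the half-open bbox
    t, l, b, r = bbox.top, bbox.left, bbox.bottom, bbox.right
    rgb[t, l:r] = colour
    rgb[b - 1, l:r] = colour
    rgb[t:b, l] = colour
    rgb[t:b, r - 1] = colour


def render_overlay(
    image: GrayImage, result: "DetectionResult", path: str | Path
) -> None:
    """Write an RGB PNG of ``image`` with detection boxes drawn on top.

    Confident objects are outlined green, uncertain red (labelled with
    their estimated count) and rejected blue.  The input image is never
    modified; with zero objects the output is the grayscale image
    rendered as RGB, pixel for pixel.
    """
    if result.image_shape is not None and tuple(result.image_shape) != image.shape:
        raise ConsistencyError(
            f"detection result shape {tuple(result.image_shape)} does not "
            f"match image shape {image.shape}"
        )
    rgb = np.repeat(image.pixels[:, :, None], 3, axis=2).copy()
    labelled: list[tuple[Rect, int]] = []
    for obj in result.objects:
        _draw_box(rgb, obj.bbox, STATUS_COLOURS[obj.status])
        if obj.status == "uncertain":
            labelled.append((obj.bbox, obj.estimated_count))
    im = Image.fromarray(rgb, mode="RGB")
    if labelled:
        draw = ImageDraw.Draw(im)
        for bbox, count in labelled:
            draw.text(
                (bbox.left + 2, max(0, bbox.top - 12)),
                str(count),
                fill=STATUS_COLOURS["uncertain"],
            )
    try:
        im.save(Path(path), format="PNG")
    except OSError as exc:
        raise FormatError(f"cannot write overlay to {path}: {exc}") from exc
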