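"""Core egg-counting pipeline: binarize, label, filter by box area, count.

The method is deliberately simple and matches what laboratory users tune
by eye: a global black/white threshold separates dark eggs from the
light substrate, connected foreground components become candidate
objects, and each object's *bounding-box* area decides its fate:

* below ``min_box_area``  -> rejected (noise, debris),
* within ``[min_box_area, max_box_area]`` -> confident single egg,
* above ``max_box_area``  -> uncertain (overlapping eggs merged into one
  object), with an egg count estimated from the ratio of the object's
  *pixel* area to a per-image single-egg reference area.

Uncertain and rejected objects are the ones a human reviews in the
semi-automatic workflow (:mod:`icount.review`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .imagery import GrayImage, Rect

MODES = ("micro", "macro", "raft")

#: Default parameters: BW threshold 80, box-area band [800, 1400] px.
DEFAULT_BW_THRESHOLD = 80
DEFAULT_MIN_BOX_AREA = 800
DEFAULT_MAX_BOX_AREA = 1400

#: Fill fraction of a rotated ellipse in its bounding box, used for the
#: fallback single-egg reference area when an image has no confident
#: object (between pi/4 for axis-aligned and lower when rotated).
FALLBACK_FILL_FRACTION = 0.7

OBJECTS_HEADER = [
    "image_id", "object_id", "top", "left", "bottom", "right",
    "box_area", "pixel_area", "status", "estimated_count",
]
SUMMARY_HEADER = [
    "image_id", "n_confident", "n_uncertain", "n_rejected",
    "reference_area", "total_estimate",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the counting algorithm.

    ``bw_threshold`` is the grayscale cut-off in [0, 255]: pixels
    strictly darker are foreground.  ``min_box_area``/``max_box_area``
    bracket the bounding-box area (px) of a single egg.  ``connectivity``
    is 4 or 8 (8 merges diagonally touching eggs, so they get flagged).
    ``mode`` selects the counting strategy: ``micro`` (per-object
    counting with cluster splitting), ``macro`` (histogram estimate for
    whole-strip photographs) or ``raft`` (every large object counts as
    one, for floating egg rafts).
    """

    bw_threshold: int = DEFAULT_BW_THRESHOLD
    min_box_area: int = DEFAULT_MIN_BOX_AREA
    max_box_area: int = DEFAULT_MAX_BOX_AREA
    connectivity: int = 8
    mode: str = "micro"

    def __post_init__(self) -> None:
        if not (0 <= self.bw_threshold <= 255):
            raise ParameterError(
                f"bw_threshold must be in [0, 255], got {self.bw_threshold}"
            )
        if not (0 < self.min_box_area < self.max_box_area):
            raise ParameterError(
                "box-area band must satisfy 0 < min < max, got "
                f"[{self.min_box_area}, {self.max_box_area}]"
            )
        if self.connectivity not in (4, 8):
            raise ParameterError(
                f"connectivity must be 4 or 8, got {self.connectivity}"
            )
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class Component:
    """One maximal connected foreground component."""

    bbox: Rect
    pixel_area: int


@dataclass
class DetectedObject:
    """A classified component with its estimated egg count."""

    object_id: int
    bbox: Rect
    pixel_area: int
    status: str  # confident | uncertain | rejected
    estimated_count: int
    corrected: bool = False  # True once a reviewer overrode the count

    @property
    def box_area(self) -> int:
        return self.bbox.area


@dataclass
class DetectionResult:
    """All objects of one image plus the total estimate.

    ``labels`` (optional) is the relabelled component map in which pixel
    value equals ``object_id``; it is kept in memory for ground-truth
    matching and overlay work but never serialised to CSV.
    """

    image_id: str
    params: DetectionParams
    objects: list[DetectedObject]
    total_estimate: int
    reference_area: int
    image_shape: tuple[int, int] | None = None
    labels: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_confident(self) -> int:
        return sum(o.status == "confident" for o in self.objects)

    @property
    def n_uncertain(self) -> int:
        return sum(o.status == "uncertain" for o in self.objects)

    @property
    def n_rejected(self) -> int:
        return sum(o.status == "rejected" for o in self.objects)


def binarize(image: GrayImage, bw_threshold: int) -> np.ndarray:
    """Foreground mask: True exactly where intensity < ``bw_threshold``.

    Eggs are dark on a light substrate, so foreground is *below* the
    threshold; a threshold of 0 yields an empty mask.
    """
    if not (0 <= bw_threshold <= 255):
        raise ParameterError(
            f"bw_threshold must be in [0, 255], got {bw_threshold}"
        )
    return image.pixels < bw_threshold


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")


def label_components(
    mask: np.ndarray, connectivity: int = 8
) -> tuple[list[Component], np.ndarray]:
    """Partition foreground pixels into maximal connected components.

    Returns the components sorted by the (top, left) corner of their
    bounding boxes — a fixed scan order so object ids are reproducible —
    together with a relabelled int array in which component ``i`` (1-based
    position in the returned list) has pixel value ``i``.
    """
    raw, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return [], np.zeros_like(raw)
    slices = ndimage.find_objects(raw)
    counts = np.bincount(raw.ravel(), minlength=n + 1)
    order = sorted(
        range(1, n + 1),
        key=lambda lab: (slices[lab - 1][0].start, slices[lab - 1][1].start),
    )
    remap = np.zeros(n + 1, dtype=raw.dtype)
    components: list[Component] = []
    for new_id, lab in enumerate(order, start=1):
        remap[lab] = new_id
        rs, cs = slices[lab - 1]
        components.append(
            Component(
                bbox=Rect(rs.start, cs.start, rs.stop, cs.stop),
                pixel_area=int(counts[lab]),
            )
        )
    return components, remap[raw]


def classify_objects(
    components: Sequence[Component], params: DetectionParams
) -> list[DetectedObject]:
    """Assign confident/uncertain/rejected status by bounding-box area.

    Uncertain objects receive a provisional count of 1; the final value
    comes from :func:`estimate_cluster`.
    """
    objects = []
    for i, comp in enumerate(components, start=1):
        area = comp.bbox.area
        if area < params.min_box_area:
            status, count = "rejected", 0
        elif area <= params.max_box_area:
            status, count = "confident", 1
        else:
            status, count = "uncertain", 1
        objects.append(
            DetectedObject(
                object_id=i,
                bbox=comp.bbox,
                pixel_area=comp.pixel_area,
                status=status,
                estimated_count=count,
            )
        )
    return objects


def reference_egg_area(
    objects: Sequence[DetectedObject], params: DetectionParams
) -> int:
    """Per-image single-egg reference area in pixels.

    The median pixel area of the image's confident objects; when the
    image has none, fall back to ``FALLBACK_FILL_FRACTION`` times the
    midpoint of the box-area band.  Per-image (not global) so
    magnification differences between images self-calibrate.
    """
    areas = [o.pixel_area for o in objects if o.status == "confident"]
    if areas:
        return round_half_up(float(np.median(areas)))
    midpoint = (params.min_box_area + params.max_box_area) / 2.0
    return round_half_up(FALLBACK_FILL_FRACTION * midpoint)


def estimate_cluster(obj: DetectedObject, reference_area: int) -> int:
    """Estimated egg count of a merged (uncertain) object.

    The ratio of the object's pixel area to the single-egg reference,
    rounded half-up with a floor of 1 — the same total-area over
    average-area logic particle-analysis workflows use for clumps.
    """
    if reference_area <= 0:
        raise ParameterError(
            f"reference_area must be positive, got {reference_area}"
        )
    return max(1, round_half_up(obj.pixel_area / reference_area))


def count_eggs(image: GrayImage, params: DetectionParams | None = None) -> DetectionResult:
    """Full automatic pipeline on one image.

    binarize -> label -> classify by box area -> per-image reference ->
    cluster estimates for uncertain objects.  Deterministic for fixed
    inputs.
    """
    params = params or DetectionParams()
    mask = binarize(image, params.bw_threshold)
    components, labels = label_components(mask, params.connectivity)
    objects = classify_objects(components, params)
    ref = reference_egg_area(objects, params)
    for obj in objects:
        if obj.status == "uncertain":
            obj.estimated_count = estimate_cluster(obj, ref)
    total = sum(o.estimated_count for o in objects)
    return DetectionResult(
        image_id=image.source_id,
        params=params,
        objects=objects,
        total_estimate=total,
        reference_area=ref,
        image_shape=image.shape,
        labels=labels,
    )


def estimate_by_histogram(
    image: GrayImage, params: DetectionParams, reference_area: int
) -> int:
    """Whole-image estimate for macro photographs.

    Total foreground pixel count at the threshold divided by the
    single-egg reference area, rounded half-up; no component labelling.
    Cheap and robust at strip scale, at the price of per-object detail.
    """
    if reference_area <= 0:
        raise ParameterError(
            f"reference_area must be positive, got {reference_area}"
        )
    foreground = int(binarize(image, params.bw_threshold).sum())
    return round_half_up(foreground / reference_area)


def count_rafts(image: GrayImage, params: DetectionParams) -> DetectionResult:
    """Count floating egg rafts: one per sufficiently large object.

    Culex-style rafts cannot be split into individual eggs, so there is
    no cluster estimation: every component with box area >= min counts
    as exactly one (confident regardless of ``max_box_area``); smaller
    components are rejected.
    """
    if params.mode != "raft":
        raise ParameterError("count_rafts requires params.mode == 'raft'")
    mask = binarize(image, params.bw_threshold)
    components, labels = label_components(mask, params.connectivity)
    objects = []
    for i, comp in enumerate(components, start=1):
        if comp.bbox.area < params.min_box_area:
            status, count = "rejected", 0
        else:
            status, count = "confident", 1
        objects.append(
            DetectedObject(
                object_id=i,
                bbox=comp.bbox,
                pixel_area=comp.pixel_area,
                status=status,
                estimated_count=count,
            )
        )
    ref = reference_egg_area(objects, params)
    return DetectionResult(
        image_id=image.source_id,
        params=params,
        objects=objects,
        total_estimate=sum(o.estimated_count for o in objects),
        reference_area=ref,
        image_shape=image.shape,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# CSV serialisation


def write_objects_csv(results: Iterable[DetectionResult], path: str | Path) -> None:
    """One row per detected object across a batch of images."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(OBJECTS_HEADER)
        for res in results:
            for o in res.objects:
                writer.writerow([
                    res.image_id, o.object_id,
                    o.bbox.top, o.bbox.left, o.bbox.bottom, o.bbox.right,
                    o.box_area, o.pixel_area, o.status, o.estimated_count,
                ])


def write_summary_csv(results: Iterable[DetectionResult], path: str | Path) -> None:
    """One row per image: status tallies, reference area, total."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_HEADER)
        for res in results:
            writer.writerow([
                res.image_id, res.n_confident, res.n_uncertain,
                res.n_rejected, res.reference_area, res.total_estimate,
            ])


def read_objects_csv(
    path: str | Path, params: DetectionParams | None = None
) -> list[DetectionResult]:
    """Reconstruct per-image results from an objects CSV.

    ``labels`` maps and image shapes are not stored in CSV, so the
    reconstructed results carry neither; totals are recomputed from the
    rows and ``reference_area`` is set to 0 (unknown).
    """
    params = params or DetectionParams()
    per_image: dict[str, list[DetectedObject]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            obj = DetectedObject(
                object_id=int(row["object_id"]),
                bbox=Rect(int(row["top"]), int(row["left"]),
                          int(row["bottom"]), int(row["right"])),
                pixel_area=int(row["pixel_area"]),
                status=row["status"],
                estimated_count=int(row["estimated_count"]),
            )
            per_image.setdefault(row["image_id"], []).append(obj)
    results = []
    for image_id, objects in per_image.items():
        results.append(
            DetectionResult(
                image_id=image_id,
                params=params,
                objects=objects,
                total_estimate=sum(o.estimated_count for o in objects),
                reference_area=0,
            )
        )
    return results
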