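"""Seeded generator of synthetic oviposition-strip images with ground truth.

The generator emulates the imaging regime the counting algorithm is
designed for: a light, noisy substrate (sandpaper) bearing dark
ellipsoidal eggs with sharp contrast.  Eggs are filled rotated ellipses
with per-pixel Gaussian intensity; a controllable fraction is laid in
clusters of 2–4 touching eggs, the rest isolated with a minimum gap.

Cluster members are offset from their seed egg along the ellipse's
*minor*-axis direction with centre separation of 0.8–0.9 minor axes by
default.  This guarantees two things at default egg sizes: the members
overlap (so they merge into one connected object, like real
superimposed eggs) and the merged bounding box exceeds the default
``max_box_area``, so every synthetic merge is flagged for review rather
than silently miscounted.  Tightening ``cluster_sep_range`` emulates
genuinely superimposed eggs: heavily overlapping pairs can stay inside
the single-egg box band and are then silently undercounted — the
failure mode that dominates crowded strips.

Everything is deterministic given the spec's seed, and the ground truth
records every placement exactly — the synthetic stand-in for a manual
reference count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .detection import DetectionResult, round_half_up
from .errors import CapacityError, ParameterError
from .imagery import GrayImage

MANIFEST_HEADER = ["image_id", "image_path", "truth_path", "seed",
                   "n_eggs", "cluster_fraction"]
TRUTH_HEADER = ["image_id", "record", "row", "col", "orientation",
                "object_index", "egg_count"]

#: Relative centre separation (in minor axes) of touching cluster members.
CLUSTER_SEP_RANGE = (0.8, 0.9)


@dataclass(frozen=True)
class StripSpec:
    """Recipe for one synthetic strip image.

    Defaults describe a microscope snapshot of a sandpaper strip at a
    magnification where one egg's bounding box falls inside the default
    [800, 1400] px² acceptance band: 44 x 22 px ellipse axes (±5 %
    jitter), substrate intensity 200 ± 10, egg intensity 30 ± 10 — well
    separated by the default threshold of 80.
    """

    height: int = 1000
    width: int = 1400
    n_eggs: int = 50
    egg_major_axis: float = 44.0
    egg_minor_axis: float = 22.0
    axis_jitter: float = 0.05
    bg_mean: float = 200.0
    bg_sd: float = 10.0
    egg_mean: float = 30.0
    egg_sd: float = 10.0
    cluster_fraction: float = 0.0
    cluster_sep_range: tuple[float, float] = CLUSTER_SEP_RANGE
    min_gap: int = 6
    seed: int = 0
    image_id: str = ""
    max_attempts: int = 10000

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ParameterError("strip must be at least 1 x 1 px")
        if self.n_eggs < 0:
            raise ParameterError("n_eggs must be >= 0")
        if self.egg_minor_axis < 2 or self.egg_major_axis < self.egg_minor_axis:
            raise ParameterError(
                "egg axes must satisfy major >= minor >= 2 px"
            )
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ParameterError("cluster_fraction must lie in [0, 1]")
        lo, hi = self.cluster_sep_range
        if not (0.2 <= lo <= hi <= 0.98):
            raise ParameterError(
                "cluster_sep_range must satisfy 0.2 <= low <= high <= 0.98 "
                "(fractions of the minor axis; members must overlap)"
            )
        if self.min_gap < 2:
            raise ParameterError(
                "min_gap must be >= 2 px so separate placements stay "
                "disconnected under 8-connectivity"
            )
        if not self.egg_mean + 2 * self.egg_sd < self.bg_mean - 2 * self.bg_sd:
            raise ParameterError(
                "egg and background intensity distributions overlap: need "
                "egg_mean + 2*egg_sd < bg_mean - 2*bg_sd for dark-on-light "
                "separability"
            )
        if not self.image_id:
            object.__setattr__(self, "image_id", f"strip-{self.seed}")


#: Named starting points for common imaging conditions.
PRESETS: dict[str, dict] = {
    # part of a strip under the microscope; moderate crowding
    "micro": {"height": 1000, "width": 1400, "n_eggs": 60,
              "cluster_fraction": 0.05},
    # whole-strip camera photograph: wider field, many more eggs
    "macro": {"height": 900, "width": 2600, "n_eggs": 250,
              "cluster_fraction": 0.05},
    # crowded strip where overlap errors dominate
    "dense": {"height": 1000, "width": 1400, "n_eggs": 140,
              "cluster_fraction": 0.3},
}


@dataclass
class GroundTruth:
    """Exact record of every egg placed on a synthetic strip.

    ``egg_centers`` holds (row, col, orientation) per egg.
    ``object_truth`` maps each expected connected object (in the same
    top-to-bottom, left-to-right bbox order the detector uses) to the
    number of eggs it contains.
    """

    image_id: str
    egg_centers: list[tuple[float, float, float]]
    object_truth: list[tuple[int, int]]
    total_eggs: int


def _ellipse_mask(
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    theta: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray] | None:
    """Pixel coordinates of a filled rotated ellipse, or None if clipped.

    ``theta`` is the angle of the major axis; its unit vector in
    (row, col) coordinates is (sin θ, cos θ).
    """
    r0, c0 = center
    extent = semi_major + 1.0
    top = int(np.floor(r0 - extent))
    bottom = int(np.ceil(r0 + extent)) + 1
    left = int(np.floor(c0 - extent))
    right = int(np.ceil(c0 + extent)) + 1
    if top < 0 or left < 0 or bottom > shape[0] or right > shape[1]:
        return None
    rr, cc = np.mgrid[top:bottom, left:right]
    dr = rr - r0
    dc = cc - c0
    u = dc * np.cos(theta) + dr * np.sin(theta)      # along major axis
    v = -dc * np.sin(theta) + dr * np.cos(theta)     # along minor axis
    inside = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _disk(radius: int) -> np.ndarray:
    span = np.arange(-radius, radius + 1)
    return (span[:, None] ** 2 + span[None, :] ** 2) <= radius**2


def _plan_group_sizes(spec: StripSpec, rng: np.random.Generator) -> list[int]:
    """Split n_eggs into isolated placements (size 1) and clusters (2–4)."""
    n_isolated = round_half_up(spec.n_eggs * (1.0 - spec.cluster_fraction))
    remaining = spec.n_eggs - n_isolated
    sizes = [1] * n_isolated
    while remaining > 0:
        if remaining == 1:
            sizes.append(1)  # a lone leftover cannot form a cluster
            break
        size = int(rng.integers(2, min(4, remaining) + 1))
        if remaining - size == 1:  # avoid stranding a single egg
            size = size + 1 if size < 4 and size + 1 <= remaining else size - 1
        sizes.append(size)
        remaining -= size
    return sizes


def generate_strip(spec: StripSpec) -> tuple[GrayImage, GroundTruth]:
    """Render one synthetic strip and its exact ground truth.

    Placement is rejection sampling against an occupancy mask dilated by
    ``min_gap``, so distinct placements (isolated eggs or whole
    clusters) never touch or merge by accident.  Deterministic for a
    fixed spec: same seed, bit-identical image.

    Raises
    ------
    CapacityError
        If a placement cannot be found within ``max_attempts`` tries —
        the strip is too small for ``n_eggs`` at the requested gap.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    occupancy = np.zeros(shape, dtype=bool)
    gap_disk = _disk(spec.min_gap)

    group_sizes = _plan_group_sizes(spec, rng)
    groups: list[dict] = []  # rows, cols, centers, size per placed group

    for size in group_sizes:
        placed = False
        for _ in range(spec.max_attempts):
            theta = float(rng.uniform(0.0, np.pi))
            jit = rng.uniform(1 - spec.axis_jitter, 1 + spec.axis_jitter, (size, 2))
            r0 = float(rng.uniform(0, spec.height))
            c0 = float(rng.uniform(0, spec.width))
            # members strung along the minor-axis direction so the merged
            # bounding box always exceeds the single-egg band
            minor_dir = np.array([np.cos(theta), -np.sin(theta)])
            seps = rng.uniform(*spec.cluster_sep_range, size) * spec.egg_minor_axis
            offsets = np.concatenate([[0.0], np.cumsum(seps[1:])])
            members = []
            ok = True
            for k in range(size):
                center = (r0 + offsets[k] * minor_dir[0],
                          c0 + offsets[k] * minor_dir[1])
                px = _ellipse_mask(
                    center,
                    spec.egg_major_axis / 2 * jit[k, 0],
                    spec.egg_minor_axis / 2 * jit[k, 1],
                    theta, shape,
                )
                if px is None:
                    ok = False
                    break
                members.append((center, px))
            if not ok:
                continue
            rows = np.concatenate([px[0] for _, px in members])
            cols = np.concatenate([px[1] for _, px in members])
            # dilate the group's footprint locally by min_gap and test it
            # against the occupancy of everything placed so far
            g = spec.min_gap
            t0, b0 = int(rows.min()), int(rows.max()) + 1
            l0, r0 = int(cols.min()), int(cols.max()) + 1
            local = np.zeros((b0 - t0 + 2 * g, r0 - l0 + 2 * g), dtype=bool)
            local[rows - t0 + g, cols - l0 + g] = True
            dilated = ndimage.binary_dilation(local, structure=gap_disk)
            # overlap of the dilated window with the image
            T, B = max(t0 - g, 0), min(b0 + g, spec.height)
            L, R = max(l0 - g, 0), min(r0 + g, spec.width)
            dt, dl = T - (t0 - g), L - (l0 - g)
            if np.any(
                dilated[dt : dt + (B - T), dl : dl + (R - L)]
                & occupancy[T:B, L:R]
            ):
                continue
            occupancy[rows, cols] = True
            groups.append({
                "members": members,
                "theta": theta,
                "size": size,
                "bbox_key": (int(rows.min()), int(cols.min())),
            })
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place a group of {size} egg(s) on a "
                f"{spec.height}x{spec.width} strip after {spec.max_attempts} "
                f"attempts (n_eggs={spec.n_eggs}, min_gap={spec.min_gap})"
            )

    # paint: substrate noise first, then each egg's own intensity field
    canvas = rng.normal(spec.bg_mean, spec.bg_sd, shape)
    egg_centers: list[tuple[float, float, float]] = []
    for grp in groups:
        for (center, (rows, cols)) in grp["members"]:
            canvas[rows, cols] = rng.normal(spec.egg_mean, spec.egg_sd, rows.size)
            egg_centers.append((center[0], center[1], grp["theta"]))
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    order = sorted(range(len(groups)), key=lambda i: groups[i]["bbox_key"])
    object_truth = [(idx + 1, groups[i]["size"]) for idx, i in enumerate(order)]

    truth = GroundTruth(
        image_id=spec.image_id,
        egg_centers=egg_centers,
        object_truth=object_truth,
        total_eggs=spec.n_eggs,
    )
    return GrayImage(pixels, source_id=spec.image_id), truth


def truth_counts_for_result(
    result: DetectionResult, truth: GroundTruth
) -> dict[int, int]:
    """Map each detected object_id to the true number of eggs inside it.

    Uses the detector's label map: each recorded egg centre lands on the
    component that swallowed it.  Requires ``result.labels`` (i.e. a
    result fresh from ``count_eggs``, not one reloaded from CSV).
    """
    if result.labels is None:
        raise ParameterError(
            "result carries no label map; run count_eggs on the image"
        )
    labels = result.labels
    counts: dict[int, int] = {}
    for r, c, _ in truth.egg_centers:
        rr, cc = int(round(r)), int(round(c))
        lab = int(labels[rr, cc])
        if lab == 0:
            # centre pixel flipped by noise: take the modal label nearby
            window = labels[max(0, rr - 2): rr + 3, max(0, cc - 2): cc + 3]
            nz = window[window > 0]
            if nz.size == 0:
                continue
            lab = int(np.bincount(nz).argmax())
        counts[lab] = counts.get(lab, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Dataset serialisation


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRUTH_HEADER)
        for r, c, theta in truth.egg_centers:
            writer.writerow([truth.image_id, "egg", f"{r:.3f}", f"{c:.3f}",
                             f"{theta:.6f}", "", ""])
        for idx, count in truth.object_truth:
            writer.writerow([truth.image_id, "object", "", "", "", idx, count])


def read_ground_truth(path: str | Path) -> GroundTruth:
    centers: list[tuple[float, float, float]] = []
    objects: list[tuple[int, int]] = []
    image_id = ""
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            image_id = row["image_id"]
            if row["record"] == "egg":
                centers.append(
                    (float(row["row"]), float(row["col"]),
                     float(row["orientation"]))
                )
            elif row["record"] == "object":
                objects.append((int(row["object_index"]), int(row["egg_count"])))
    return GroundTruth(
        image_id=image_id,
        egg_centers=centers,
        object_truth=objects,
        total_eggs=len(centers),
    )


def generate_dataset(
    specs: Sequence[StripSpec], out_dir: str | Path
) -> pd.DataFrame:
    """Write one PNG + one ground-truth CSV per spec, plus a manifest.

    Re-running with identical specs reproduces byte-identical files.
    Returns the manifest as a DataFrame (also written to
    ``manifest.csv`` in ``out_dir``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in specs:
        image, truth = generate_strip(spec)
        image_path = out_dir / f"{spec.image_id}.png"
        truth_path = out_dir / f"{spec.image_id}_truth.csv"
        Image.fromarray(image.pixels, mode="L").save(image_path, format="PNG")
        write_ground_truth(truth, truth_path)
        rows.append({
            "image_id": spec.image_id,
            "image_path": image_path.name,
            "truth_path": truth_path.name,
            "seed": spec.seed,
            "n_eggs": spec.n_eggs,
            "cluster_fraction": spec.cluster_fraction,
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_HEADER)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def spec_from_preset(preset: str, **overrides) -> StripSpec:
    """Build a StripSpec from a named preset plus overrides."""
    if preset not in PRESETS:
        raise ParameterError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return StripSpec(**kwargs)
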