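import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icount import DetectionParams, GrayImage

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def default_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def blank_image() -> GrayImage:
    """A pure-white 120x160 image with no eggs."""
    return GrayImage(np.full((120, 160), 255, dtype=np.uint8), source_id="blank")


def make_blob_image(
    shape: tuple[int, int],
    blobs: list[tuple[int, int, int, int]],
    bg: int = 255,
    fg: int = 0,
) -> GrayImage:
    """Light background with dark filled rectangles (top, left, h, w)."""
    arr = np.full(shape, bg, dtype=np.uint8)
    for top, left, h, w in blobs:
        arr[top : top + h, left : left + w] = fg
    return GrayImage(arr, source_id="blobs")


def flood_fill_components(mask: np.ndarray, connectivity: int) -> set[frozenset]:
    """Brute-force connected components via explicit stack-based flood
    fill — the independent oracle for the labelling routine."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = set()
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            stack, comp = [(r, c)], set()
            seen[r, c] = True
            while stack:
                cr, cc = stack.pop()
                comp.add((cr, cc))
                for dr, dc in nbrs:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                            and not seen[nr, nc]:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            comps.add(frozenset(comp))
    return comps


def components_from_labels(labels: np.ndarray) -> set[frozenset]:
    comps = set()
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        comps.add(frozenset(zip(rows.tolist(), cols.tolist())))
    return comps
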