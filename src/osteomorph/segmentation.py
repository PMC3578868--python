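"""Binarization chain: background flattening, open-close smoothing,
count-calibrated global thresholding, particle deletion, labeling.

The chain mirrors routine phase-contrast morphometry practice: a single
brightness threshold is calibrated once per dataset by minimizing the
disagreement between post-cleanup object counts and reference (manually
determined, here ground-truth) cell counts on ~20 calibration images, then
applied to every image of the run.

Background removal uses grey-opening estimate subtraction (a morphological
rolling-ball analogue): the opening window is larger than any cell's minor
footprint, so cells are erased from the background estimate while slow
illumination trends survive and are subtracted.  Foreground polarity is
bright-on-dark by default; ``invert`` handles dark-on-bright inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .config import SegmentationConfig

__all__ = [
    "ObjectRegion", "LabeledObjectSet", "preprocess", "binarize",
    "optimize_threshold", "extract_objects", "segment_field",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass(frozen=True)
class ObjectRegion:
    """One labeled connected component: its label, bbox slices and crop mask."""

    label: int
    slices: tuple[slice, slice]
    mask: np.ndarray  # bool crop, True where this object

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class LabeledObjectSet:
    """Per-field segmentation result with contiguous labels 1..N."""

    labels: np.ndarray
    objects: list[ObjectRegion]
    source: str = ""

    def __len__(self) -> int:
        return len(self.objects)


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy ** 2 + xx ** 2) <= radius ** 2


def preprocess(image: np.ndarray, params: SegmentationConfig | None = None) -> np.ndarray:
    """Flatten the background and smooth with grayscale open-close.

    The background estimate is a grey opening with a square window of side
    ``background_kernel`` (separable, fast); subtracting it removes
    illumination gradients while leaving compact bright objects.  The result
    is then smoothed by a grayscale opening followed by closing with small
    disk footprints.  Output is float64, same shape, >= 0.
    """
    params = params or SegmentationConfig()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("preprocess expects a non-empty 2-D grayscale image")
    if params.invert:
        img = img.max() - img
    k = int(params.background_kernel)
    background = ndi.grey_opening(img, size=(k, k))
    flat = img - background
    if params.open_radius > 0:
        flat = ndi.grey_opening(flat, footprint=_disk(params.open_radius))
    if params.close_radius > 0:
        flat = ndi.grey_closing(flat, footprint=_disk(params.close_radius))
    return np.clip(flat, 0.0, None)


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground = pixels with intensity >= threshold (bright-on-dark)."""
    return np.asarray(image) >= threshold


def extract_objects(binary: np.ndarray, params: SegmentationConfig | None = None,
                    source: str = "") -> LabeledObjectSet:
    """Label 8-connected components and delete sub-size particles.

    Components with area < ``min_particle_area`` are removed; survivors are
    relabeled 1..N in raster-scan order.  Border-touching objects are kept.
    """
    params = params or SegmentationConfig()
    raw, n = ndi.label(np.asarray(binary, dtype=bool), structure=_EIGHT)
    if n == 0:
        return LabeledObjectSet(raw.astype(np.int32), [], source)
    areas = np.bincount(raw.ravel())[1:]
    keep = np.flatnonzero(areas >= params.min_particle_area) + 1
    mapping = np.zeros(n + 1, dtype=np.int32)
    mapping[keep] = np.arange(1, len(keep) + 1)
    labels = mapping[raw]
    objects: list[ObjectRegion] = []
    slices = ndi.find_objects(labels)
    for new_label, sl in enumerate(slices, start=1):
        mask = labels[sl] == new_label
        objects.append(ObjectRegion(new_label, sl, mask))
    return LabeledObjectSet(labels, objects, source)


def optimize_threshold(calibration: Sequence[tuple[np.ndarray, int]],
                       grid: Sequence[float],
                       params: SegmentationConfig | None = None) -> float:
    """Count-calibrated global threshold.

    For every grid level, binarize each (already preprocessed) calibration
    image, delete particles, and count objects; return the level minimizing
    the total absolute count error against the reference counts.  Ties go to
    the lower threshold.
    """
    params = params or SegmentationConfig()
    if len(calibration) == 0:
        raise ValueError("optimize_threshold requires at least one calibration pair")
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    best_thr, best_err = grid[0], None
    for thr in grid:
        err = 0
        for img, ref in calibration:
            n = len(extract_objects(binarize(img, thr), params))
            err += abs(n - int(ref))
        if best_err is None or err < best_err:
            best_thr, best_err = thr, err
    return best_thr


def segment_field(image: np.ndarray, threshold: float,
                  params: SegmentationConfig | None = None,
                  source: str = "") -> LabeledObjectSet:
    """preprocess -> binarize -> particle deletion -> labels, in one call."""
    pre = preprocess(image, params)
    return extract_objects(binarize(pre, threshold), params, source)


def default_threshold_grid(params: SegmentationConfig) -> np.ndarray:
    lo, hi, step = params.threshold_grid
    return np.arange(lo, hi + step / 2, step)
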