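"""Frame-differencing (Delta) segmentation.

The core idea: pixels whose intensity does not change between consecutive
frames belong to the static background; a growing or moving spheroid leaves
a band of changed pixels at its advancing edge. Subtracting consecutive
frames therefore removes the background — including bright halo artifacts
and dust that defeat direct thresholding of phase-contrast images — and the
difference image can be thresholded at a single native intensity unit.

The absolute difference is used: subtraction of unsigned frames is
ill-defined for negative changes, and a spheroid edge both brightens (phase
halo) and darkens (body) as it advances, so both signs mark motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.measure import label

from .io_plate import FrameSeries


@dataclass
class DeltaImage:
    """Absolute intensity difference between two consecutive frames.

    ``assigned_timepoint`` is the *later* frame's timepoint: the mask derived
    from a Delta describes where the spheroid is now.
    """

    values: np.ndarray
    assigned_timepoint: int
    smoothing_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("DeltaImage values must be 2-D")
        if (self.values < 0).any():
            raise ValueError("DeltaImage values must be non-negative")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the Delta segmentation pipeline.

    ``threshold`` is in native intensity units; the default of 1 classifies
    any nonzero integer change as motion (difference 0 = background).
    ``expansion_radius`` dilates surviving components to recover the full
    spheroid footprint from its thin motion band.
    """

    threshold: float = 1.0
    smoothing_sigma: float = 1.0
    expansion_radius: int = 5
    min_object_area: int = 50
    keep: Literal["largest_object", "all_objects"] = "largest_object"
    intensity_guard_multiple: float = 10.0

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1 native intensity unit")
        if self.expansion_radius < 0:
            raise ValueError("expansion_radius must be >= 0")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")
        if self.keep not in ("largest_object", "all_objects"):
            raise ValueError(f"unknown keep mode {self.keep!r}")


@dataclass
class SpheroidMask:
    """Binary segmentation of one timepoint, with centroid and provenance."""

    mask: np.ndarray
    timepoint: int
    centroid: tuple[float, float] | None
    area_px: int
    empty: bool
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if int(self.mask.sum()) != self.area_px:
            raise ValueError("area_px must equal the mask's true-pixel count")
        if self.empty != (self.area_px == 0):
            raise ValueError("empty flag inconsistent with mask content")
        if (self.centroid is None) != self.empty:
            raise ValueError("centroid must be defined iff mask is non-empty")


def compute_delta(
    frame_prev: np.ndarray, frame_next: np.ndarray, smoothing_sigma: float = 0.0
) -> DeltaImage:
    """Pixel-wise absolute difference of two frames, optionally pre-smoothed.

    Frames are widened to float before subtraction so unsigned wraparound
    cannot occur. Symmetric in its two frame arguments.
    """
    a = np.asarray(frame_prev)
    b = np.asarray(frame_next)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")
    af = a.astype(np.float64)
    bf = b.astype(np.float64)
    if smoothing_sigma > 0:
        af = ndimage.gaussian_filter(af, smoothing_sigma)
        bf = ndimage.gaussian_filter(bf, smoothing_sigma)
    return DeltaImage(np.abs(bf - af), assigned_timepoint=0, smoothing_sigma=smoothing_sigma)


def threshold_delta(delta: DeltaImage, threshold: float = 1.0) -> np.ndarray:
    """Classify pixels: True where the Delta reaches the motion threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1 native intensity unit")
    return delta.values >= threshold


def refine_mask(raw: np.ndarray, config: SegmentationConfig = SegmentationConfig()) -> SpheroidMask:
    """Turn a raw thresholded Delta into a single spheroid mask.

    Pipeline: (1) drop 8-connected components smaller than
    ``min_object_area``; (2) dilate survivors by a disk of
    ``expansion_radius`` (the pixel expansion recovering the body from the
    motion band); (3) fill holes; (4) optionally keep only the largest
    component. An empty survivor set is a flagged state, not an error.
    """
    raw = np.asarray(raw, dtype=bool)
    if config.min_object_area > 0:
        # drop components with fewer than min_object_area pixels
        kept = morphology.remove_small_objects(
            raw, max_size=config.min_object_area - 1, connectivity=2
        )
    else:
        kept = raw
    if not kept.any():
        return SpheroidMask(
            mask=np.zeros_like(raw), timepoint=0, centroid=None, area_px=0, empty=True
        )
    if config.expansion_radius > 0:
        kept = morphology.dilation(kept, morphology.disk(config.expansion_radius)).astype(bool)
    kept = ndimage.binary_fill_holes(kept)
    if config.keep == "largest_object":
        lab, n = label(kept, connectivity=2, return_num=True)
        if n > 1:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            kept = lab == int(np.argmax(sizes))
    area = int(kept.sum())
    coords = np.nonzero(kept)
    centroid = (float(coords[0].mean()), float(coords[1].mean()))
    return SpheroidMask(mask=kept, timepoint=0, centroid=centroid, area_px=area, empty=False)


def segment_series(
    series: FrameSeries, config: SegmentationConfig = SegmentationConfig()
) -> list[SpheroidMask]:
    """Segment a whole well: T frames yield T-1 masks at timepoints t0+1..

    Consecutive pairs are processed independently (results do not depend on
    evaluation order). A guard flags frames with a global intensity shift
    (e.g. a medium change): the *median* Delta value is background-dominated
    and near zero for an honest frame pair, so any Delta whose median exceeds
    ``intensity_guard_multiple`` times the series-typical median (and at
    least one intensity unit) produces a mask marked ``low_confidence``
    rather than silently used.
    """
    if series.n_timepoints < 2:
        raise ValueError("segmenting a series requires at least 2 frames")
    deltas = [
        compute_delta(series.frames[i], series.frames[i + 1], config.smoothing_sigma)
        for i in range(series.n_timepoints - 1)
    ]
    med = np.array([np.median(d.values) for d in deltas])
    guard_level = max(config.intensity_guard_multiple * float(np.median(med)), 1.0)
    suspect = med >= guard_level

    masks: list[SpheroidMask] = []
    for i, d in enumerate(deltas):
        tp = series.t0_index + i + 1
        d.assigned_timepoint = tp
        raw = threshold_delta(d, config.threshold)
        m = refine_mask(raw, config)
        m.timepoint = tp
        m.low_confidence = bool(suspect[i])
        masks.append(m)
    return masks
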