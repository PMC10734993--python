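"""ROI cropping and binary segmentation of the root profile.

Each stabilized frame is cropped to a rectangle containing only the root
of interest, then thresholded globally (between-class variance / Otsu) and
cleaned morphologically into a single-component mask.  The root is assumed
to be the minority intensity class inside a well-chosen ROI, which is how
``polarity="auto"`` resolves which side of the threshold is root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open rectangle [r0, r1) x [c0, c1), origin top-left."""

    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if not (0 <= self.r0 < self.r1 and 0 <= self.c0 < self.c1):
            raise ValueError(f"invalid ROI rectangle {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)

    def validate_within(self, image_shape: tuple[int, int]) -> None:
        if self.r1 > image_shape[0] or self.c1 > image_shape[1]:
            raise ValueError(f"ROI {self} exceeds image shape {image_shape}")


def crop_roi(frame: np.ndarray, roi: RegionOfInterest) -> np.ndarray:
    """Pure sub-image extraction; downstream coordinates are ROI-relative."""
    frame = np.asarray(frame)
    roi.validate_within(frame.shape[:2])
    return frame[roi.r0: roi.r1, roi.c0: roi.c1].copy()


def binarize(
    image: np.ndarray,
    polarity: str = "auto",
    min_area: int = 64,
    closing_radius: int = 1,
    threshold_method: str = "otsu",
    min_separation: float = 4.0,
) -> np.ndarray:
    """Segment the root: global threshold, polarity resolution, cleanup.

    Parameters
    ----------
    image:
        Grayscale float array (RGB is reduced by channel mean).
    polarity:
        ``"root_dark"``, ``"root_bright"``, or ``"auto"`` (the minority
        class below/above the threshold is taken as root).
    min_area:
        Connected components smaller than this (px^2) are removed.
    closing_radius:
        Radius of the disk used for morphological closing; 0 disables.
    threshold_method:
        Only ``"otsu"`` (between-class variance maximization) is provided.
    min_separation:
        Bimodality guard: the between-class mean separation must exceed
        ``min_separation`` times the pooled within-class spread, else the
        image is treated as root-free (empty mask).  Otsu always finds
        *some* threshold, even on pure noise, where the split of a single
        Gaussian gives a separation-to-spread ratio of ~2.7; a real
        root/gel boundary at typical contrast sits an order of magnitude
        higher.

    Returns
    -------
    Boolean mask, root pixels True; after cleanup it has at most one
    8-connected component (possibly empty).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image.mean(axis=2)
    if np.ptp(image) == 0:
        raise ValueError("no contrast: image is constant")
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    thresh = threshold_otsu(image)
    bright = image > thresh
    lo, hi = image[~bright], image[bright]
    if lo.size and hi.size:
        pooled = math.hypot(lo.std(), hi.std()) / math.sqrt(2)
        if pooled > 0 and (hi.mean() - lo.mean()) / pooled < min_separation:
            return np.zeros_like(image, dtype=bool)
    if polarity == "root_bright":
        mask = bright
    elif polarity == "root_dark":
        mask = ~bright
    elif polarity == "auto":
        mask = bright if bright.mean() < 0.5 else ~bright
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    if closing_radius > 0:
        mask = ndi.binary_closing(mask, structure=disk(closing_radius))
    mask = ndi.binary_fill_holes(mask)
    labeled, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 0:
        sizes = ndi.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        largest = 1 + int(np.argmax(sizes))
        if sizes[largest - 1] < min_area:
            return np.zeros_like(mask, dtype=bool)
        mask = labeled == largest
    return mask.astype(bool)
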