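"""Germ-granule image quantification.

Difference-of-Gaussians (DoG) band-pass filtering, uniform thresholding,
channel colocalization, and puncta metrics in regions of interest.  The DoG
is ``blur(sigma_small) - blur(sigma_large)`` so that punctate objects give a
positive response suitable for bright-object thresholding; it is applied per
2-D slice of a (z, y, x) stack by default.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ConfigError, DataError


def dog_filter(
    stack: np.ndarray,
    sigma_small: float = 1.0,
    sigma_large: float = 4.0,
    per_slice: bool = True,
) -> np.ndarray:
    """Difference-of-Gaussians band-pass filter.

    ``output = gaussian(sigma_small) - gaussian(sigma_large)``, linear in
    the input, with reflective boundary handling.  A constant image maps to
    (numerically) zero.
    """
    if sigma_small <= 0 or sigma_large <= 0 or sigma_small >= sigma_large:
        raise ConfigError(
            f"require 0 < sigma_small < sigma_large, got "
            f"{sigma_small}, {sigma_large}"
        )
    img = np.asarray(stack, dtype=float)
    if img.ndim == 2:
        return _dog2d(img, sigma_small, sigma_large)
    if per_slice:
        return np.stack([_dog2d(sl, sigma_small, sigma_large) for sl in img])
    return ndimage.gaussian_filter(img, sigma_small, mode="reflect") - \
        ndimage.gaussian_filter(img, sigma_large, mode="reflect")


def _dog2d(img: np.ndarray, s_small: float, s_large: float) -> np.ndarray:
    return (
        ndimage.gaussian_filter(img, s_small, mode="reflect")
        - ndimage.gaussian_filter(img, s_large, mode="reflect")
    )


def threshold_mask(stack: np.ndarray, threshold: float) -> np.ndarray:
    """Voxels strictly above ``threshold``; exact-equal values are excluded."""
    if not np.isfinite(threshold):
        raise ConfigError("threshold must be finite")
    return np.asarray(stack) > threshold


def suggest_threshold(stack: np.ndarray) -> float:
    """Otsu threshold initializer (intended for synthetic calibration only;
    real analyses use a manually chosen, uniform threshold)."""
    return float(threshold_otsu(np.asarray(stack, dtype=float)))


def colocalization_fraction(
    mask_query: np.ndarray, mask_reference: np.ndarray
) -> float | None:
    """Fraction of query-channel thresholded voxels overlapping the reference.

    ``|query AND reference| / |query|`` over the whole stack.  Returns
    ``None`` (undefined, not 0) when the query mask is empty.
    """
    q = np.asarray(mask_query, dtype=bool)
    r = np.asarray(mask_reference, dtype=bool)
    if q.shape != r.shape:
        raise DataError(f"mask shapes differ: {q.shape} vs {r.shape}")
    nq = int(q.sum())
    if nq == 0:
        return None
    return float(np.logical_and(q, r).sum()) / nq


def measure_colocalization(
    stack_query: np.ndarray,
    stack_reference: np.ndarray,
    threshold_query: float,
    threshold_reference: float,
    sigma_small: float = 1.0,
    sigma_large: float = 4.0,
) -> float | None:
    """DoG -> threshold -> colocalization fraction for two channels."""
    mq = threshold_mask(dog_filter(stack_query, sigma_small, sigma_large), threshold_query)
    mr = threshold_mask(
        dog_filter(stack_reference, sigma_small, sigma_large), threshold_reference
    )
    return colocalization_fraction(mq, mr)


@dataclasses.dataclass
class PunctaStats:
    count: int
    roi_area: float
    density: float  # count / roi_area
    sizes: list[int]  # per-punctum pixel counts
    intensities: list[float]  # per-punctum summed intensity


def puncta_metrics(
    mask: np.ndarray, intensity: np.ndarray, roi: np.ndarray
) -> PunctaStats:
    """Count and measure puncta inside an ROI.

    Puncta are 8-connected components per 2-D slice of ``mask`` intersected
    with the (y, x) ROI; density is count divided by ROI pixel area.
    """
    mask = np.asarray(mask, dtype=bool)
    intensity = np.asarray(intensity, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if mask.shape != intensity.shape:
        raise DataError("mask and intensity shapes differ")
    if roi.shape != mask.shape[-2:]:
        raise DataError(f"ROI shape {roi.shape} does not match image plane")
    area = float(roi.sum())
    if area == 0:
        raise DataError("empty ROI")
    slices = mask[None] if mask.ndim == 2 else mask
    planes = intensity[None] if intensity.ndim == 2 else intensity
    count = 0
    sizes: list[int] = []
    intens: list[float] = []
    for sl, pl in zip(slices, planes):
        labeled = label(sl & roi, connectivity=2)
        for region in regionprops(labeled, intensity_image=pl):
            count += 1
            sizes.append(int(region.area))
            intens.append(float(region.image_intensity[region.image].sum()))
    return PunctaStats(
        count=count,
        roi_area=area,
        density=count / area,
        sizes=sizes,
        intensities=intens,
    )
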