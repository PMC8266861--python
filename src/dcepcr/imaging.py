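"""Tumor segmentation from enhancement maps and ROI patch construction.

A DCE series holds one pre-contrast and two post-contrast volumes. Two
semi-quantitative pharmacokinetic maps drive segmentation:

* peak enhancement        ``PE  = (post1 - pre) / pre``
* signal enhancement ratio ``SER = (post1 - pre) / (post2 - pre)``

Voxels inside a reader-supplied seed region whose PE exceeds a threshold
and whose SER falls in a configured range, restricted to the largest
connected component, form the tumor mask. The classifier input is a square
patch whose side equals the clinical largest diameter (LD), centred on the
tumor centroid in the slice with the largest tumor area, cropped from the
first post-contrast volume and resized to 227 x 227 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "DceSeries",
    "RoiPatch",
    "EnhancementMaps",
    "SegmentationError",
    "compute_enhancement_maps",
    "segment_tumor",
    "extract_roi",
    "dice_coefficient",
    "box_to_mask",
]

ROI_SIZE = 227  #: side of the model-input patch, fixed by the extractor contract
MIN_LD_PX = 8  #: floor on the crop side in pixels


class SegmentationError(RuntimeError):
    """Raised when thresholding yields no tumor voxels for a case."""


@dataclass(frozen=True)
class DceSeries:
    """One patient-timepoint: pre-contrast plus two post-contrast volumes."""

    pre: np.ndarray
    post1: np.ndarray
    post2: np.ndarray
    pixel_spacing: float

    def __post_init__(self):
        for name in ("pre", "post1", "post2"):
            v = getattr(self, name)
            object.__setattr__(self, name, np.asarray(v, dtype=float))
        if not (self.pre.shape == self.post1.shape == self.post2.shape):
            raise ValueError("pre/post1/post2 must share one shape")
        if self.pre.ndim != 3:
            raise ValueError("volumes must be 3-D (slices, rows, cols)")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if min(self.pre.min(), self.post1.min(), self.post2.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self):
        return self.pre.shape


@dataclass(frozen=True)
class EnhancementMaps:
    """PE and SER maps with validity masks.

    Voxels with a non-positive denominator (``pre <= 0`` for PE,
    ``post2 - pre <= 0`` for SER) carry NaN and are flagged invalid; they
    never pass thresholding.
    """

    pe: np.ndarray
    ser: np.ndarray
    pe_valid: np.ndarray
    ser_valid: np.ndarray


@dataclass(frozen=True)
class RoiPatch:
    """227 x 227 model-input patch with provenance."""

    image: np.ndarray
    source_slice: int
    center: tuple
    ld_mm: float
    ld_px: int
    timepoint: str

    def __post_init__(self):
        img = np.asarray(self.image, dtype=float)
        object.__setattr__(self, "image", img)
        if img.shape != (ROI_SIZE, ROI_SIZE):
            raise ValueError(f"patch must be {ROI_SIZE}x{ROI_SIZE}, got {img.shape}")
        if self.ld_px < 1:
            raise ValueError("ld_px must be >= 1")
        if self.timepoint not in ("T1", "T2"):
            raise ValueError("timepoint must be 'T1' or 'T2'")


def compute_enhancement_maps(series: DceSeries) -> EnhancementMaps:
    """Compute PE and SER maps; degenerate denominators are flagged invalid."""
    with np.errstate(divide="ignore", invalid="ignore"):
        pe_valid = series.pre > 0
        pe = np.where(pe_valid, (series.post1 - series.pre) / series.pre, np.nan)
        wash = series.post2 - series.pre
        ser_valid = pe_valid & (wash > 0)
        ser = np.where(ser_valid, (series.post1 - series.pre) / wash, np.nan)
    return EnhancementMaps(pe=pe, ser=ser, pe_valid=pe_valid, ser_valid=ser_valid)


def box_to_mask(shape, box) -> np.ndarray:
    """Convert a ``((z0, z1), (r0, r1), (c0, c1))`` half-open box to a mask."""
    m = np.zeros(shape, dtype=bool)
    (z0, z1), (r0, r1), (c0, c1) = box
    m[z0:z1, r0:r1, c0:c1] = True
    return m


def segment_tumor(series: DceSeries, seed_region: np.ndarray,
                  pe_threshold: float = 0.7,
                  ser_range: tuple = (0.9, np.inf),
                  case_id: str = "<unnamed>") -> np.ndarray:
    """Threshold PE/SER inside the seed region; keep the largest component.

    Raises :class:`SegmentationError` naming ``case_id`` when no voxel
    survives, which typically means the thresholds do not match the
    contrast behaviour of the case.
    """
    seed_region = np.asarray(seed_region, dtype=bool)
    if seed_region.shape != series.shape:
        raise ValueError("seed_region shape must match the series")
    if not seed_region.any():
        raise ValueError("seed_region is empty")
    maps = compute_enhancement_maps(series)
    lo, hi = ser_range
    with np.errstate(invalid="ignore"):
        cand = (seed_region & maps.pe_valid & maps.ser_valid
                & (maps.pe > pe_threshold) & (maps.ser >= lo) & (maps.ser <= hi))
    if not cand.any():
        raise SegmentationError(
            f"case {case_id}: no voxel passed PE > {pe_threshold} and "
            f"SER in [{lo}, {hi}]; check thresholds against the enhancement maps")
    labeled, n = ndimage.label(cand)
    sizes = ndimage.sum_labels(cand, labeled, index=np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def extract_roi(series: DceSeries, mask: np.ndarray, ld_mm: float,
                timepoint: str = "T1") -> RoiPatch:
    """Crop the LD-sized square around the tumor and resize to 227 x 227.

    The slice with the largest in-slice mask area is used (ties broken
    toward the lowest slice index); the crop is a half-open window of side
    ``round(ld_mm / pixel_spacing)`` (min 8 px) centred on the rounded
    in-slice centroid, taken from the first post-contrast volume, with
    out-of-bounds regions zero-padded, then bilinearly resized.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape:
        raise ValueError("mask shape must match the series")
    if not mask.any():
        raise ValueError("mask is empty")
    areas = mask.sum(axis=(1, 2))
    sl = int(np.argmax(areas))  # argmax returns the lowest index on ties
    rows, cols = np.nonzero(mask[sl])
    center = (_round_half_up(rows.mean()), _round_half_up(cols.mean()))
    ld_px = max(MIN_LD_PX, _round_half_up(ld_mm / series.pixel_spacing))
    r0 = center[0] - ld_px // 2
    c0 = center[1] - ld_px // 2
    crop = np.zeros((ld_px, ld_px))
    img = series.post1[sl]
    rr0, rr1 = max(r0, 0), min(r0 + ld_px, img.shape[0])
    cc0, cc1 = max(c0, 0), min(c0 + ld_px, img.shape[1])
    if rr0 < rr1 and cc0 < cc1:
        crop[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] = img[rr0:rr1, cc0:cc1]
    patch = resize(crop, (ROI_SIZE, ROI_SIZE), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
    return RoiPatch(image=patch, source_slice=sl, center=center,
                    ld_mm=float(ld_mm), ld_px=ld_px, timepoint=timepoint)
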