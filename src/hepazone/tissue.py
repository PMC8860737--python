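"""Foreground (tissue) masking of brightfield whole-slide images.

Histology background is bright, tissue is darker, so a global Otsu threshold
on the luma channel separates the two.  Small bright holes inside the tissue
(vessel lumens, tears) are filled, tiny stray foreground specks are removed,
and the edges are smoothed by a median blur and a morphological opening.

Default area thresholds: connected tissue pieces must be at least the area
of a circle of 1 mm diameter (0.785 mm²); enclosed empty spaces larger than
0.00785 mm² are kept as background (e.g. the gap between two tissue
segments), smaller ones are filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

#: Area of a circle of 1 mm diameter, in mm².
DEFAULT_MIN_TISSUE_AREA_MM2 = math.pi * 0.5 ** 2
#: One hundredth of the above; holes smaller than this are filled.
DEFAULT_MIN_HOLE_AREA_MM2 = DEFAULT_MIN_TISSUE_AREA_MM2 / 100.0

GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class TissueMask:
    mask: np.ndarray  # bool, True = tissue
    resolution_nm_per_px: float

    @property
    def area_mm2(self) -> float:
        px_mm = self.resolution_nm_per_px * 1e-6
        return float(self.mask.sum()) * px_mm * px_mm


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luma Y = 0.299 R + 0.587 G + 0.114 B, rounded half-even to uint8."""
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {rgb.shape}")
    y = rgb[..., 0] * GRAY_WEIGHTS[0] + rgb[..., 1] * GRAY_WEIGHTS[1] + rgb[..., 2] * GRAY_WEIGHTS[2]
    return np.rint(y).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu threshold over the 256-bin histogram of an 8-bit image.

    Maximizes the between-class intensity variance.  Tissue (foreground) is
    the dark side of the split — at or below the returned threshold, which
    belongs to the lower class.
    """
    gray = np.asarray(gray)
    if gray.min() == gray.max():
        raise ValueError("constant image: Otsu threshold undefined")
    counts = np.bincount(gray.ravel().astype(np.uint8), minlength=256)
    return int(threshold_otsu(hist=(counts, np.arange(256))))


def filter_contours(mask: np.ndarray, resolution_nm_per_px: float,
                    min_tissue_area_mm2: float = DEFAULT_MIN_TISSUE_AREA_MM2,
                    min_hole_area_mm2: float = DEFAULT_MIN_HOLE_AREA_MM2,
                    fill_large_holes: bool = False) -> np.ndarray:
    """Keep large tissue components; fill only small enclosed holes.

    Foreground components (8-connected) smaller than ``min_tissue_area_mm2``
    are discarded.  Enclosed background components (4-connected, not touching
    the image border) with area <= ``min_hole_area_mm2`` are filled; larger
    enclosed spaces stay background unless ``fill_large_holes`` is set.
    """
    if min_tissue_area_mm2 <= 0 or min_hole_area_mm2 <= 0:
        raise ValueError("area thresholds must be positive")
    mask = np.asarray(mask).astype(bool)
    px_mm2 = (resolution_nm_per_px * 1e-6) ** 2
    min_tissue_px = min_tissue_area_mm2 / px_mm2
    min_hole_px = min_hole_area_mm2 / px_mm2

    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_tissue_px
        keep[0] = False
        mask = keep[lab]
    else:
        mask = np.zeros_like(mask)

    holes, n_h = ndimage.label(~mask)  # 4-connectivity for background
    if n_h:
        border_labels = np.unique(np.concatenate([
            holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]]))
        sizes = np.bincount(holes.ravel())
        fill = np.ones(n_h + 1, dtype=bool)
        fill[0] = False
        fill[border_labels] = False
        if not fill_large_holes:
            fill &= sizes <= min_hole_px
        mask = mask | fill[holes]
    return mask


def smooth_mask(mask: np.ndarray, median_kernel: int = 11,
                opening_radius: int = 5) -> np.ndarray:
    """Median blur followed by opening with a disk structuring element."""
    if median_kernel % 2 != 1 or median_kernel < 1:
        raise ValueError("median kernel must be odd and positive")
    mask = np.asarray(mask).astype(bool)
    if median_kernel > 1:
        mask = median_filter(mask, footprint=np.ones((median_kernel, median_kernel), bool))
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius))
    return mask.astype(bool)


def compute_tissue_mask(rgb: np.ndarray, resolution_nm_per_px: float,
                        min_tissue_area_mm2: float = DEFAULT_MIN_TISSUE_AREA_MM2,
                        min_hole_area_mm2: float = DEFAULT_MIN_HOLE_AREA_MM2,
                        median_kernel: int = 11, opening_radius: int = 5,
                        fill_large_holes: bool = False) -> TissueMask:
    """Grayscale -> Otsu -> contour filtering -> edge smoothing.

    Raises if no tissue survives (e.g. an all-background image).
    """
    gray = to_grayscale(rgb)
    try:
        thr = otsu_threshold(gray)
    except ValueError as exc:
        raise ValueError("cannot mask tissue: " + str(exc)) from exc
    fg = gray <= thr
    fg = filter_contours(fg, resolution_nm_per_px, min_tissue_area_mm2,
                         min_hole_area_mm2, fill_large_holes)
    fg = smooth_mask(fg, median_kernel, opening_radius)
    if not fg.any():
        raise ValueError("no tissue found: mask empty after filtering")
    return TissueMask(fg, resolution_nm_per_px)
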