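"""Lung-parenchyma segmentation and max-SUV circular ROI extraction.

The nodule region of interest is found without any seed point: Otsu
thresholding plus a morphological opening isolates the dark lung field from
the bright thorax, and the hottest SUV pixel inside the lung marks the
nodule.  A circular template of radius ``R`` (default 30 mm, covering
nodules up to 30 mm diameter) around that pixel bounds all downstream
computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, segmentation

from .errors import DegenerateInputError, EmptyMaskError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "PetCtSlice",
    "RoiResult",
    "segment_lung_parenchyma",
    "find_max_suv_pixel",
    "extract_roi",
]


@dataclass(frozen=True)
class PetCtSlice:
    """A co-registered CT gray raster and SUV raster on one pixel grid."""

    ct: np.ndarray
    suv: np.ndarray
    pixel_spacing_mm: float = 1.0

    def __post_init__(self):
        ct = np.asarray(self.ct, dtype=float)
        suv = np.asarray(self.suv, dtype=float)
        if ct.ndim != 2 or ct.shape != suv.shape:
            raise ParameterError(
                f"ct and suv must be 2-D rasters of equal shape, got "
                f"{ct.shape} and {suv.shape}"
            )
        if self.pixel_spacing_mm <= 0:
            raise ParameterError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "ct", ct)
        object.__setattr__(self, "suv", suv)


@dataclass(frozen=True)
class RoiResult:
    """Circular nodule ROI centred on the maximum-SUV lung pixel."""

    roi_mask: np.ndarray
    center_O: tuple[int, int]
    radius_R_mm: float
    radius_px: int
    lung_mask: np.ndarray


def segment_lung_parenchyma(
    sl: PetCtSlice, open_radius_px: int = 2, close_radius_px: int = 3
) -> np.ndarray:
    """Binary lung-field mask from the CT channel.

    Otsu's threshold (maximum between-class variance on a 256-bin histogram)
    separates dark lung air from bright soft tissue; components touching the
    image border (air outside the body) are discarded, a disk closing seals
    vessel bands that would otherwise split the lung field, holes (nodules,
    vessels) are filled, a disk opening removes thin spurs, and the largest
    one or two remaining components are returned.
    """
    ct = sl.ct
    if np.ptp(ct) == 0:
        raise DegenerateInputError("constant CT image: no Otsu threshold exists")
    threshold = filters.threshold_otsu(ct, nbins=256)
    low = ct < threshold
    low = segmentation.clear_border(low)
    if close_radius_px > 0:
        low = morphology.closing(low, morphology.disk(close_radius_px))
    low = ndimage.binary_fill_holes(low)
    if open_radius_px > 0:
        low = morphology.opening(low, morphology.disk(open_radius_px))
    labels, n_labels = ndimage.label(low, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        raise EmptyMaskError("no lung-like component found below the Otsu threshold")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_labels + 1))
    order = np.argsort(areas)[::-1]
    keep = [order[0] + 1]
    # a second lung is kept when it is comparable in size to the first
    if n_labels > 1 and areas[order[1]] >= 0.2 * areas[order[0]]:
        keep.append(order[1] + 1)
    return np.isin(labels, keep)


def find_max_suv_pixel(suv: np.ndarray, lung_mask: np.ndarray) -> tuple[int, int]:
    """Coordinates of the maximum SUV inside the lung mask.

    Ties are broken in row-major order (smallest row, then smallest column).
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if not lung_mask.any():
        raise EmptyMaskError("empty lung mask: cannot locate the maximum SUV")
    masked = np.where(lung_mask, np.asarray(suv, dtype=float), -np.inf)
    flat = int(np.argmax(masked))
    return np.unravel_index(flat, masked.shape)


def extract_roi(
    sl: PetCtSlice, radius_R_mm: float = 30.0, open_radius_px: int = 2
) -> RoiResult:
    """Circular nodule ROI: lung mask -> hottest pixel O -> disk of radius R.

    The template radius is converted from mm to the nearest integer pixel
    count; the ROI is the set of pixels within that Euclidean distance of O,
    clipped to the grid (not to the lung mask).
    """
    if radius_R_mm <= 0:
        raise ParameterError("radius_R_mm must be positive")
    lung_mask = segment_lung_parenchyma(sl, open_radius_px=open_radius_px)
    center = find_max_suv_pixel(sl.suv, lung_mask)
    radius_px = int(round(radius_R_mm / sl.pixel_spacing_mm))
    rows, cols = np.ogrid[0 : sl.ct.shape[0], 0 : sl.ct.shape[1]]
    roi_mask = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius_px**2
    logger.info(
        "ROI centre O=%s, radius %.1f mm = %d px, area %d px",
        center,
        radius_R_mm,
        radius_px,
        int(roi_mask.sum()),
    )
    return RoiResult(
        roi_mask=roi_mask,
        center_O=(int(center[0]), int(center[1])),
        radius_R_mm=float(radius_R_mm),
        radius_px=radius_px,
        lung_mask=lung_mask,
    )
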