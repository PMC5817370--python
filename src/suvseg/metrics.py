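"""Segmentation evaluation: Dice overlap, Hausdorff distance, false positive.

DSC and FP are reported on the 0-100 scale; the Hausdorff distance is the
full symmetric contour-to-contour distance, reported both in pixels and in
mm via the pixel spacing.  FP uses the ground-truth area as denominator and
can therefore exceed 100 under gross oversegmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .errors import UndefinedMetricError

__all__ = [
    "MetricReport",
    "dice",
    "hausdorff",
    "false_positive",
    "mask_boundary",
    "evaluate_masks",
]


@dataclass(frozen=True)
class MetricReport:
    dsc_percent: float
    hd_mm: float
    hd_px: float
    fp_percent: float


def _as_mask(a) -> np.ndarray:
    return np.asarray(a).astype(bool)


def dice(ag, ar) -> float:
    """DSC = 2 |Ag n Ar| / (|Ag| + |Ar|) * 100."""
    ag, ar = _as_mask(ag), _as_mask(ar)
    denom = int(ag.sum()) + int(ar.sum())
    if denom == 0:
        raise UndefinedMetricError("dice is undefined for two empty masks")
    return 200.0 * int((ag & ar).sum()) / denom


def mask_boundary(mask) -> np.ndarray:
    """Contour pixels: foreground with at least one 4-neighbour background.

    Pixels on the image border count as boundary (the outside of the grid is
    treated as background).
    """
    mask = _as_mask(mask)
    cross = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return mask & ~eroded


def hausdorff(points_a, points_b, spacing_mm: float = 1.0) -> float:
    """Symmetric Hausdorff distance of two point sets, scaled to mm."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise UndefinedMetricError("hausdorff is undefined for an empty point set")
    d = max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    return float(d) * spacing_mm


def false_positive(ag, ar) -> float:
    """FP = (|Ar| - |Ag n Ar|) / |Ag| * 100 (can exceed 100)."""
    ag, ar = _as_mask(ag), _as_mask(ar)
    n_ag = int(ag.sum())
    if n_ag == 0:
        raise UndefinedMetricError("false positive is undefined for an empty truth")
    return 100.0 * (int(ar.sum()) - int((ag & ar).sum())) / n_ag


def evaluate_masks(ag, ar, pixel_spacing_mm: float = 1.0) -> MetricReport:
    """All three metrics for a truth/result mask pair on one grid."""
    boundary_g = np.argwhere(mask_boundary(ag))
    boundary_r = np.argwhere(mask_boundary(ar))
    hd_px = hausdorff(boundary_g, boundary_r, spacing_mm=1.0)
    return MetricReport(
        dsc_percent=dice(ag, ar),
        hd_mm=hd_px * pixel_spacing_mm,
        hd_px=hd_px,
        fp_percent=false_positive(ag, ar),
    )
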