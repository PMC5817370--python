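"""Automatic threshold-iteration initial contour inside the ROI.

Starting from the midpoint of the gray range, the threshold is repeatedly
replaced by the mean of the below/above class means until it moves by no
more than ``lambda_tol`` (default 0.1).  The resulting binarisation is
cleaned by a single rule: the boundary enclosing the largest (hole-filled)
connected component becomes the initial contour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateInputError, EmptyMaskError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdIterState",
    "ContourPolyline",
    "iterate_threshold",
    "binarize",
    "select_initial_contour",
]

_MAX_ITER = 1000


@dataclass(frozen=True)
class ThresholdIterState:
    """Converged state of the automatic threshold iteration."""

    T: float
    G_max: float
    G_min: float
    alpha_b: float
    alpha_n: float
    lambda_tol: float
    n_iter: int
    history: tuple[float, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class ContourPolyline:
    """Closed boundary polyline of a pixel region (sub-pixel vertices)."""

    vertices: np.ndarray  # (N, 2) array of (row, col) positions
    closed: bool
    enclosed_area_px: int


def iterate_threshold(
    gray: np.ndarray, lambda_tol: float = 0.1, mask: np.ndarray | None = None
) -> ThresholdIterState:
    """Run the two-class mean-threshold iteration to convergence.

    ``gray`` may be any raster; if ``mask`` is given only those pixels are
    used.  The background class is strictly below T, the nodule class at or
    above it.  If one class empties, its mean is taken as the previous
    threshold, which leaves T unchanged and terminates the iteration.
    """
    if lambda_tol <= 0:
        raise ParameterError("lambda_tol must be positive")
    values = np.asarray(gray, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values.ravel()
    if values.size == 0 or np.ptp(values) == 0:
        raise DegenerateInputError(
            "threshold iteration needs at least two distinct gray values"
        )
    g_max, g_min = float(values.max()), float(values.min())
    t = (g_max + g_min) / 2.0
    history = [t]
    alpha_b = alpha_n = t
    for n_iter in range(1, _MAX_ITER + 1):
        below = values < t
        alpha_b = float(values[below].mean()) if below.any() else t
        alpha_n = float(values[~below].mean()) if (~below).any() else t
        t_new = (alpha_b + alpha_n) / 2.0
        history.append(t_new)
        converged = abs(t_new - t) <= lambda_tol
        t = t_new
        if converged:
            break
    logger.debug("threshold iteration: %s", history)
    return ThresholdIterState(
        T=t,
        G_max=g_max,
        G_min=g_min,
        alpha_b=alpha_b,
        alpha_n=alpha_n,
        lambda_tol=lambda_tol,
        n_iter=n_iter,
        history=tuple(history),
    )


def binarize(gray: np.ndarray, T: float) -> np.ndarray:
    """Binary raster: 1 where gray >= T, else 0."""
    return (np.asarray(gray, dtype=float) >= T).astype(np.uint8)


def _filled_component_masks(binary: np.ndarray):
    labels, n_labels = ndimage.label(
        np.asarray(binary, dtype=bool), structure=np.ones((3, 3), dtype=int)
    )
    for lab in range(1, n_labels + 1):
        yield ndimage.binary_fill_holes(labels == lab)


def select_initial_contour(binary: np.ndarray) -> ContourPolyline:
    """Boundary of the maximum-area foreground component.

    Components are 8-connected and their areas are measured with holes
    filled; ties go to the component whose first pixel comes earliest in
    row-major order.  The boundary is traced at the 0.5 level of the filled
    component, giving a closed sub-pixel polyline.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise EmptyMaskError("no foreground component to build a contour from")
    best = None
    best_key = None
    for filled in _filled_component_masks(binary):
        area = int(filled.sum())
        first_pixel = int(np.argmax(filled))
        key = (-area, first_pixel)
        if best_key is None or key < best_key:
            best, best_key = filled, key
    contours = measure.find_contours(np.pad(best.astype(float), 1), 0.5)
    vertices = max(contours, key=len) - 1.0
    if len(vertices) < 3:
        raise EmptyMaskError("selected component is too small to trace")
    return ContourPolyline(
        vertices=vertices, closed=True, enclosed_area_px=int(-best_key[0])
    )


def contour_to_mask(contour: ContourPolyline, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a closed contour back to a pixel mask (centres inside)."""
    from skimage import draw

    rr, cc = draw.polygon(contour.vertices[:, 0], contour.vertices[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask
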