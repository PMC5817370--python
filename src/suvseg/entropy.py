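"""SUV information-entropy edge guide for the level-set evolution.

For each point x near the zero level set, a circular neighbourhood R(x) of
radius r (default 15 px) is split by the contour into an inside part and an
outside part.  The SUV values of each part are modelled as approximately
Gaussian; evaluating the Gaussian density at every pixel of the part and
normalising gives a discrete probability vector whose Shannon entropy (in
bits) measures how homogeneous the part is: a homogeneous part has equal
densities and maximal entropy log2(n).  The edge guide weight

    F_i(x) = exp(-H_i(x))

is therefore smallest where the SUV distribution is homogeneous (the
contour should stop there) and larger where the neighbourhood mixes nodule
and vessel/background uptake (the contour should keep moving).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyRegionError,
    EvolutionCollapsedError,
    InvalidDistributionError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GuideField",
    "shannon_entropy",
    "suv_region_entropy",
    "edge_guide",
    "build_guide_field",
]


@dataclass(frozen=True)
class GuideField:
    """Edge-guide weights and entropies on the full grid.

    Outside the evaluation band the guide is neutral (F = 1, entropy NaN).
    """

    F1: np.ndarray
    F2: np.ndarray
    H_suv_inside: np.ndarray
    H_suv_outside: np.ndarray
    sigma_floor: float
    radius_r_px: int


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector, 0*log0 := 0."""
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidDistributionError(
            "entries must be nonnegative and sum to 1 within 1e-9"
        )
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _gaussian_probabilities(values: np.ndarray, sigma_floor: float) -> np.ndarray:
    """Normalised Gaussian densities of the values under their own fit.

    The 1/(sqrt(2*pi)*sigma) prefactor is constant within a region and
    cancels on normalisation, so only exp(-z^2/2) is evaluated.
    """
    c = values.mean()
    sigma = max(float(values.std()), sigma_floor)
    dens = np.exp(-0.5 * ((values - c) / sigma) ** 2)
    return dens / dens.sum()


def suv_region_entropy(
    suv: np.ndarray, region: np.ndarray, sigma_floor: float = 1e-3
) -> float:
    """Entropy (bits) of the Gaussian-modelled SUV distribution of a region.

    ``region`` is a boolean mask over ``suv``.  A constant region yields
    equal probabilities and hence entropy log2(n).
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise EmptyRegionError("cannot compute SUV entropy of an empty region")
    values = np.asarray(suv, dtype=float)[region]
    return shannon_entropy(_gaussian_probabilities(values, sigma_floor))


def _disk_offsets(radius: int) -> np.ndarray:
    dr, dc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = dr**2 + dc**2 <= radius**2
    return np.stack([dr[keep], dc[keep]], axis=1)


def edge_guide(
    suv: np.ndarray,
    phi: np.ndarray,
    x: tuple[int, int],
    radius_r_px: int = 15,
    sigma_floor: float = 1e-3,
) -> tuple[float, float]:
    """Edge-guide weights (F1, F2) at one contour point.

    The neighbourhood R(x) is split into the inside part (phi >= 0) and the
    outside part (phi < 0).  If either part is empty the point gets neutral
    weights (1, 1).
    """
    suv = np.asarray(suv, dtype=float)
    offsets = _disk_offsets(radius_r_px) + np.asarray(x, dtype=int)
    in_grid = (
        (offsets[:, 0] >= 0)
        & (offsets[:, 0] < suv.shape[0])
        & (offsets[:, 1] >= 0)
        & (offsets[:, 1] < suv.shape[1])
    )
    offsets = offsets[in_grid]
    values = suv[offsets[:, 0], offsets[:, 1]]
    inside = phi[offsets[:, 0], offsets[:, 1]] >= 0
    if not inside.any() or inside.all():
        logger.warning("edge_guide at %s: one side of the contour is empty", x)
        return 1.0, 1.0
    h3 = shannon_entropy(_gaussian_probabilities(values[inside], sigma_floor))
    h4 = shannon_entropy(_gaussian_probabilities(values[~inside], sigma_floor))
    return float(np.exp(-h3)), float(np.exp(-h4))


def build_guide_field(
    suv: np.ndarray,
    phi: np.ndarray,
    radius_r_px: int = 15,
    band_px: float = 3.0,
    sigma_floor: float = 1e-3,
    roi_mask: np.ndarray | None = None,
) -> GuideField:
    """Evaluate the edge guide at every pixel within ``band_px`` of the contour.

    The evaluation is vectorised over band pixels.  Outside the band the
    guide is neutral (F = 1); if the level set has no zero crossing at all
    the evolution has collapsed and an error is raised.
    """
    suv = np.asarray(suv, dtype=float)
    phi = np.asarray(phi, dtype=float)
    inside_full = phi >= 0
    interior = inside_full if roi_mask is None else (inside_full & roi_mask)
    domain_size = phi.size if roi_mask is None else int(np.sum(roi_mask))
    n_inside = int(interior.sum())
    if n_inside == 0 or n_inside == domain_size:
        raise EvolutionCollapsedError("level set has no zero crossing")

    band = np.abs(phi) <= band_px
    if roi_mask is not None:
        band &= roi_mask
    points = np.argwhere(band)

    f1 = np.ones_like(phi)
    f2 = np.ones_like(phi)
    h_in = np.full_like(phi, np.nan)
    h_out = np.full_like(phi, np.nan)
    if points.size == 0:
        return GuideField(f1, f2, h_in, h_out, sigma_floor, radius_r_px)

    offs = _disk_offsets(radius_r_px)
    rows = points[:, 0][:, None] + offs[None, :, 0]
    cols = points[:, 1][:, None] + offs[None, :, 1]
    valid = (
        (rows >= 0) & (rows < phi.shape[0]) & (cols >= 0) & (cols < phi.shape[1])
    )
    rows_c = np.clip(rows, 0, phi.shape[0] - 1)
    cols_c = np.clip(cols, 0, phi.shape[1] - 1)
    values = suv[rows_c, cols_c]
    inside = inside_full[rows_c, cols_c] & valid
    outside = ~inside_full[rows_c, cols_c] & valid

    h3, n3 = _rowwise_entropy(values, inside, sigma_floor)
    h4, n4 = _rowwise_entropy(values, outside, sigma_floor)
    ok = (n3 > 0) & (n4 > 0)
    n_empty = int((~ok).sum())
    if n_empty:
        logger.warning("%d band points had an empty contour side", n_empty)

    rr, cc = points[:, 0], points[:, 1]
    f1[rr[ok], cc[ok]] = np.exp(-h3[ok])
    f2[rr[ok], cc[ok]] = np.exp(-h4[ok])
    h_in[rr[ok], cc[ok]] = h3[ok]
    h_out[rr[ok], cc[ok]] = h4[ok]
    return GuideField(f1, f2, h_in, h_out, sigma_floor, radius_r_px)


def _rowwise_entropy(values: np.ndarray, member: np.ndarray, sigma_floor: float):
    """Entropy of each row's masked values, matching ``suv_region_entropy``."""
    w = member.astype(float)
    n = w.sum(axis=1)
    safe_n = np.maximum(n, 1.0)
    mean = (values * w).sum(axis=1) / safe_n
    var = (((values - mean[:, None]) ** 2) * w).sum(axis=1) / safe_n
    sigma = np.maximum(np.sqrt(var), sigma_floor)
    dens = np.exp(-0.5 * ((values - mean[:, None]) / sigma[:, None]) ** 2) * w
    total = np.maximum(dens.sum(axis=1), 1e-300)
    p = dens / total[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return -plogp.sum(axis=1), n
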