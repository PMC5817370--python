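"""Synthetic co-registered CT/SUV slice pairs with a vessel-attached nodule.

The generator emulates the data regime the segmentation method targets: a
roughly circular solid nodule (radius a few mm up to ~12 mm) attached to an
elongated vascular band whose CT gray value is nearly identical to the
nodule's, embedded in dark lung parenchyma inside a bright thorax ring.
On the SUV channel the nodule is markedly hotter than the vessel, which in
turn is hotter than parenchyma — the contrast that SUV-entropy edge guidance
relies on.  Additive Gaussian noise and a smooth multiplicative bias field
model acquisition noise and intensity inhomogeneity.

Everything is deterministic given ``(spec, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import ParameterError

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the vessel-attached-nodule phantom."""

    grid_size: int = 128
    pixel_spacing_mm: float = 1.0
    nodule_center: tuple[float, float] = (64.0, 64.0)
    nodule_radius_mm: float = 7.0
    vessel_width_mm: float = 3.0
    vessel_angle_deg: float = 30.0
    ct_gray_nodule: float = 150.0
    ct_gray_vessel: float = 145.0
    ct_gray_parenchyma: float = 40.0
    ct_gray_background: float = 210.0
    suv_nodule: float = 6.0
    suv_vessel: float = 1.8
    suv_parenchyma: float = 0.4
    noise_sigma_ct: float = 5.0
    noise_sigma_suv: float = 0.15
    bias_amplitude: float = 0.1
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.nodule_radius_mm <= 0:
            raise ParameterError("nodule_radius_mm must be positive")
        if self.vessel_width_mm <= 0:
            raise ParameterError("vessel_width_mm must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ParameterError("pixel_spacing_mm must be positive")
        if not (self.suv_nodule > self.suv_vessel >= self.suv_parenchyma >= 0):
            raise ParameterError(
                "SUV contrast must satisfy suv_nodule > suv_vessel >= "
                "suv_parenchyma >= 0"
            )
        r_px = self.nodule_radius_mm / self.pixel_spacing_mm
        row, col = self.nodule_center
        n = self.grid_size
        if (
            row - r_px < 0
            or col - r_px < 0
            or row + r_px > n - 1
            or col + r_px > n - 1
        ):
            raise ParameterError("nodule disk does not fit inside the grid")
        return self


@dataclass(frozen=True)
class PhantomSample:
    """A generated slice pair with its ground truth."""

    ct: np.ndarray
    suv: np.ndarray
    truth_mask: np.ndarray
    truth_contour: np.ndarray  # closed (N, 2) polyline of (row, col) vertices
    spec: PhantomSpec

    @property
    def vessel_mask(self) -> np.ndarray:
        """Vessel band outside the nodule disk (for diagnostics)."""
        return _region_masks(self.spec)[3]


def _region_masks(spec: PhantomSpec):
    """Noiseless layout: (lung, nodule, vessel-incl-overlap, vessel-excl-nodule)."""
    n = spec.grid_size
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    c_row, c_col = spec.nodule_center
    r_px = spec.nodule_radius_mm / spec.pixel_spacing_mm

    # lung field: disk inset from the border; the rest is the thorax ring
    lung_radius = n / 2.0 - 8.0
    lung = (rows - (n - 1) / 2.0) ** 2 + (cols - (n - 1) / 2.0) ** 2 <= lung_radius**2

    # pixel-centre-inside rasterisation; distance exactly equal to the radius
    # counts as inside
    d2 = (rows - c_row) ** 2 + (cols - c_col) ** 2
    nodule = d2 <= r_px**2

    # vessel band: straight line at vessel_angle_deg, offset so that its inner
    # edge overlaps the nodule rim by one pixel (guarantees 4-adjacency)
    theta = np.deg2rad(spec.vessel_angle_deg)
    direction = np.array([np.sin(theta), np.cos(theta)])  # along the vessel
    normal = np.array([-direction[1], direction[0]])
    w_px = spec.vessel_width_mm / spec.pixel_spacing_mm
    offset = r_px + w_px / 2.0 - 1.0
    line_point = np.array([c_row, c_col]) + offset * normal
    dist_to_line = np.abs(
        (rows - line_point[0]) * normal[0] + (cols - line_point[1]) * normal[1]
    )
    vessel_full = (dist_to_line <= w_px / 2.0) & lung
    vessel = vessel_full & ~nodule
    return lung, nodule, vessel_full, vessel


def _bias_field(n: int, amplitude: float) -> np.ndarray:
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    return 1.0 + amplitude * np.cos(np.pi * rows / n) * np.cos(np.pi * cols / n)


def _trace_closed_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(np.pad(mask.astype(float), 1), 0.5)
    if not contours:
        raise ParameterError("mask rasterised to an empty region")
    longest = max(contours, key=len)
    return longest - 1.0  # undo padding


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one CT/SUV pair with exact nodule ground truth.

    The CT layout is piecewise constant (thorax ring, parenchyma, nodule
    disk, attached vessel band) multiplied by a smooth bias field with
    additive Gaussian noise, clipped to [0, 255].  The SUV layout uses the
    analogous levels plus noise, clipped at 0.  ``truth_mask`` is the exact
    rasterised nodule disk, vessel excluded.
    """
    spec.validate()
    lung, nodule, _, vessel = _region_masks(spec)

    ct = np.full(lung.shape, spec.ct_gray_background, dtype=float)
    ct[lung] = spec.ct_gray_parenchyma
    ct[vessel] = spec.ct_gray_vessel
    ct[nodule] = spec.ct_gray_nodule

    suv = np.zeros(lung.shape, dtype=float)
    suv[lung] = spec.suv_parenchyma
    suv[vessel] = spec.suv_vessel
    suv[nodule] = spec.suv_nodule

    rng = np.random.default_rng(spec.seed)
    ct = ct * _bias_field(spec.grid_size, spec.bias_amplitude)
    if spec.noise_sigma_ct > 0:
        ct = ct + rng.normal(0.0, spec.noise_sigma_ct, ct.shape)
    ct = np.clip(ct, 0.0, 255.0)
    if spec.noise_sigma_suv > 0:
        suv = suv + rng.normal(0.0, spec.noise_sigma_suv, suv.shape)
    suv = np.clip(suv, 0.0, None)

    return PhantomSample(
        ct=ct,
        suv=suv,
        truth_mask=nodule,
        truth_contour=_trace_closed_contour(nodule),
        spec=spec,
    )


def generate_cohort(
    base_spec: PhantomSpec,
    n: int,
    seed: int,
    radius_range_mm: tuple[float, float] = (3.0, 12.0),
    width_range_mm: tuple[float, float] = (2.0, 4.0),
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with jittered nodule radius and vessel geometry.

    Radius and vessel width are drawn uniformly from the given ranges and the
    vessel orientation uniformly over the circle; each sample receives a
    distinct RNG seed derived from ``seed``.  The cohort is fully reproducible
    from ``(base_spec, n, seed)``.
    """
    if n < 1:
        raise ParameterError("cohort size n must be >= 1")
    jitter = np.random.default_rng(np.random.SeedSequence(seed))
    children = np.random.SeedSequence(seed).spawn(n)
    samples = []
    for child in children:
        spec_i = dataclasses.replace(
            base_spec,
            nodule_radius_mm=float(jitter.uniform(*radius_range_mm)),
            vessel_width_mm=float(jitter.uniform(*width_range_mm)),
            vessel_angle_deg=float(jitter.uniform(0.0, 360.0)),
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        samples.append(generate_phantom(spec_i))
    return samples
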