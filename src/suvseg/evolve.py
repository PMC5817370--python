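"""Level-set evolution of an entropy-guided, joint-vector LBF energy.

The contour is the zero crossing of a level-set function phi (positive
inside).  Its energy has three parts:

* a local binary fitting (LBF) data term that fits Gaussian-weighted local
  means inside and outside the contour — here computed jointly on the CT
  gray channel and the SUV channel (rescaled to [0, 255] so the channels
  are commensurable), with the per-pixel residuals weighted by the SUV
  information-entropy edge guide;
* a length penalty nu * integral(delta(phi) |grad phi|) that keeps the
  contour smooth and shrinks thin spurs such as attached vessels;
* a distance-regularising penalty mu * integral((|grad phi| - 1)^2 / 2)
  that keeps phi close to a signed distance function, replacing explicit
  reinitialisation.

Minimisation is explicit gradient descent:

    d(phi)/dt = -delta(phi) (lambda1 e1 - lambda2 e2)
                + nu delta(phi) div(grad phi / |grad phi|)
                + mu (laplacian(phi) - div(grad phi / |grad phi|))

A classic single-channel, unguided LBF path is provided as the reference
baseline; the joint model reduces to it exactly when the SUV channel weight
is zero and the guide is neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import RunConfig
from .entropy import GuideField, build_guide_field
from .errors import EvolutionCollapsedError, NumericalBlowupError
from .initcontour import ContourPolyline, contour_to_mask
from .preprocess import PetCtSlice, RoiResult

__all__ = [
    "LevelSetState",
    "JointFit",
    "EvolutionResult",
    "heaviside_smooth",
    "dirac_smooth",
    "gaussian_fit",
    "pointwise_data_terms",
    "curvature",
    "total_energy",
    "step",
    "descend_fixed",
    "run",
    "run_classic_lbf",
]

_DEN_FLOOR = 1e-12


def heaviside_smooth(x, epsilon: float = 1.0):
    """Arctan-smoothed Heaviside H_eps(x) in (0, 1)."""
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(x, dtype=float) / epsilon))


def dirac_smooth(x, epsilon: float = 1.0):
    """Smoothed Dirac delta, the derivative of ``heaviside_smooth``."""
    x = np.asarray(x, dtype=float)
    return (epsilon / np.pi) / (epsilon**2 + x**2)


def _kconv(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian convolution, kernel truncated at 4 sigma, unit sum."""
    return ndimage.gaussian_filter(image, sigma, mode="reflect", truncate=4.0)


def gaussian_fit(
    channel: np.ndarray, phi: np.ndarray, sigma_g: float = 1.5, epsilon: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Local inside/outside fitting values f1, f2 of one intensity channel.

    f1 = K*(I H) / K*H  and  f2 = K*(I (1-H)) / K*(1-H)  with H = H_eps(phi).
    """
    channel = np.asarray(channel, dtype=float)
    h = heaviside_smooth(phi, epsilon)
    f1 = _kconv(channel * h, sigma_g) / np.maximum(_kconv(h, sigma_g), _DEN_FLOOR)
    hc = 1.0 - h
    f2 = _kconv(channel * hc, sigma_g) / np.maximum(_kconv(hc, sigma_g), _DEN_FLOOR)
    return f1, f2


@dataclass(frozen=True)
class JointFit:
    """Local fitting rasters of the CT/SUV joint vector."""

    f1_ct: np.ndarray
    f2_ct: np.ndarray
    f1_suv: np.ndarray
    f2_suv: np.ndarray
    sigma_g: float = 1.5
    Lambda1: float = 1.0
    Lambda2: float = 1.0

    @classmethod
    def compute(
        cls,
        ct: np.ndarray,
        suv: np.ndarray,
        phi: np.ndarray,
        sigma_g: float = 1.5,
        epsilon: float = 1.0,
        Lambda1: float = 1.0,
        Lambda2: float = 1.0,
    ) -> "JointFit":
        f1_ct, f2_ct = gaussian_fit(ct, phi, sigma_g, epsilon)
        f1_suv, f2_suv = gaussian_fit(suv, phi, sigma_g, epsilon)
        return cls(f1_ct, f2_ct, f1_suv, f2_suv, sigma_g, Lambda1, Lambda2)


def pointwise_data_terms(
    ct: np.ndarray,
    suv: np.ndarray,
    fit: JointFit,
    guide: GuideField | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Entropy-weighted joint squared residuals e1 (inside), e2 (outside)."""
    f1w = 1.0 if guide is None else guide.F1
    f2w = 1.0 if guide is None else guide.F2
    e1 = f1w * (
        fit.Lambda1 * (ct - fit.f1_ct) ** 2 + fit.Lambda2 * (suv - fit.f1_suv) ** 2
    )
    e2 = f2w * (
        fit.Lambda1 * (ct - fit.f2_ct) ** 2 + fit.Lambda2 * (suv - fit.f2_suv) ** 2
    )
    return e1, e2


def curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|) by central differences, |grad| floored."""
    gr, gc = np.gradient(np.asarray(phi, dtype=float))
    norm = np.maximum(np.sqrt(gr**2 + gc**2), 1e-10)
    return np.gradient(gr / norm, axis=0) + np.gradient(gc / norm, axis=1)


@dataclass
class LevelSetState:
    """The evolving level-set function and its evolution parameters."""

    phi: np.ndarray
    k: int = 0
    F_k: float = np.nan
    dt: float = 0.1
    epsilon: float = 1.0
    nu: float = 0.001 * 255.0**2
    mu: float = 1.0
    chi: float = 1e-3
    k_max: int = 300
    lambda1: float = 1.0
    lambda2: float = 1.0


def _energy_parts(
    e1: np.ndarray,
    e2: np.ndarray,
    phi: np.ndarray,
    state: LevelSetState,
    roi_mask: np.ndarray | None,
) -> tuple[float, float, float, float]:
    h = heaviside_smooth(phi, state.epsilon)
    fit_density = state.lambda1 * e1 * h + state.lambda2 * e2 * (1.0 - h)
    gr, gc = np.gradient(phi)
    norm = np.sqrt(gr**2 + gc**2)
    length_density = dirac_smooth(phi, state.epsilon) * norm
    penalty_density = 0.5 * (norm - 1.0) ** 2
    if roi_mask is not None:
        fit_density = fit_density[roi_mask]
        length_density = length_density[roi_mask]
        penalty_density = penalty_density[roi_mask]
    e_fit = float(np.sum(fit_density))
    length = float(np.sum(length_density))
    penalty = float(np.sum(penalty_density))
    total = e_fit + state.nu * length + state.mu * penalty
    return total, e_fit, length, penalty


def total_energy(
    ct: np.ndarray,
    suv: np.ndarray,
    fit: JointFit,
    guide: GuideField | None,
    state: LevelSetState,
    roi_mask: np.ndarray | None = None,
) -> float:
    """Total energy F = E' + nu*L + mu*P (grid sums, unit pixel measure)."""
    e1, e2 = pointwise_data_terms(ct, suv, fit, guide)
    total, *_ = _energy_parts(e1, e2, state.phi, state, roi_mask)
    if not np.isfinite(total):
        raise NumericalBlowupError("level-set energy is not finite")
    return total


def _force(
    e1: np.ndarray, e2: np.ndarray, phi: np.ndarray, state: LevelSetState
) -> np.ndarray:
    delta = dirac_smooth(phi, state.epsilon)
    kappa = curvature(phi)
    lap = ndimage.laplace(phi)
    return (
        -delta * (state.lambda1 * e1 - state.lambda2 * e2)
        + state.nu * delta * kappa
        + state.mu * (lap - kappa)
    )


def step(
    state: LevelSetState,
    ct: np.ndarray,
    suv: np.ndarray,
    fit: JointFit,
    guide: GuideField | None = None,
    roi_mask: np.ndarray | None = None,
) -> LevelSetState:
    """One explicit gradient-descent update of phi (no step-size control)."""
    e1, e2 = pointwise_data_terms(ct, suv, fit, guide)
    force = _force(e1, e2, state.phi, state)
    if roi_mask is not None:
        force = np.where(roi_mask, force, 0.0)
    phi_new = state.phi + state.dt * force
    if not np.all(np.isfinite(phi_new)):
        raise NumericalBlowupError("phi became non-finite during the update")
    return replace(state, phi=phi_new, k=state.k + 1)


def descend_fixed(
    state: LevelSetState,
    ct: np.ndarray,
    suv: np.ndarray,
    fit: JointFit,
    guide: GuideField | None,
    n_steps: int,
    roi_mask: np.ndarray | None = None,
    max_halvings: int = 6,
) -> tuple[LevelSetState, list[float]]:
    """Gradient descent with frozen fit/guide fields and dt halving.

    With the fitting values and guide weights held fixed the update is the
    exact descent direction of the energy; whenever a step would raise the
    energy the step is rejected and dt halved (up to ``max_halvings``).
    Returns the final state and the accepted energy trace.
    """
    e1, e2 = pointwise_data_terms(ct, suv, fit, guide)
    f0, *_ = _energy_parts(e1, e2, state.phi, state, roi_mask)
    energies = [f0]
    halvings = 0
    current = state
    while current.k - state.k < n_steps:
        trial = step(current, ct, suv, fit, guide, roi_mask)
        f_trial, *_ = _energy_parts(e1, e2, trial.phi, current, roi_mask)
        if f_trial > energies[-1] + 1e-6 * abs(f0) and halvings < max_halvings:
            current = replace(current, dt=current.dt / 2.0)
            halvings += 1
            continue
        current = replace(trial, dt=current.dt, F_k=f_trial)
        energies.append(f_trial)
    return current, energies


@dataclass(frozen=True)
class EvolutionResult:
    """Final mask, energy trace and stopping diagnostics of one evolution."""

    mask: np.ndarray
    trace: pd.DataFrame  # columns: k, E_fit, length, penalty, F, dt
    stop_reason: str  # "converged" | "max_iterations"
    n_iter: int
    phi: np.ndarray
    dt_final: float


def _initial_phi(init, shape: tuple[int, int]) -> np.ndarray:
    """Signed Euclidean distance to the initial contour, positive inside."""
    if isinstance(init, ContourPolyline):
        mask = contour_to_mask(init, shape)
    else:
        mask = np.asarray(init, dtype=bool)
    if not mask.any():
        raise EvolutionCollapsedError("initial contour encloses no pixels")
    return ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(
        ~mask
    )


def _crop_box(roi_mask: np.ndarray, pad: int, shape: tuple[int, int]):
    rows = np.any(roi_mask, axis=1).nonzero()[0]
    cols = np.any(roi_mask, axis=0).nonzero()[0]
    r0 = max(int(rows[0]) - pad, 0)
    r1 = min(int(rows[-1]) + pad + 1, shape[0])
    c0 = max(int(cols[0]) - pad, 0)
    c1 = min(int(cols[-1]) + pad + 1, shape[1])
    return slice(r0, r1), slice(c0, c1)


def _seed_in_crop(roi: RoiResult | None, box) -> tuple[int, int] | None:
    if roi is None:
        return None
    return (roi.center_O[0] - box[0].start, roi.center_O[1] - box[1].start)


def _check_zero_crossing(phi: np.ndarray, roi_mask: np.ndarray) -> None:
    inside = (phi >= 0) & roi_mask
    n = int(inside.sum())
    if n == 0 or n == int(roi_mask.sum()):
        raise EvolutionCollapsedError("zero level set vanished inside the ROI")


def rescale_to_255(channel: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Min-max rescale a channel to [0, 255] over ``mask`` (or the grid)."""
    channel = np.asarray(channel, dtype=float)
    ref = channel if mask is None else channel[mask]
    lo, hi = float(ref.min()), float(ref.max())
    if hi <= lo:
        return np.zeros_like(channel)
    return (channel - lo) * (255.0 / (hi - lo))


def run(
    sl: PetCtSlice,
    roi: RoiResult | None,
    init: ContourPolyline | np.ndarray,
    config: RunConfig | None = None,
) -> EvolutionResult:
    """Full entropy-guided joint-vector evolution from an initial contour.

    The computation is restricted to the ROI disk (when given) on a crop
    padded by the entropy radius; phi starts as the signed distance to the
    initial contour and is updated until the energy is stable
    (|F_k - F_(k-1)| <= chi) or ``k_max`` iterations are reached.
    """
    cfg = (config or RunConfig()).validate()
    shape = sl.ct.shape
    roi_full = roi.roi_mask if roi is not None else np.ones(shape, dtype=bool)
    box = _crop_box(roi_full, pad=cfg.r_px, shape=shape)
    ct = sl.ct[box].astype(float)
    suv_raw = sl.suv[box].astype(float)
    roi_mask = roi_full[box]
    suv_scaled = rescale_to_255(suv_raw, roi_mask)
    phi = _initial_phi(init, shape)[box]

    state = LevelSetState(
        phi=phi,
        dt=cfg.dt,
        epsilon=cfg.epsilon,
        nu=cfg.nu,
        mu=cfg.mu,
        chi=cfg.chi,
        k_max=cfg.k_max,
        lambda1=cfg.lambda1,
        lambda2=cfg.lambda2,
    )

    def fields(phi_now):
        fit = JointFit.compute(
            ct,
            suv_scaled,
            phi_now,
            sigma_g=cfg.sigma_g,
            epsilon=cfg.epsilon,
            Lambda1=cfg.Lambda1,
            Lambda2=cfg.Lambda2,
        )
        if cfg.use_entropy_guide:
            guide = build_guide_field(
                suv_raw,
                phi_now,
                radius_r_px=cfg.r_px,
                band_px=cfg.band_px,
                sigma_floor=cfg.sigma_floor,
            )
        else:
            guide = None
        return pointwise_data_terms(ct, suv_scaled, fit, guide)

    seed_point = _seed_in_crop(roi, box)
    return _evolution_loop(state, fields, roi_mask, cfg, box, shape, seed_point)


def _select_component(mask: np.ndarray, seed_point: tuple[int, int] | None):
    """Keep the mask component holding the SUV seed (else the largest).

    The zero level set may split into several closed curves while an
    attached vessel is being carved away; the nodule is the component
    containing the maximum-SUV pixel the ROI was built from.
    """
    labels, n_labels = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_labels <= 1:
        return mask
    target = 0
    if seed_point is not None:
        target = int(labels[seed_point])
    if target == 0:
        areas = ndimage.sum_labels(
            np.ones_like(labels), labels, range(1, n_labels + 1)
        )
        target = int(np.argmax(areas)) + 1
    return labels == target


def _evolution_loop(state, fields, roi_mask, cfg, box, shape, seed_point=None):
    phi = state.phi
    crop_all = np.ones_like(roi_mask)
    _check_zero_crossing(phi, crop_all)
    e1, e2 = fields(phi)
    f_prev, e_fit, length, penalty = _energy_parts(e1, e2, phi, state, None)
    if not np.isfinite(f_prev):
        raise NumericalBlowupError("initial energy is not finite")
    f0 = f_prev
    dt = state.dt
    halvings = 0
    rows = [(0, e_fit, length, penalty, f_prev, dt)]
    stop_reason = "max_iterations"
    k = 0
    f_frozen = f_prev
    force = _force(e1, e2, phi, state)
    while k < state.k_max:
        # line search against the energy of the *current* fields: the fields
        # are re-estimated every iteration, so descent is only well defined
        # per step with the fields frozen
        phi_trial = phi + dt * force
        if not np.all(np.isfinite(phi_trial)):
            raise NumericalBlowupError("phi became non-finite during the update")
        f_trial, *_ = _energy_parts(e1, e2, phi_trial, state, None)
        if (
            f_trial > f_frozen + 1e-6 * abs(f0)
            and halvings < cfg.max_dt_halvings
        ):
            dt /= 2.0
            halvings += 1
            continue
        _check_zero_crossing(phi_trial, crop_all)
        e1, e2 = fields(phi_trial)
        f_new, e_fit, length, penalty = _energy_parts(
            e1, e2, phi_trial, state, None
        )
        if not np.isfinite(f_new):
            raise NumericalBlowupError("level-set energy is not finite")
        k += 1
        phi = phi_trial
        rows.append((k, e_fit, length, penalty, f_new, dt))
        if abs(f_new - f_prev) <= state.chi:
            stop_reason = "converged"
            f_prev = f_new
            break
        f_prev = f_new
        f_frozen = f_new
        force = _force(e1, e2, phi, state)

    mask_crop = (phi >= 0) & roi_mask
    mask_crop = _select_component(mask_crop, seed_point)
    mask_full = np.zeros(shape, dtype=bool)
    mask_full[box] = mask_crop
    phi_full = np.full(shape, -np.inf)
    phi_full[box] = phi
    trace = pd.DataFrame(
        rows, columns=["k", "E_fit", "length", "penalty", "F", "dt"]
    )
    return EvolutionResult(
        mask=mask_full,
        trace=trace,
        stop_reason=stop_reason,
        n_iter=k,
        phi=phi_full,
        dt_final=dt,
    )


def run_classic_lbf(
    sl: PetCtSlice,
    roi: RoiResult | None,
    init: ContourPolyline | np.ndarray,
    config: RunConfig | None = None,
) -> EvolutionResult:
    """Reference classic LBF evolution: CT channel only, no edge guide.

    Kept as an independently assembled baseline; the joint model with
    ``Lambda2 = 0`` and ``use_entropy_guide = False`` reproduces it exactly.
    """
    cfg = (config or RunConfig()).validate()
    shape = sl.ct.shape
    roi_full = roi.roi_mask if roi is not None else np.ones(shape, dtype=bool)
    box = _crop_box(roi_full, pad=cfg.r_px, shape=shape)
    ct = sl.ct[box].astype(float)
    roi_mask = roi_full[box]
    phi = _initial_phi(init, shape)[box]

    state = LevelSetState(
        phi=phi,
        dt=cfg.dt,
        epsilon=cfg.epsilon,
        nu=cfg.nu,
        mu=cfg.mu,
        chi=cfg.chi,
        k_max=cfg.k_max,
        lambda1=cfg.lambda1,
        lambda2=cfg.lambda2,
    )

    def fields(phi_now):
        f1, f2 = gaussian_fit(ct, phi_now, cfg.sigma_g, cfg.epsilon)
        e1 = cfg.Lambda1 * (ct - f1) ** 2
        e2 = cfg.Lambda1 * (ct - f2) ** 2
        return e1, e2

    seed_point = _seed_in_crop(roi, box)
    return _evolution_loop(state, fields, roi_mask, cfg, box, shape, seed_point)
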