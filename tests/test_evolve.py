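"""Level-set primitives, energies, descent and the evolution driver."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from suvseg import (
    JointFit,
    LevelSetState,
    RunConfig,
    curvature,
    dice,
    dirac_smooth,
    extract_roi,
    gaussian_fit,
    heaviside_smooth,
    run,
    run_classic_lbf,
    total_energy,
)
from suvseg.errors import NumericalBlowupError
from suvseg.evolve import descend_fixed, pointwise_data_terms, step
from tests.conftest import to_slice


def signed_distance(mask):
    mask = mask.astype(bool)
    return ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(
        ~mask
    )


class TestSmoothedStepFunctions:
    def test_heaviside_identities(self):
        assert heaviside_smooth(0.0, 1.0) == pytest.approx(0.5)
        assert heaviside_smooth(1.0, 1.0) == pytest.approx(0.75)
        assert heaviside_smooth(2.0, 2.0) == pytest.approx(0.75)
        assert heaviside_smooth(1e9, 1.0) == pytest.approx(1.0, abs=1e-6)
        assert heaviside_smooth(-1e9, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_dirac_identities_and_normalisation(self):
        assert dirac_smooth(0.0, 1.0) == pytest.approx(1.0 / np.pi)
        assert dirac_smooth(1.0, 1.0) == pytest.approx(1.0 / (2.0 * np.pi))
        x = np.linspace(-1000.0, 1000.0, 2_000_001)
        integral = np.trapezoid(dirac_smooth(x, 1.0), x)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_dirac_is_derivative_of_heaviside(self):
        x = np.linspace(-3, 3, 601)
        numeric = np.gradient(heaviside_smooth(x, 1.0), x)
        assert np.allclose(numeric[5:-5], dirac_smooth(x, 1.0)[5:-5], atol=1e-3)


class TestGaussianFit:
    def test_constant_channel_fits_constant(self):
        phi = signed_distance(np.pad(np.ones((6, 6), bool), 7))
        f1, f2 = gaussian_fit(np.full(phi.shape, 42.0), phi, sigma_g=1.5)
        assert np.allclose(f1, 42.0)
        assert np.allclose(f2, 42.0)

    def test_step_image_matches_direct_convolution_oracle(self):
        n = 20
        channel = np.where(np.arange(n)[None, :] < 10, 150.0, 50.0).repeat(n, 0)
        mask = np.zeros((n, n), bool)
        mask[:, :10] = True
        phi = signed_distance(mask)
        f1, f2 = gaussian_fit(channel, phi, sigma_g=1.5, epsilon=1.0)
        # oracle: explicit truncated-kernel convolution (valid in the interior)
        radius = int(4 * 1.5 + 0.5)
        k1 = np.exp(-0.5 * (np.arange(-radius, radius + 1) / 1.5) ** 2)
        k1 /= k1.sum()
        kern = np.outer(k1, k1)
        h = heaviside_smooth(phi, 1.0)
        for r, c in [(9, 9), (10, 7), (9, 13), (12, 8)]:
            patch = slice(r - radius, r + radius + 1), slice(c - radius, c + radius + 1)
            num = (kern * (channel * h)[patch]).sum()
            den = (kern * h[patch]).sum()
            assert f1[r, c] == pytest.approx(num / den, rel=1e-10)
        assert f1[10, 4] == pytest.approx(150.0, abs=1.0)
        assert f2[10, 16] == pytest.approx(50.0, abs=1.0)


class TestDataTerms:
    def test_zero_residual_gives_zero(self):
        ct = np.full((8, 8), 90.0)
        fit = JointFit(ct, ct, ct * 0, ct * 0)
        e1, e2 = pointwise_data_terms(ct, ct * 0, fit)
        assert np.all(e1 == 0) and np.all(e2 == 0)

    def test_channel_gating_and_loop_oracle(self, rng):
        ct = rng.uniform(0, 255, (8, 8))
        suv = rng.uniform(0, 255, (8, 8))
        fits = [rng.uniform(0, 255, (8, 8)) for _ in range(4)]
        fit = JointFit(*fits, Lambda1=1.0, Lambda2=0.7)
        e1, e2 = pointwise_data_terms(ct, suv, fit)
        for r in range(8):
            for c in range(8):
                want1 = (ct[r, c] - fits[0][r, c]) ** 2 + 0.7 * (
                    suv[r, c] - fits[2][r, c]
                ) ** 2
                want2 = (ct[r, c] - fits[1][r, c]) ** 2 + 0.7 * (
                    suv[r, c] - fits[3][r, c]
                ) ** 2
                assert e1[r, c] == pytest.approx(want1, rel=1e-12)
                assert e2[r, c] == pytest.approx(want2, rel=1e-12)
        gated = JointFit(*fits, Lambda1=1.0, Lambda2=0.0)
        g1, _ = pointwise_data_terms(ct, suv, gated)
        assert np.allclose(g1, (ct - fits[0]) ** 2)


class TestCurvature:
    @pytest.mark.parametrize("rho", [10.0, 15.0, 20.0])
    def test_circle_signed_distance_curvature(self, rho):
        n = 64
        rows, cols = np.mgrid[0:n, 0:n].astype(float)
        phi = rho - np.hypot(rows - n / 2, cols - n / 2)
        kappa = curvature(phi)
        band = np.abs(phi) < 1.5
        assert np.abs(kappa[band]).mean() == pytest.approx(1.0 / rho, rel=0.10)

    def test_planar_phi_is_flat(self):
        rows, cols = np.mgrid[0:32, 0:32].astype(float)
        phi = 0.7 * rows + 0.2 * cols - 10.0
        assert np.abs(curvature(phi))[2:-2, 2:-2].max() < 1e-10

    def test_monotone_in_inverse_radius(self):
        n, c = 96, 48.0
        rows, cols = np.mgrid[0:n, 0:n].astype(float)
        means = []
        for rho in (12.0, 24.0):
            phi = rho - np.hypot(rows - c, cols - c)
            kappa = curvature(phi)
            means.append(np.abs(kappa[np.abs(phi) < 1.5]).mean())
        assert means[0] > means[1]


class TestTotalEnergy:
    def test_signed_distance_has_negligible_penalty(self):
        mask = np.zeros((40, 40), bool)
        mask[12:28, 12:28] = True
        phi = signed_distance(mask)
        ct = np.full(phi.shape, 100.0)
        fit = JointFit(ct, ct, ct * 0, ct * 0)
        state = LevelSetState(phi=phi, nu=0.0, mu=1.0)
        f = total_energy(ct, ct * 0, fit, None, state)
        # data and length terms are off/zero-residual; remaining P is small
        assert f < 0.05 * phi.size

    def test_matches_triple_loop_oracle(self, rng):
        ct = rng.uniform(0, 255, (8, 8))
        suv = rng.uniform(0, 255, (8, 8))
        fits = [rng.uniform(0, 255, (8, 8)) for _ in range(4)]
        phi = rng.normal(0, 2, (8, 8))
        fit = JointFit(*fits)
        state = LevelSetState(phi=phi, nu=3.0, mu=0.5, epsilon=1.0)
        got = total_energy(ct, suv, fit, None, state)

        def grad_rows(a):
            g = np.zeros_like(a)
            g[1:-1] = (a[2:] - a[:-2]) / 2.0
            g[0] = a[1] - a[0]
            g[-1] = a[-1] - a[-2]
            return g

        e_fit = length = penalty = 0.0
        gr = np.apply_along_axis(grad_rows, 0, phi)
        gc = np.apply_along_axis(grad_rows, 1, phi)
        for r in range(8):
            for c in range(8):
                e1 = (ct[r, c] - fits[0][r, c]) ** 2 + (suv[r, c] - fits[2][r, c]) ** 2
                e2 = (ct[r, c] - fits[1][r, c]) ** 2 + (suv[r, c] - fits[3][r, c]) ** 2
                h = 0.5 * (1 + 2 / np.pi * np.arctan(phi[r, c]))
                d = 1.0 / (np.pi * (1 + phi[r, c] ** 2))
                norm = np.hypot(gr[r, c], gc[r, c])
                e_fit += e1 * h + e2 * (1 - h)
                length += d * norm
                penalty += 0.5 * (norm - 1.0) ** 2
        assert got == pytest.approx(e_fit + 3.0 * length + 0.5 * penalty, rel=1e-10)


class TestStep:
    def test_balanced_data_force_leaves_only_regulariser(self):
        mask = np.zeros((24, 24), bool)
        mask[8:16, 8:16] = True
        phi = signed_distance(mask)
        ct = np.full(phi.shape, 80.0)
        fit = JointFit(ct, ct, ct * 0, ct * 0)  # e1 == e2 == 0
        state = LevelSetState(phi=phi, nu=0.0, mu=1.0, dt=0.05)
        new = step(state, ct, ct * 0, fit)
        expected = phi + 0.05 * (ndimage.laplace(phi) - curvature(phi))
        assert np.allclose(new.phi, expected)
        assert new.k == 1

    def test_inside_misfit_pushes_phi_down(self):
        mask = np.zeros((16, 16), bool)
        mask[5:11, 5:11] = True
        phi = signed_distance(mask)
        ct = np.full(phi.shape, 100.0)
        f1 = np.full(phi.shape, 0.0)  # inside fit badly wrong -> e1 large
        f2 = ct.copy()  # outside fit perfect -> e2 = 0
        fit = JointFit(f1, f2, ct * 0, ct * 0)
        state = LevelSetState(phi=phi, nu=0.0, mu=0.0, dt=0.01)
        new = step(state, ct, ct * 0, fit)
        boundary = np.abs(phi) < 1.0
        assert (new.phi[boundary] < phi[boundary]).all()

    def test_nonfinite_phi_raises(self):
        phi = np.full((8, 8), np.inf)
        ct = np.zeros((8, 8))
        fit = JointFit(ct, ct, ct, ct)
        with pytest.raises(NumericalBlowupError):
            step(LevelSetState(phi=phi), ct, ct, fit)


class TestDescendFixed:
    def test_energy_nonincreasing_on_fixed_fields(self, rng):
        mask = np.zeros((32, 32), bool)
        mask[10:22, 8:20] = True
        phi = signed_distance(mask) + 1.5
        ct = np.clip(rng.normal(100, 20, phi.shape), 0, 255)
        fit = JointFit.compute(ct, ct * 0, phi)
        state = LevelSetState(phi=phi, dt=0.01)
        _, energies = descend_fixed(state, ct, ct * 0, fit, None, 60)
        e = np.array(energies)
        assert (np.diff(e) <= 1e-6 * abs(e[0])).all()


class TestDistanceRegulariser:
    def test_pure_regulariser_restores_unit_gradient(self):
        mask = np.zeros((40, 40), bool)
        mask[12:28, 12:28] = True
        phi = 2.0 * signed_distance(mask)  # steepened by a factor 2
        ct = np.full(phi.shape, 50.0)
        fit = JointFit(ct, ct, ct * 0, ct * 0)  # zero data force
        state = LevelSetState(phi=phi, nu=0.0, mu=1.0, dt=0.2)
        for _ in range(400):
            state = step(state, ct, ct * 0, fit)
        gr, gc = np.gradient(state.phi)
        norm = np.hypot(gr, gc)
        band = np.abs(state.phi) < 5.0
        assert 0.8 <= norm[band].mean() <= 1.2


class TestRunDriver:
    def test_zero_iterations_returns_initial_mask(self, noiseless_sample):
        sl = to_slice(noiseless_sample)
        roi = extract_roi(sl)
        cfg = dataclasses.replace(RunConfig(), k_max=0)
        res = run(sl, roi, noiseless_sample.truth_mask, cfg)
        assert np.array_equal(res.mask, noiseless_sample.truth_mask)
        assert res.n_iter == 0

    def test_perfect_start_does_not_degrade(self, noiseless_sample):
        sl = to_slice(noiseless_sample)
        roi = extract_roi(sl)
        res = run(sl, roi, noiseless_sample.truth_mask, RunConfig())
        assert dice(noiseless_sample.truth_mask, res.mask) >= 99.5

    def test_dice_improves_over_first_iterations(self, phantom_sample):
        from suvseg import binarize, iterate_threshold, select_initial_contour
        from suvseg.initcontour import contour_to_mask

        sl = to_slice(phantom_sample)
        roi = extract_roi(sl)
        tstate = iterate_threshold(sl.ct, 0.1, mask=roi.roi_mask)
        binary = binarize(sl.ct, tstate.T)
        binary[~roi.roi_mask] = 0
        init = select_initial_contour(binary)
        dsc0 = dice(phantom_sample.truth_mask, contour_to_mask(init, sl.ct.shape))
        cfg = dataclasses.replace(RunConfig(), k_max=50)
        res = run(sl, roi, init, cfg)
        assert dice(phantom_sample.truth_mask, res.mask) > dsc0

    def test_energy_trace_columns(self, noiseless_sample):
        sl = to_slice(noiseless_sample)
        roi = extract_roi(sl)
        cfg = dataclasses.replace(RunConfig(), k_max=5)
        res = run(sl, roi, noiseless_sample.truth_mask, cfg)
        assert list(res.trace.columns) == ["k", "E_fit", "length", "penalty", "F", "dt"]
        assert len(res.trace) == res.n_iter + 1

    def test_classic_baseline_keeps_vessel(self, phantom_sample):
        from suvseg import binarize, iterate_threshold, select_initial_contour

        sl = to_slice(phantom_sample)
        roi = extract_roi(sl)
        tstate = iterate_threshold(sl.ct, 0.1, mask=roi.roi_mask)
        binary = binarize(sl.ct, tstate.T)
        binary[~roi.roi_mask] = 0
        init = select_initial_contour(binary)
        cfg = dataclasses.replace(RunConfig(), k_max=60)
        base = run_classic_lbf(sl, roi, init, cfg)
        # gray-only LBF cannot separate the vessel: large false positive area
        overlap = (base.mask & phantom_sample.vessel_mask).sum()
        assert overlap > 0
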