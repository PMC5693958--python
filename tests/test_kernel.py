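"""Depth kernel assembly and per-frequency eigenanalysis: Gram structure,
closed-form eigenproblems, rotational symmetry, and spectrum normalization."""

import numpy as np
import pytest

from cpet.alpha import RangeEnergyModel, alpha_prf_grid, sensitivity
from cpet.geometry import DepthGrid
from cpet.kernel import (
    DepthKernel,
    build_depth_kernel,
    eigendecompose_kernel,
    interpolate_kernel,
    kernel_at_vector,
    normalized_spectrum,
    radial_frequency_samples,
)
from cpet.listmode import AttributeSpec, BinSpec, PRFGrid


def _scaled_prf(prf: PRFGrid, factor: float) -> PRFGrid:
    return PRFGrid(
        attrs=prf.attrs, bins=prf.bins, depths_um=prf.depths_um,
        sensitivity=prf.sensitivity * factor, iz=prf.iz, ix=prf.ix, iy=prf.iy,
        itheta=prf.itheta, iphi=prf.iphi, ie=prf.ie, mass=prf.mass * factor,
        n_out_of_range=prf.n_out_of_range, meta=prf.meta,
    )


class TestKernelBuild:
    def test_zero_frequency_q2_is_sensitivity_outer_product(self, alpha_model):
        """At rho = 0 the position-only kernel is S(z) S(z') exactly."""
        grid = DepthGrid(np.array([5.0, 15.0, 25.0]), 40.0, 10.0)
        bins = BinSpec(4.0, 48.0, 5160.0)
        prf = alpha_prf_grid(grid.depths_um, AttributeSpec.position(), bins, alpha_model)
        k = build_depth_kernel(prf, grid, [0.0])
        s = np.array([sensitivity(z, alpha_model) for z in grid.depths_um])
        assert np.allclose(k.values[0], np.outer(s, s), rtol=1e-10)

    def test_single_depth_kernel_nonnegative(self, alpha_model):
        grid = DepthGrid(np.array([10.0]), 40.0, 2.0)
        bins = BinSpec(4.0, 48.0, 5160.0)
        prf = alpha_prf_grid(grid.depths_um, AttributeSpec.position(), bins, alpha_model)
        k = build_depth_kernel(prf, grid, radial_frequency_samples(bins.lateral_nyquist, 8))
        assert np.all(k.values >= -1e-15)

    def test_rotational_symmetry(self, small_alpha_system):
        """K built along (rho, 0) equals K built along (0, rho)."""
        sys = small_alpha_system
        for rho in (0.01, 0.05, 0.1):
            ka = kernel_at_vector(sys["prf"], sys["grid"], (rho, 0.0))
            kb = kernel_at_vector(sys["prf"], sys["grid"], (0.0, rho))
            assert np.allclose(ka, kb, rtol=1e-6, atol=1e-6 * np.abs(ka).max())

    def test_hermitian_psd_at_every_sample(self, small_alpha_system):
        k = small_alpha_system["kernel"]
        assert np.allclose(k.values, np.swapaxes(k.values, 1, 2), atol=1e-12)
        es = small_alpha_system["es"]
        assert es.mu.min() >= 0.0

    def test_frequency_above_lattice_limit_rejected(self, small_alpha_system):
        sys = small_alpha_system
        limit = np.sqrt(2) * sys["bins"].lateral_nyquist
        with pytest.raises(ValueError, match="Nyquist"):
            build_depth_kernel(sys["prf"], sys["grid"], [limit * 1.01])

    def test_mismatched_depths_rejected(self, small_alpha_system):
        sys = small_alpha_system
        other = DepthGrid(np.array([1.0, 2.0]), 40.0, 1.0)
        with pytest.raises(ValueError):
            build_depth_kernel(sys["prf"], other, [0.0])

    def test_hilbert_schmidt_norm_finite(self, small_alpha_system):
        k = small_alpha_system["kernel"]
        hs = np.sum(k.values**2, axis=(1, 2)) * k.dz_um**2
        assert np.all(np.isfinite(hs))


class TestEigendecomposition:
    def test_one_by_one_closed_form(self):
        grid = DepthGrid(np.array([10.0]), 40.0, 2.0)
        k = DepthKernel(np.array([0.0]), np.array([[[3.5]]]), grid.depths_um, 2.0, 0.125)
        es = eigendecompose_kernel(k, grid)
        assert es.mu[0, 0] == pytest.approx(3.5 * 2.0)
        assert es.w[0, 0, 0] == pytest.approx(1.0 / np.sqrt(2.0))

    def test_two_by_two_closed_form(self):
        grid = DepthGrid(np.array([1.0, 2.0]), 4.0, 1.0)
        a, b = 2.0, 0.5
        vals = np.array([[[a, b], [b, a]]])
        k = DepthKernel(np.array([0.0]), vals, grid.depths_um, 1.0, 0.125)
        es = eigendecompose_kernel(k, grid)
        assert np.allclose(np.sort(es.mu[0]), [a - b, a + b])

    def test_spectral_reconstruction(self, small_alpha_system):
        """sum_n mu_n w_n w_n^T (Dz-weighted) reproduces every K(rho)."""
        k, es = small_alpha_system["kernel"], small_alpha_system["es"]
        for i in range(0, k.rho.size, 8):
            w = es.w[i]
            # with the Dz-weighted normalization <w_n, w_m> dz = delta, the
            # reconstruction is K = sum_n mu_n w_n w_n^T
            rec = (w * es.mu[i]) @ w.T
            assert np.allclose(rec, k.values[i], atol=1e-8 * max(es.mu_max, 1.0))

    def test_eigenvector_weighted_orthonormality(self, small_alpha_system):
        es = small_alpha_system["es"]
        w = es.w[0]
        gram = w.T @ w * es.dz_um
        assert np.allclose(gram, np.eye(w.shape[1]), atol=1e-8)

    def test_trace_identity(self, small_alpha_system):
        """Sum of eigenvalues equals the Dz-weighted trace of K at each rho."""
        k, es = small_alpha_system["kernel"], small_alpha_system["es"]
        tr = np.trace(k.values, axis1=1, axis2=2) * es.dz_um
        assert np.allclose(es.mu.sum(axis=1), tr, rtol=1e-8)

    def test_asymmetric_kernel_rejected(self):
        grid = DepthGrid(np.array([1.0, 2.0]), 4.0, 1.0)
        vals = np.array([[[1.0, 0.2], [0.1, 1.0]]])
        k = DepthKernel(np.array([0.0]), vals, grid.depths_um, 1.0, 0.125)
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose_kernel(k, grid)


class TestNormalizedSpectrum:
    def test_self_normalization_unique_maximum(self, small_alpha_system):
        es = small_alpha_system["es"]
        tab = normalized_spectrum(es)
        assert tab.lam.max() == 1.0
        assert int((tab.lam == 1.0).sum()) == 1
        assert tab.lam.min() >= 0.0

    def test_non_increasing_in_mode_index(self, small_alpha_system):
        es = small_alpha_system["es"]
        assert np.all(np.diff(es.lam, axis=1) <= 1e-15)

    def test_scale_invariance(self, small_alpha_system, alpha_model):
        """Scaling every PRF mass leaves the normalized spectrum unchanged."""
        sys = small_alpha_system
        half = _scaled_prf(sys["prf"], 0.5)
        k2 = build_depth_kernel(half, sys["grid"], sys["kernel"].rho)
        es2 = eigendecompose_kernel(k2, sys["grid"])
        assert np.allclose(es2.lam, sys["es"].lam, atol=1e-10)

    def test_q2_zero_frequency_rank_one(self, alpha_model):
        """The position-only kernel at rho=0 is the rank-1 outer product S S^T."""
        grid = DepthGrid.alpha_default()
        bins = BinSpec.alpha_default()
        prf = alpha_prf_grid(grid.depths_um, AttributeSpec.position(), bins, alpha_model)
        k = build_depth_kernel(prf, grid, [0.0])
        es = eigendecompose_kernel(k, grid)
        assert int((es.lam[0] > 1e-6).sum()) == 1


class TestInterpolation:
    def test_doubling_refinement(self, small_alpha_system):
        """Halving the radial sample spacing changes the interpolated kernel
        little: the kernel is smooth in rho."""
        sys = small_alpha_system
        rho_max = np.sqrt(2) * sys["bins"].lateral_nyquist
        coarse = build_depth_kernel(sys["prf"], sys["grid"],
                                    radial_frequency_samples(rho_max, 33))
        fine = build_depth_kernel(sys["prf"], sys["grid"],
                                  radial_frequency_samples(rho_max, 65))
        scale = np.abs(fine.values).max()
        errs = [
            np.abs(interpolate_kernel(coarse, r) - fine.values[i]).max() / scale
            for i, r in enumerate(fine.rho)
        ]
        assert max(errs) < 0.02

    def test_out_of_range_rejected(self, small_alpha_system):
        with pytest.raises(ValueError):
            interpolate_kernel(small_alpha_system["kernel"],
                               small_alpha_system["kernel"].rho[-1] * 1.1)
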