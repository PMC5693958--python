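"""Phantom voxelization, projector identities of the measurement/null
decomposition, and the forward/adjoint operator pair."""

import numpy as np
import pytest

from cpet.decompose import (
    CylinderSpec,
    DataCube,
    VoxelObject,
    adjoint_backproject,
    build_test_object,
    decompose,
    forward_project,
    measurement_component,
    null_component,
    scaled_null_norm,
    seven_cylinder_phantom,
    _retained_projectors,
)
from cpet.geometry import DepthGrid, SlabGeometry, alpha_slab
from cpet.kernel import interpolate_kernel
from cpet.listmode import ListModeTable


@pytest.fixture()
def small_phantom_grid():
    slab = SlabGeometry(40.0, (96.0, 96.0))
    grid = DepthGrid(np.arange(2.5, 40.0, 5.0), 40.0, 5.0)
    return slab, grid


class TestPhantom:
    def test_empty_spec_list_gives_zero_object(self, small_phantom_grid):
        slab, grid = small_phantom_grid
        obj = build_test_object([], slab, grid, 4.0)
        assert np.all(obj.values == 0.0)

    def test_single_cylinder_volume_oracle(self):
        """Voxel count x voxel volume matches pi r^2 h within 2% at 1-um voxels."""
        slab = alpha_slab()
        grid = DepthGrid.alpha_default()
        c = CylinderSpec(0.0, 0.0, 12.0, 4.0, 12.0)
        obj = build_test_object([c], slab, grid, 1.0)
        vox = obj.values.sum() * obj.voxel_volume_um3
        assert vox == pytest.approx(c.volume_um3, rel=0.02)

    def test_default_phantom_total_activity(self):
        slab = alpha_slab()
        grid = DepthGrid.alpha_default()
        specs = seven_cylinder_phantom(slab)
        assert len(specs) == 7
        obj = build_test_object(specs, slab, grid, 1.0)
        total = obj.values.sum() * obj.voxel_volume_um3
        analytic = sum(c.density * c.volume_um3 for c in specs)
        assert total == pytest.approx(analytic, rel=0.02)

    def test_overlapping_cylinders_sum_densities(self, small_phantom_grid):
        slab, grid = small_phantom_grid
        c = CylinderSpec(0.0, 0.0, 10.0, 5.0, 10.0, density=1.0)
        one = build_test_object([c], slab, grid, 4.0)
        two = build_test_object([c, c], slab, grid, 4.0)
        assert np.allclose(two.values, 2 * one.values)

    def test_out_of_slab_cylinder_rejected(self, small_phantom_grid):
        slab, grid = small_phantom_grid
        with pytest.raises(ValueError):
            build_test_object([CylinderSpec(0.0, 0.0, 10.0, 35.0, 10.0)], slab, grid, 4.0)
        with pytest.raises(ValueError):
            build_test_object([CylinderSpec(45.0, 0.0, 10.0, 5.0, 10.0)], slab, grid, 4.0)


def _mode_object(sys, freq_index: int, depth_profile: np.ndarray) -> VoxelObject:
    """Real object: one lateral cosine mode times a depth profile."""
    bins, grid = sys["bins"], sys["grid"]
    n = bins.n_lateral
    fx = np.fft.fftfreq(n, d=bins.lateral_width_um)
    x = bins.lateral_centers_um
    lateral = np.cos(2 * np.pi * fx[freq_index] * x)[:, None] * np.ones((1, n))
    return VoxelObject(lateral[:, :, None] * depth_profile[None, None, :],
                       bins.lateral_width_um, grid)


class TestProjector:
    def test_retained_eigenprofile_is_fixed_point(self, small_alpha_system):
        sys = small_alpha_system
        k, es = sys["kernel"], sys["es"]
        idx = 3
        fx = np.fft.fftfreq(sys["bins"].n_lateral, d=sys["bins"].lateral_width_um)
        rho = abs(fx[idx])
        mu, y = np.linalg.eigh(interpolate_kernel(k, rho) * k.dz_um)
        lam_min = 1e-2
        retained = np.where(mu >= lam_min * es.mu_max)[0]
        assert retained.size > 0
        w = y[:, retained[-1]] / np.sqrt(k.dz_um)
        f = _mode_object(sys, idx, w)
        fm = measurement_component(f, k, es, lam_min)
        assert np.allclose(fm.values, f.values, atol=1e-8 * np.abs(f.values).max())

    def test_discarded_eigenprofile_is_annihilated(self, small_alpha_system):
        sys = small_alpha_system
        k, es = sys["kernel"], sys["es"]
        idx = 3
        fx = np.fft.fftfreq(sys["bins"].n_lateral, d=sys["bins"].lateral_width_um)
        rho = abs(fx[idx])
        mu, y = np.linalg.eigh(interpolate_kernel(k, rho) * k.dz_um)
        lam_min = 1e-2
        discarded = np.where(mu < lam_min * es.mu_max)[0]
        assert discarded.size > 0
        w = y[:, discarded[0]] / np.sqrt(k.dz_um)
        f = _mode_object(sys, idx, w)
        fm = measurement_component(f, k, es, lam_min)
        assert np.abs(fm.values).max() <= 1e-8 * np.abs(f.values).max()

    def test_idempotence(self, small_alpha_system):
        sys = small_alpha_system
        rng = np.random.default_rng(0)
        n = sys["bins"].n_lateral
        f = VoxelObject(rng.standard_normal((n, n, sys["grid"].n)),
                        sys["bins"].lateral_width_um, sys["grid"])
        once = measurement_component(f, sys["kernel"], sys["es"], 1e-3)
        twice = measurement_component(once, sys["kernel"], sys["es"], 1e-3)
        assert np.allclose(twice.values, once.values, atol=1e-8 * np.abs(once.values).max())

    def test_orthogonality_and_pythagoras(self, small_alpha_system):
        sys = small_alpha_system
        slab = sys["slab"]
        phantom = build_test_object(seven_cylinder_phantom(slab), slab, sys["grid"], 4.0)
        dec = decompose(phantom, sys["kernel"], sys["es"], 1e-3)
        f2 = phantom.norm() ** 2
        assert abs(dec.f_meas.inner(dec.f_null)) <= 1e-6 * f2
        split = dec.f_meas.norm() ** 2 + dec.f_null.norm() ** 2
        assert split == pytest.approx(f2, rel=1e-6)
        # Pythagorean identity for the scaled norm
        expect = np.sqrt(max(0.0, 1.0 - dec.f_meas.norm() ** 2 / f2))
        assert dec.scaled_null_norm == pytest.approx(expect, abs=1e-8)

    def test_null_component_trivial_cases(self, small_alpha_system):
        sys = small_alpha_system
        n = sys["bins"].n_lateral
        f = VoxelObject(np.ones((n, n, sys["grid"].n)), sys["bins"].lateral_width_um, sys["grid"])
        zero = VoxelObject(np.zeros_like(f.values), f.lateral_width_um, f.depth_grid)
        assert np.all(null_component(f, f).values == 0.0)
        assert np.allclose(null_component(f, zero).values, f.values)
        assert scaled_null_norm(zero, f) == 0.0
        assert scaled_null_norm(f, f) == 1.0
        with pytest.raises(ValueError):
            scaled_null_norm(zero, zero)

    def test_grid_mismatch_rejected(self, small_alpha_system):
        sys = small_alpha_system
        n = sys["bins"].n_lateral
        f = VoxelObject(np.ones((n, n, sys["grid"].n)), sys["bins"].lateral_width_um, sys["grid"])
        other = VoxelObject(np.ones((n, n, sys["grid"].n)), 2.0, sys["grid"])
        with pytest.raises(ValueError):
            null_component(f, other)

    def test_lambda_min_domain(self, small_alpha_system):
        sys = small_alpha_system
        n = sys["bins"].n_lateral
        f = VoxelObject(np.zeros((n, n, sys["grid"].n)), sys["bins"].lateral_width_um, sys["grid"])
        with pytest.raises(ValueError):
            measurement_component(f, sys["kernel"], sys["es"], 0.0)


class TestForwardAdjoint:
    def test_zero_object_zero_data(self, small_alpha_system):
        sys = small_alpha_system
        n = sys["bins"].n_lateral
        f = VoxelObject(np.zeros((n, n, sys["grid"].n)), sys["bins"].lateral_width_um, sys["grid"])
        u = forward_project(f, sys["prf"])
        assert np.all(u.values == 0.0)
        bp = adjoint_backproject(u, sys["prf"], f_template=f)
        assert np.all(bp.values == 0.0)

    def test_point_source_reproduces_prf_slice(self, small_alpha_system):
        """A unit point source at a grid node forward-projects to its PRF
        slice (shifted to the source's lateral bin)."""
        sys = small_alpha_system
        bins, grid, prf = sys["bins"], sys["grid"], sys["prf"]
        n = bins.n_lateral
        iz, ix0, iy0 = 1, n // 2 + 3, n // 2 - 2
        vals = np.zeros((n, n, grid.n))
        vals[ix0, iy0, iz] = 1.0
        f = VoxelObject(vals, bins.lateral_width_um, grid)
        u = forward_project(f, prf)
        dense = prf.to_dense(iz)  # (x, y, E) here
        dv = f.voxel_volume_um3
        for bi, key in enumerate(u.keys):
            aligned = np.roll(dense[:, :, key], (-(n // 2), -(n // 2)), axis=(0, 1))
            expected = dv * np.roll(aligned, (ix0, iy0), axis=(0, 1))
            assert np.allclose(u.values[bi], expected, atol=1e-12)

    def test_adjoint_identity(self, small_alpha_system):
        """<u, L f> (plain data sum) equals <L† u, f> (voxel-volume-weighted)."""
        sys = small_alpha_system
        rng = np.random.default_rng(7)
        n = sys["bins"].n_lateral
        f = VoxelObject(rng.standard_normal((n, n, sys["grid"].n)),
                        sys["bins"].lateral_width_um, sys["grid"])
        lf = forward_project(f, sys["prf"])
        u = DataCube(rng.standard_normal(lf.values.shape), lf.keys, lf.attrs, lf.bins)
        lhs = float(np.sum(u.values * lf.values))
        bp = adjoint_backproject(u, sys["prf"], f_template=f)
        rhs = bp.inner(f)
        assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_single_event_backprojection_is_prf_profile(self, small_alpha_system):
        """The point-process adjoint of one event returns the PRF mass at that
        event's attribute bin, laid out over (r, z)."""
        sys = small_alpha_system
        bins, prf = sys["bins"], sys["prf"]
        n = bins.n_lateral
        t = ListModeTable.from_arrays([1.0], [1.0], [0.0], [0.0], [1000.0],
                                      {"depth_um": sys["grid"].depths_um[0]})
        bp = adjoint_backproject(t, prf)
        ie = np.searchsorted(bins.energy_edges_kev, 1000.0, side="right") - 1
        ix0 = np.searchsorted(bins.lateral_edges_um, 1.0, side="right") - 1
        for iz in range(prf.n_depths):
            kz, slices = prf.lateral_slices(iz)
            want = np.zeros((n, n))
            if ie in kz:
                # brute force: bp[r] = p_aligned[(event_bin - r) mod n]
                aligned = np.roll(slices[list(kz).index(ie)], (-(n // 2), -(n // 2)), axis=(0, 1))
                want = np.roll(aligned[::-1, ::-1], (ix0 + 1, ix0 + 1), axis=(0, 1))
            assert np.allclose(bp.values[:, :, iz], want, atol=1e-12)

    def test_mismatched_grids_rejected(self, small_alpha_system):
        sys = small_alpha_system
        n = sys["bins"].n_lateral
        f = VoxelObject(np.zeros((n, n, sys["grid"].n)), 2.0, sys["grid"])
        with pytest.raises(ValueError):
            forward_project(f, sys["prf"])
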