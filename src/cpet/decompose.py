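"""Test object, measurement/null decomposition, and forward/adjoint operators.

An object f(R) is decomposed into the part recoverable from noise-free data
(the measurement component, the projection onto eigenfunctions of L†L with
normalized eigenvalue above a cutoff) and the invisible remainder (the null
component).  Thanks to lateral shift invariance the projector acts per 2-D
spatial frequency on the depth profile of the object's lateral DFT, using the
depth-kernel eigenvectors at that radial frequency.

The scaled null norm ``||f_null|| / ||f||`` (voxel-volume-weighted L2)
summarizes how much of the object a given detector configuration cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .geometry import DepthGrid, SlabGeometry
from .kernel import DepthKernel, EigenSystem, interpolate_kernel
from .listmode import AttributeSpec, BinSpec, ListModeTable, PRFGrid, histogram_listmode

__all__ = [
    "CylinderSpec",
    "VoxelObject",
    "Decomposition",
    "DataCube",
    "seven_cylinder_phantom",
    "build_test_object",
    "measurement_component",
    "null_component",
    "scaled_null_norm",
    "decompose",
    "forward_project",
    "adjoint_backproject",
]


@dataclass(frozen=True)
class CylinderSpec:
    """z-axis-aligned cylinder of uniform activity density (lengths in um)."""

    cx_um: float
    cy_um: float
    radius_um: float
    top_um: float
    height_um: float
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.height_um <= 0:
            raise ValueError("cylinder radius and height must be positive")
        if self.density < 0:
            raise ValueError("activity density must be nonnegative")

    @property
    def volume_um3(self) -> float:
        return float(np.pi * self.radius_um**2 * self.height_um)


def seven_cylinder_phantom(slab: SlabGeometry) -> list[CylinderSpec]:
    """The default 7-cylinder test object, scaled to the slab thickness.

    The shipped configuration stores all lengths as fractions of the slab
    thickness, so the same object serves the 40-um alpha and 100-um beta
    geometries.
    """
    text = resources.files("cpet").joinpath("data/phantom7.yaml").read_text()
    cfg = yaml.safe_load(text)
    t = slab.thickness_um
    return [
        CylinderSpec(
            cx_um=c["cx"] * t,
            cy_um=c["cy"] * t,
            radius_um=c["radius"] * t,
            top_um=c["top"] * t,
            height_um=c["height"] * t,
            density=float(c.get("density", 1.0)),
        )
        for c in cfg["cylinders"]
    ]


@dataclass
class VoxelObject:
    """Object function on a voxel grid aligned with the depth samples.

    ``values[ix, iy, iz]``; lateral voxels of width ``lateral_width_um``
    centered on the detector footprint, depth slices of thickness ``dz``
    centered on the DepthGrid samples.  Components of a decomposition may be
    signed; activity objects are nonnegative.
    """

    values: np.ndarray
    lateral_width_um: float
    depth_grid: DepthGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("voxel object must be a 3-D array (x, y, z)")
        if self.values.shape[2] != self.depth_grid.n:
            raise ValueError("depth slice count must equal the depth grid size")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel object contains non-finite values")

    @property
    def voxel_volume_um3(self) -> float:
        return self.lateral_width_um**2 * self.depth_grid.dz_um

    @property
    def lateral_centers_um(self) -> np.ndarray:
        n = self.values.shape[0]
        h = n * self.lateral_width_um / 2.0
        return -h + (np.arange(n) + 0.5) * self.lateral_width_um

    def norm(self) -> float:
        """Voxel-volume-weighted L2 norm."""
        return float(np.sqrt(np.sum(self.values**2) * self.voxel_volume_um3))

    def inner(self, other: "VoxelObject") -> float:
        self._check_same_grid(other)
        return float(np.sum(self.values * other.values) * self.voxel_volume_um3)

    def _check_same_grid(self, other: "VoxelObject") -> None:
        if (
            self.values.shape != other.values.shape
            or self.lateral_width_um != other.lateral_width_um
            or not np.array_equal(self.depth_grid.depths_um, other.depth_grid.depths_um)
        ):
            raise ValueError("voxel grids do not match")

    def xz_projection(self) -> np.ndarray:
        """Sum over y: the coronal (xz-plane) view used for reporting."""
        return self.values.sum(axis=1)

    def to_hdf5(self, group) -> None:
        group.create_dataset("values", data=self.values)
        group.attrs["lateral_width_um"] = self.lateral_width_um
        group.create_dataset("depths_um", data=self.depth_grid.depths_um)
        group.attrs["slab_thickness_um"] = self.depth_grid.slab_thickness_um
        group.attrs["dz_um"] = self.depth_grid.dz_um

    @classmethod
    def from_hdf5(cls, group) -> "VoxelObject":
        grid = DepthGrid(
            group["depths_um"][...],
            float(group.attrs["slab_thickness_um"]),
            float(group.attrs["dz_um"]),
        )
        return cls(group["values"][...], float(group.attrs["lateral_width_um"]), grid)


def build_test_object(
    specs: list[CylinderSpec],
    geom: SlabGeometry,
    grid: DepthGrid,
    lateral_voxel_um: float,
) -> VoxelObject:
    """Voxelize cylinders by the center-point test onto the detector footprint.

    A voxel belongs to a cylinder iff its center is inside; overlapping
    cylinders sum their densities (an empty list gives an all-zero object).
    Cylinders must lie inside the slab and the detector footprint.
    """
    hx, hy = geom.half_extent_um
    nx = int(round(2 * hx / lateral_voxel_um))
    ny = int(round(2 * hy / lateral_voxel_um))
    if abs(nx * lateral_voxel_um - 2 * hx) > 1e-9 or abs(ny * lateral_voxel_um - 2 * hy) > 1e-9:
        raise ValueError("lateral voxel size must tile the detector extent")
    if nx != ny:
        raise ValueError("only square detector footprints are supported")
    xc = -hx + (np.arange(nx) + 0.5) * lateral_voxel_um
    yc = -hy + (np.arange(ny) + 0.5) * lateral_voxel_um
    zc = grid.depths_um
    values = np.zeros((nx, ny, grid.n))
    for c in specs:
        if c.top_um < 0 or c.top_um + c.height_um > geom.thickness_um:
            raise ValueError(f"cylinder {c} extends outside the slab depth range")
        if abs(c.cx_um) + c.radius_um > hx or abs(c.cy_um) + c.radius_um > hy:
            raise ValueError(f"cylinder {c} extends outside the detector footprint")
        lat = (xc[:, None] - c.cx_um) ** 2 + (yc[None, :] - c.cy_um) ** 2 < c.radius_um**2
        dep = (zc >= c.top_um) & (zc < c.top_um + c.height_um)
        values += c.density * lat[:, :, None] * dep[None, None, :]
    return VoxelObject(values, lateral_voxel_um, grid)


# ---------------------------------------------------------------------------
# measurement / null decomposition
# ---------------------------------------------------------------------------


def _retained_projectors(
    kernel: DepthKernel,
    mu_max: float,
    lambda_min: float,
    radii: np.ndarray,
):
    """Per-radius projector onto eigenvectors with mu/mu_max >= lambda_min.

    The kernel matrices are interpolated linearly in rho and the Dz-weighted
    eigenproblem solved at each requested radius; the projector in plain
    coordinates is ``P = dz W W^T`` with W the retained eigenvector columns.
    Radii beyond the sampled range have no eigen-system and are fully null.
    """
    dz = kernel.dz_um
    n = kernel.n_depths
    rho_max = kernel.rho[-1] * (1 + 1e-9)
    projs = np.zeros((radii.size, n, n))
    retained = np.zeros(radii.size, dtype=int)
    covered = radii <= rho_max
    for i, r in enumerate(radii):
        if not covered[i]:
            continue
        kmat = interpolate_kernel(kernel, min(r, kernel.rho[-1]))
        mu, y = np.linalg.eigh(kmat * dz)
        keep = mu >= lambda_min * mu_max
        m = int(keep.sum())
        retained[i] = m
        if m:
            w = y[:, keep] / np.sqrt(dz)
            projs[i] = dz * (w @ w.T)
    return projs, retained, covered


def measurement_component(
    f: VoxelObject,
    kernel: DepthKernel,
    es: EigenSystem,
    lambda_min: float = 1e-6,
) -> VoxelObject:
    """Project an object onto the retained (above-cutoff) eigenfunctions.

    Per lateral DFT frequency vector, the complex depth profile is projected
    onto the depth-kernel eigenvectors with ``mu/mu_max >= lambda_min`` under
    the Dz-weighted inner product; frequencies whose radius exceeds the
    kernel's sampled range are treated as fully null.  The result is an
    orthogonal projection, so decomposition identities (idempotence,
    orthogonality, Pythagorean split) hold to floating point.
    """
    if not (0.0 < lambda_min < 1.0):
        raise ValueError(f"lambda_min must be in (0, 1), got {lambda_min}")
    if not np.array_equal(f.depth_grid.depths_um, kernel.depths_um):
        raise ValueError("object depth slices do not match the kernel depth grid")
    nx, ny, nz = f.values.shape
    fx = np.fft.fftfreq(nx, d=f.lateral_width_um)
    fy = np.fft.fftfreq(ny, d=f.lateral_width_um)
    radii = np.hypot(fx[:, None], fy[None, :]).ravel()
    uniq, inv = np.unique(np.round(radii, 12), return_inverse=True)

    projs, _, _ = _retained_projectors(kernel, es.mu_max, lambda_min, uniq)

    g = np.fft.fft2(f.values, axes=(0, 1)).reshape(nx * ny, nz)
    out = np.empty_like(g)
    order = np.argsort(inv, kind="stable")
    bounds = np.searchsorted(inv[order], np.arange(uniq.size + 1))
    for i in range(uniq.size):
        rows = order[bounds[i] : bounds[i + 1]]
        if rows.size:
            out[rows] = g[rows] @ projs[i].T
    fm = np.fft.ifft2(out.reshape(nx, ny, nz), axes=(0, 1))
    scale = max(np.abs(f.values).max(), 1e-300)  # input scale: the output may be ~0
    if np.abs(fm.imag).max() / scale > 1e-9:
        raise ValueError("measurement component has a non-real residue; inputs inconsistent")
    return VoxelObject(fm.real, f.lateral_width_um, f.depth_grid)


def null_component(f: VoxelObject, f_meas: VoxelObject) -> VoxelObject:
    """Exact voxelwise remainder f - f_meas (the part invisible to the system)."""
    f._check_same_grid(f_meas)
    return VoxelObject(f.values - f_meas.values, f.lateral_width_um, f.depth_grid)


def scaled_null_norm(f_null: VoxelObject, f: VoxelObject) -> float:
    """||f_null|| / ||f|| in the voxel-volume-weighted L2 norm, in [0, 1]."""
    nf = f.norm()
    if nf == 0:
        raise ValueError("scaled null norm undefined for a zero object")
    return f_null.norm() / nf


@dataclass
class Decomposition:
    """Measurement/null split of an object for one detector configuration."""

    f_meas: VoxelObject
    f_null: VoxelObject
    scaled_null_norm: float
    lambda_min: float
    normalized_inner: float
    retained_per_rho: dict = field(default_factory=dict)


def decompose(
    f: VoxelObject,
    kernel: DepthKernel,
    es: EigenSystem,
    lambda_min: float = 1e-6,
) -> Decomposition:
    """Full measurement/null decomposition with orthogonality diagnostics."""
    fm = measurement_component(f, kernel, es, lambda_min)
    fn = null_component(f, fm)
    nf2 = f.norm() ** 2
    inner = fm.inner(fn) / nf2 if nf2 > 0 else 0.0
    nx = f.values.shape[0]
    fx = np.fft.fftfreq(nx, d=f.lateral_width_um)
    radii = np.hypot(fx[:, None], fx[None, :]).ravel()
    uniq = np.unique(np.round(radii, 12))
    _, retained, covered = _retained_projectors(kernel, es.mu_max, lambda_min, uniq)
    return Decomposition(
        f_meas=fm,
        f_null=fn,
        scaled_null_norm=scaled_null_norm(fn, f),
        lambda_min=lambda_min,
        normalized_inner=inner,
        retained_per_rho={
            "rho": uniq,
            "retained": retained,
            "n_uncovered": int((~covered).sum()),
        },
    )


# ---------------------------------------------------------------------------
# forward and adjoint operators (oracle checks)
# ---------------------------------------------------------------------------


@dataclass
class DataCube:
    """Mean binned data: one lateral image per occupied non-position bin.

    ``values[b]`` is the expected event count per attribute bin over the
    detector plane for non-position bin key ``keys[b]`` (exposure tau = 1).
    """

    values: np.ndarray
    keys: np.ndarray
    attrs: AttributeSpec
    bins: BinSpec

    def norm(self) -> float:
        """Plain l2 norm over bins (a fixed bin measure would rescale ratios)."""
        return float(np.sqrt(np.sum(self.values**2)))


def forward_project(f: VoxelObject, prf: PRFGrid) -> DataCube:
    """Mean data of an object: depth-summed lateral convolution with the PRF.

    ``u_b(r_d) = sum_z DV (f(., z) * prf_b(., z))(r_d)`` via circular FFT
    convolution on the common lateral grid (object voxels and PRF bins must
    coincide).
    """
    _check_lateral_match(f, prf)
    nx, ny, nz = f.values.shape
    dv = f.voxel_volume_um3
    keys_all, _ = prf.nonlateral_key()
    uniq = np.unique(keys_all)
    pos = {k: i for i, k in enumerate(uniq)}
    acc = np.zeros((uniq.size, nx, ny), dtype=complex)
    f_hat = np.fft.fft2(f.values, axes=(0, 1))
    for iz in range(nz):
        keys_z, slices = prf.lateral_slices(iz)
        if keys_z.size == 0:
            continue
        # put the zero-offset bin at index 0 so the circular convolution is
        # physically aligned with the detector coordinates
        slices = np.roll(slices, (-(nx // 2), -(ny // 2)), axis=(1, 2))
        p_hat = np.fft.fft2(slices, axes=(1, 2))
        rows = np.array([pos[k] for k in keys_z])
        acc[rows] += p_hat * f_hat[None, :, :, iz] * dv
    values = np.fft.ifft2(acc, axes=(1, 2)).real
    return DataCube(values=values, keys=uniq, attrs=prf.attrs, bins=prf.bins)


def adjoint_backproject(data, prf: PRFGrid, f_template: VoxelObject | None = None) -> VoxelObject:
    """Adjoint of the forward operator applied to binned data or an event list.

    ``(L† u)(r, z) = sum_b sum_{r_d} u_b(r_d) prf_b(r_d - r, z)`` — a lateral
    cross-correlation per depth.  For a list-mode table the events are
    first binned as raw counts, so a single-event list returns the PRF mass
    profile at that event's attribute bin across all depths (the point
    process adjoint).
    """
    if isinstance(data, ListModeTable):
        single = histogram_listmode(data, prf.bins, prf.attrs, n_emitted=max(len(data), 1))
        keys, slices = single.lateral_slices(0)
        cube = DataCube(
            values=slices * max(len(data), 1),  # undo the 1/n_emitted normalization: raw counts
            keys=keys,
            attrs=prf.attrs,
            bins=prf.bins,
        )
    else:
        cube = data
    if cube.attrs != prf.attrs or cube.bins != prf.bins:
        raise ValueError("data bins do not match the PRF bins")
    nx = prf.bins.n_lateral
    nz = prf.n_depths
    pos = {k: i for i, k in enumerate(cube.keys)}
    u_hat = np.fft.fft2(cube.values, axes=(1, 2))
    out = np.zeros((nx, nx, nz))
    for iz in range(nz):
        keys_z, slices = prf.lateral_slices(iz)
        if keys_z.size == 0:
            continue
        rows = [pos.get(k) for k in keys_z]
        sel = [(i, r) for i, r in enumerate(rows) if r is not None]
        if not sel:
            continue
        si, ri = zip(*sel)
        shifted = np.roll(slices[list(si)], (-(nx // 2), -(nx // 2)), axis=(1, 2))
        p_hat = np.fft.fft2(shifted, axes=(1, 2))
        corr = np.fft.ifft2(u_hat[list(ri)] * p_hat.conj(), axes=(1, 2)).real
        out[:, :, iz] = corr.sum(axis=0)
    if f_template is not None:
        return VoxelObject(out, f_template.lateral_width_um, f_template.depth_grid)
    grid = DepthGrid(prf.depths_um, float(prf.depths_um[-1]),
                     float(np.diff(prf.depths_um)[0]) if nz > 1 else float(prf.depths_um[0]))
    return VoxelObject(out, prf.bins.lateral_width_um, grid)


def _check_lateral_match(f: VoxelObject, prf: PRFGrid) -> None:
    if not np.array_equal(f.depth_grid.depths_um, prf.depths_um):
        raise ValueError("object depth slices do not match the PRF depths")
    if abs(f.lateral_width_um - prf.bins.lateral_width_um) > 1e-12:
        raise ValueError("object voxels and PRF lateral bins must have equal width")
    if f.values.shape[0] != prf.bins.n_lateral or f.values.shape[1] != prf.bins.n_lateral:
        raise ValueError("object lateral grid and PRF lateral bins must coincide")
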