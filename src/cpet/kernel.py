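"""Symmetry-reduced projection/backprojection kernel and its eigensystem.

The projection/backprojection operator L†L of a laterally shift-invariant
system diagonalizes over 2-D Fourier modes: at each spatial frequency vector
rho the residual coupling is only along depth, through the kernel

    K(rho, z, z') = sum_b  P_b(rho, z) conj(P_b(rho, z')),

where ``P_b`` is the lateral Fourier transform of the PRF slice in
non-position attribute bin b.  K is Hermitian PSD by construction (a Gram
matrix).  Rotational symmetry reduces the dependence to the radial magnitude
rho, so the kernel is sampled on a radial frequency grid and the Dz-weighted
N x N eigenproblem is solved per sample; eigenvalues are reported relative to
the global maximum.

Frequencies up to the axis Nyquist are evaluated along (rho, 0).  Radii
between the axis Nyquist and sqrt(2) x Nyquist — present in the corners of a
square object DFT grid — are evaluated along the diagonal direction
rho (1, 1)/sqrt 2, where the frequency vector is still representable on the
bin lattice; rotational symmetry makes the two choices equivalent and the
(rho,0)/(0,rho) invariant checks it numerically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DepthGrid
from .listmode import PRFGrid

__all__ = [
    "DepthKernel",
    "EigenSystem",
    "build_depth_kernel",
    "kernel_at_vector",
    "eigendecompose_kernel",
    "normalized_spectrum",
    "interpolate_kernel",
    "radial_frequency_samples",
]


@dataclass
class DepthKernel:
    """K(rho, z, z') sampled on a radial frequency grid.

    ``values[k]`` is the real symmetric N x N kernel matrix at radial
    frequency ``rho[k]`` (cycles/um).  ``nyquist`` is the axis Nyquist of the
    lateral bin lattice; radii up to sqrt(2) x nyquist are supported.
    """

    rho: np.ndarray
    values: np.ndarray
    depths_um: np.ndarray
    dz_um: float
    nyquist: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = self.depths_um.size
        if self.values.shape != (self.rho.size, n, n):
            raise ValueError("kernel array shape mismatch")

    @property
    def n_depths(self) -> int:
        return int(self.depths_um.size)

    def to_hdf5(self, group) -> None:
        group.create_dataset("rho", data=self.rho)
        group.create_dataset("values", data=self.values)
        group.create_dataset("depths_um", data=self.depths_um)
        group.attrs["dz_um"] = self.dz_um
        group.attrs["nyquist"] = self.nyquist
        group.attrs["provenance"] = json.dumps(self.provenance, sort_keys=True, default=str)

    @classmethod
    def from_hdf5(cls, group) -> "DepthKernel":
        return cls(
            rho=group["rho"][...],
            values=group["values"][...],
            depths_um=group["depths_um"][...],
            dz_um=float(group.attrs["dz_um"]),
            nyquist=float(group.attrs["nyquist"]),
            provenance=json.loads(group.attrs.get("provenance", "{}")),
        )


@dataclass
class EigenSystem:
    """Per-frequency eigenpairs of the depth kernel.

    ``mu[k, n]`` are eigenvalues in descending order at ``rho[k]``;
    ``w[k, :, n]`` the matching eigenvectors, orthonormal under the
    Dz-weighted inner product ``<a, b> = sum_i a_i b_i Dz``.  ``mu_max`` is
    the global maximum over the sampled radii and normalizes the spectrum
    ``lam = mu / mu_max``.
    """

    rho: np.ndarray
    mu: np.ndarray
    w: np.ndarray
    dz_um: float
    mu_max: float

    @property
    def lam(self) -> np.ndarray:
        return self.mu / self.mu_max

    def to_hdf5(self, group) -> None:
        group.create_dataset("rho", data=self.rho)
        group.create_dataset("mu", data=self.mu)
        group.create_dataset("w", data=self.w)
        group.attrs["dz_um"] = self.dz_um
        group.attrs["mu_max"] = self.mu_max

    @classmethod
    def from_hdf5(cls, group) -> "EigenSystem":
        return cls(group["rho"][...], group["mu"][...], group["w"][...],
                   float(group.attrs["dz_um"]), float(group.attrs["mu_max"]))


# ---------------------------------------------------------------------------
# kernel construction
# ---------------------------------------------------------------------------


class _KernelWorkspace:
    """Precomputed sparsity structure for re-evaluating the Gram kernel at
    many frequencies.

    The lateral Fourier sums P_b(rho, z) are sparse over (non-position bin b,
    depth) pairs; the per-frequency work is two bincounts over the PRF
    entries plus a sparse Gram product, instead of a dense nb x N matrix
    multiply.
    """

    def __init__(self, prf: PRFGrid):
        key, _ = prf.nonlateral_key()
        uniq, b_idx = np.unique(key, return_inverse=True)
        self.nb = uniq.size
        self.nd = prf.n_depths
        pair = b_idx.astype(np.int64) * self.nd + prf.iz
        pairs, self.inv = np.unique(pair, return_inverse=True)
        rows = pairs // self.nd  # ascending: csr structure for free
        self.indices = (pairs % self.nd).astype(np.int32)
        self.indptr = np.searchsorted(rows, np.arange(self.nb + 1)).astype(np.int64)
        centers = prf.bins.lateral_centers_um
        self.xc = centers[prf.ix]
        self.yc = centers[prf.iy]
        self.mass = prf.mass
        self.n_pairs = pairs.size

    def gram(self, fx: float, fy: float) -> np.ndarray:
        from scipy import sparse

        phase = -2.0 * np.pi * (fx * self.xc + fy * self.yc)
        vr = np.bincount(self.inv, weights=self.mass * np.cos(phase), minlength=self.n_pairs)
        vi = np.bincount(self.inv, weights=self.mass * np.sin(phase), minlength=self.n_pairs)
        m = sparse.csr_matrix((vr + 1j * vi, self.indices, self.indptr), shape=(self.nb, self.nd))
        return (m.conj().T @ m).toarray()


def kernel_at_vector(prf: PRFGrid, grid: DepthGrid, freq_vec: tuple[float, float]) -> np.ndarray:
    """Complex Hermitian kernel at one 2-D frequency vector (test hook)."""
    if not np.array_equal(prf.depths_um, grid.depths_um):
        raise ValueError("PRF depths do not match the depth grid")
    return _KernelWorkspace(prf).gram(*freq_vec)


def build_depth_kernel(
    prf: PRFGrid,
    grid: DepthGrid,
    freqs,
    imag_tol: float | None = 1e-10,
) -> DepthKernel:
    """Assemble K(rho, z, z') at the requested radial frequencies.

    ``imag_tol`` bounds the relative imaginary residue tolerated before the
    Hermitian kernel is reduced to its real part; pass ``None`` for Monte
    Carlo PRFs, whose statistical parity violation makes the residue
    O(1/sqrt(counts)) (the real part of a Hermitian PSD form is still
    symmetric PSD).
    """
    if not np.array_equal(prf.depths_um, grid.depths_um):
        raise ValueError("PRF depths do not match the depth grid")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    nyq = prf.bins.lateral_nyquist
    if np.any(freqs < 0):
        raise ValueError("radial frequencies must be nonnegative")
    if np.any(freqs > np.sqrt(2.0) * nyq * (1 + 1e-9)):
        raise ValueError(
            f"requested frequency {freqs.max():.4g} exceeds the lattice limit "
            f"sqrt(2) x Nyquist = {np.sqrt(2)*nyq:.4g} cycles/um"
        )
    ws = _KernelWorkspace(prf)
    nd = grid.n
    out = np.empty((freqs.size, nd, nd))
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    for k, rho in enumerate(freqs):
        if rho <= nyq * (1 + 1e-12):
            kmat = ws.gram(rho, 0.0)
        else:
            kmat = ws.gram(rho * inv_sqrt2, rho * inv_sqrt2)
        scale = max(np.abs(kmat).max(), 1e-300)
        herm = np.abs(kmat - kmat.conj().T).max() / scale
        if herm > 1e-10:
            raise ValueError(f"kernel not Hermitian at rho={rho}: residue {herm:.2e}")
        imag = np.abs(kmat.imag).max() / scale
        if imag_tol is not None and imag > imag_tol:
            raise ValueError(
                f"kernel imaginary residue {imag:.2e} at rho={rho} exceeds {imag_tol:.1e}; "
                "pass imag_tol=None for Monte Carlo PRFs"
            )
        out[k] = kmat.real
    return DepthKernel(
        rho=freqs,
        values=out,
        depths_um=grid.depths_um,
        dz_um=grid.dz_um,
        nyquist=nyq,
        provenance={"q": prf.attrs.q, "attributes": prf.attrs.attributes, **prf.meta},
    )


def radial_frequency_samples(rho_max: float, n: int = 64, rho_min: float | None = None) -> np.ndarray:
    """Zero plus ``n - 1`` geometrically spaced radii up to ``rho_max``.

    The kernel varies fastest at low frequency, so the sampling is
    logarithmic; ``rho_min`` defaults to ``rho_max / 512`` (about the first
    nonzero frequency of the default object grids).
    """
    if n < 2 or rho_max <= 0:
        raise ValueError("need n >= 2 and rho_max > 0")
    if rho_min is None:
        rho_min = rho_max / 512.0
    return np.concatenate([[0.0], np.geomspace(rho_min, rho_max, n - 1)])


# ---------------------------------------------------------------------------
# eigendecomposition
# ---------------------------------------------------------------------------


def _eigh_weighted(kmat: np.ndarray, dz: float):
    """Dz-weighted eigenproblem  sum_j K_ij dz w_j = mu w_i  via the
    similarity transform with the square-root weight (trivial for uniform
    weights: eigh of K*dz)."""
    mu, y = np.linalg.eigh(kmat * dz)
    order = np.argsort(mu)[::-1]
    return mu[order], y[:, order]  # y orthonormal in plain l2; w = y / sqrt(dz)


def eigendecompose_kernel(
    K: DepthKernel,
    grid: DepthGrid,
    negative_tol: float = 1e-10,
) -> EigenSystem:
    """Solve the per-frequency depth eigenproblem of the sampled kernel.

    Eigenvalues more negative than ``negative_tol x mu_max`` abort (the Gram
    construction guarantees PSD, so that indicates a corrupted kernel);
    smaller negatives are clipped to zero.
    """
    if not np.array_equal(K.depths_um, grid.depths_um):
        raise ValueError("kernel depths do not match the depth grid")
    sym = np.abs(K.values - np.swapaxes(K.values, 1, 2)).max()
    scale = max(np.abs(K.values).max(), 1e-300)
    if sym / scale > 1e-10:
        raise ValueError(f"kernel not symmetric: relative residue {sym/scale:.2e}")
    n = K.n_depths
    mu = np.empty((K.rho.size, n))
    w = np.empty((K.rho.size, n, n))
    for k in range(K.rho.size):
        mu_k, y = _eigh_weighted(K.values[k], K.dz_um)
        mu[k] = mu_k
        w[k] = y / np.sqrt(K.dz_um)
    mu_max = float(mu.max())
    if mu_max <= 0:
        raise ValueError("degenerate system: all eigenvalues vanish")
    if mu.min() < -negative_tol * mu_max:
        raise ValueError(
            f"eigenvalue {mu.min():.3e} below -{negative_tol:.1e} x mu_max={mu_max:.3e}; "
            "kernel is not PSD"
        )
    np.clip(mu, 0.0, None, out=mu)
    return EigenSystem(rho=K.rho, mu=mu, w=w, dz_um=K.dz_um, mu_max=mu_max)


def normalized_spectrum(es: EigenSystem) -> pd.DataFrame:
    """Long-form table of lambda_n(rho) = mu_n(rho)/mu_max (columns rho, n, lam)."""
    if es.mu_max <= 0:
        raise ValueError("degenerate system: mu_max must be positive")
    n = es.mu.shape[1]
    rho = np.repeat(es.rho, n)
    idx = np.tile(np.arange(n), es.rho.size)
    return pd.DataFrame({"rho": rho, "n": idx, "lam": es.lam.ravel()})


def interpolate_kernel(K: DepthKernel, rho: float) -> np.ndarray:
    """Linear-in-rho interpolation of the sampled kernel matrices.

    K varies smoothly in rho; interpolating the matrices (rather than the
    eigen-systems, which suffer sign and ordering ambiguities) preserves
    symmetry and positive semidefiniteness.  Accuracy is checked by a
    sample-doubling test in the suite.
    """
    grid = K.rho
    if rho < grid[0] - 1e-12 or rho > grid[-1] * (1 + 1e-9):
        raise ValueError(f"rho={rho} outside the sampled range [{grid[0]}, {grid[-1]}]")
    j = int(np.searchsorted(grid, rho, side="right") - 1)
    j = min(max(j, 0), grid.size - 2)
    t = (rho - grid[j]) / (grid[j + 1] - grid[j])
    t = min(max(t, 0.0), 1.0)
    return (1.0 - t) * K.values[j] + t * K.values[j + 1]
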