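"""Slab geometry and depth sampling for a planar-detector emission tomograph.

The imaging geometry is a uniform tissue slab (approximated by water) with a
planar particle-processing detector at ``z = 0``; depth ``z`` increases into
the tissue.  All lengths are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SlabGeometry", "DepthGrid", "alpha_slab", "beta_slab"]


@dataclass(frozen=True)
class SlabGeometry:
    """Tissue slab imaged by a planar detector at ``z = 0``.

    Parameters
    ----------
    thickness_um
        Tissue thickness ``z_max``; source depths lie in ``(0, z_max]``.
    detector_extent_um
        Lateral detector size ``(Lx, Ly)``.  The point response functions are
        computed for an unbounded detector plane (required by the lateral
        shift-invariance argument); the finite extent is enforced only when
        sampling list-mode events and when laying out voxel grids.
    """

    thickness_um: float
    detector_extent_um: tuple[float, float] = (160.0, 160.0)

    def __post_init__(self) -> None:
        if not self.thickness_um > 0:
            raise ValueError(f"slab thickness must be positive, got {self.thickness_um}")
        if len(self.detector_extent_um) != 2 or min(self.detector_extent_um) <= 0:
            raise ValueError(f"detector extent must be two positive lengths, got {self.detector_extent_um}")

    @property
    def half_extent_um(self) -> tuple[float, float]:
        return (self.detector_extent_um[0] / 2.0, self.detector_extent_um[1] / 2.0)

    def contains_depth(self, z: float) -> bool:
        return 0.0 < z <= self.thickness_um


def alpha_slab() -> SlabGeometry:
    """40-um tissue layer with a 160 x 160 um^2 detector (alpha-ET default)."""
    return SlabGeometry(40.0, (160.0, 160.0))


def beta_slab() -> SlabGeometry:
    """100-um tissue layer with a 1024 x 1024 um^2 detector (BET default)."""
    return SlabGeometry(100.0, (1024.0, 1024.0))


@dataclass(frozen=True)
class DepthGrid:
    """Discrete depth samples used for the kernel eigenproblem and voxel slices.

    ``K(rho, z, z')`` is evaluated on ``depths_um x depths_um``; each sample
    carries a quadrature weight ``dz_um`` (midpoint rule on slices of that
    thickness), so a grid of N depths yields N eigenvalues per spatial
    frequency.
    """

    depths_um: np.ndarray
    slab_thickness_um: float
    dz_um: float = field(default=0.0)

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths_um, dtype=float)
        object.__setattr__(self, "depths_um", depths)
        if depths.ndim != 1 or depths.size == 0:
            raise ValueError("depth grid must be a non-empty 1-D array")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("depth samples must be strictly increasing")
        if depths[0] <= 0 or depths[-1] > self.slab_thickness_um:
            raise ValueError(
                f"depth samples must lie in (0, {self.slab_thickness_um}], got range "
                f"[{depths[0]}, {depths[-1]}]"
            )
        dz = self.dz_um
        if dz <= 0:
            steps = np.diff(depths)
            dz = float(steps[0]) if depths.size > 1 else float(self.slab_thickness_um)
            if depths.size > 1 and not np.allclose(steps, dz):
                raise ValueError("dz_um must be given explicitly for non-uniform depth grids")
        object.__setattr__(self, "dz_um", float(dz))

    @property
    def n(self) -> int:
        return int(self.depths_um.size)

    @classmethod
    def alpha_default(cls) -> "DepthGrid":
        """20 depths {1, 3, ..., 39} um in the 40-um slab, 2-um slices."""
        return cls(np.arange(1.0, 40.0, 2.0), 40.0, 2.0)

    @classmethod
    def beta_default(cls) -> "DepthGrid":
        """20 depths {5, 10, ..., 100} um in the 100-um slab, 5-um slices."""
        return cls(np.arange(5.0, 101.0, 5.0), 100.0, 5.0)
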