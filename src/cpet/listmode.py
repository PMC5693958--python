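"""Attribute space, list-mode tables, and binned point-response grids.

A particle-processing detector estimates, per detected particle, a subset of
the five attributes ``(x_d, y_d, s_x, s_y, E)``: detector-plane position,
lateral direction cosines of the track at the detector entrance, and residual
kinetic energy.  List-mode data are per-event attribute vectors; binning them
(or integrating an analytic model over bins) yields a point response function
(PRF) grid per source depth, whose total mass per depth is the detection
sensitivity S(z).

Binning conventions
-------------------
* Direction is binned in polar/azimuthal angles (theta, phi), reconstructed
  from the direction cosines: ``theta = arccos(sqrt(1 - s_x^2 - s_y^2))``
  measured from the detector normal, ``phi = atan2(s_y, s_x)``.
* All axes use half-open bins ``[low, high)``; a value exactly on an interior
  edge falls in the upper bin.
* Lateral positions are binned as offsets from the source's lateral position
  (the PRFs are laterally shift-invariant).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "BinSpec",
    "ListModeTable",
    "PRFGrid",
    "histogram_listmode",
    "read_listmode",
    "write_listmode",
]

LISTMODE_COLUMNS = ("x_d_um", "y_d_um", "s_x", "s_y", "E_keV")

_ALLOWED_COMBOS = {
    ("x_d", "y_d"),
    ("x_d", "y_d", "E"),
    ("x_d", "y_d", "s_x", "s_y"),
    ("x_d", "y_d", "s_x", "s_y", "E"),
}


@dataclass(frozen=True)
class AttributeSpec:
    """Which of ``(x_d, y_d, s_x, s_y, E)`` the detector measures.

    Only the four combinations studied for CPET detectors are allowed; all of
    them include the two position attributes.
    """

    attributes: tuple[str, ...]

    def __post_init__(self) -> None:
        attrs = tuple(self.attributes)
        object.__setattr__(self, "attributes", attrs)
        if attrs not in _ALLOWED_COMBOS:
            raise ValueError(
                f"attribute combination {attrs} is not one of the supported detector "
                f"configurations {sorted(_ALLOWED_COMBOS)}"
            )

    @property
    def q(self) -> int:
        return len(self.attributes)

    @property
    def has_direction(self) -> bool:
        return "s_x" in self.attributes

    @property
    def has_energy(self) -> bool:
        return "E" in self.attributes

    @classmethod
    def position(cls) -> "AttributeSpec":
        return cls(("x_d", "y_d"))

    @classmethod
    def position_energy(cls) -> "AttributeSpec":
        return cls(("x_d", "y_d", "E"))

    @classmethod
    def position_direction(cls) -> "AttributeSpec":
        return cls(("x_d", "y_d", "s_x", "s_y"))

    @classmethod
    def all_five(cls) -> "AttributeSpec":
        return cls(("x_d", "y_d", "s_x", "s_y", "E"))

    @classmethod
    def from_q(cls, q: int) -> "AttributeSpec":
        """Map q = 2, 3, 4, 5 to the detector configurations compared in the study."""
        table = {2: cls.position, 3: cls.position_energy, 4: cls.position_direction, 5: cls.all_five}
        if q not in table:
            raise ValueError(f"q must be in {{2,3,4,5}}, got {q}")
        return table[q]()

    def is_subset_of(self, other: "AttributeSpec") -> bool:
        return set(self.attributes) <= set(other.attributes)


@dataclass(frozen=True)
class BinSpec:
    """Bin widths and axis ranges for the attribute grid.

    Defaults follow the study's histogram dimensions: 2-degree angular bins
    and 20-keV energy bins; the lateral width is 4 um for the beta Monte
    Carlo and 2 um for the analytic alpha model (see factory methods).
    """

    lateral_width_um: float
    lateral_half_extent_um: float
    energy_max_kev: float
    theta_width_deg: float = 2.0
    phi_width_deg: float = 2.0
    energy_width_kev: float = 20.0

    def __post_init__(self) -> None:
        for name in ("lateral_width_um", "lateral_half_extent_um", "energy_max_kev",
                     "theta_width_deg", "phi_width_deg", "energy_width_kev"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.lateral_half_extent_um < self.lateral_width_um:
            raise ValueError("lateral half extent smaller than one bin")
        n = self.lateral_half_extent_um / self.lateral_width_um
        if abs(n - round(n)) > 1e-9:
            raise ValueError("lateral half extent must be an integer number of bins")
        if abs(90.0 / self.theta_width_deg - round(90.0 / self.theta_width_deg)) > 1e-9:
            raise ValueError("theta bin width must divide 90 degrees")
        if abs(360.0 / self.phi_width_deg - round(360.0 / self.phi_width_deg)) > 1e-9:
            raise ValueError("phi bin width must divide 360 degrees")

    # -- edges ---------------------------------------------------------------
    @property
    def lateral_edges_um(self) -> np.ndarray:
        h, w = self.lateral_half_extent_um, self.lateral_width_um
        return np.arange(-h, h + 0.5 * w, w)

    @property
    def lateral_centers_um(self) -> np.ndarray:
        e = self.lateral_edges_um
        return 0.5 * (e[:-1] + e[1:])

    @property
    def n_lateral(self) -> int:
        return int(round(2 * self.lateral_half_extent_um / self.lateral_width_um))

    @property
    def theta_edges_deg(self) -> np.ndarray:
        return np.arange(0.0, 90.0 + 0.5 * self.theta_width_deg, self.theta_width_deg)

    @property
    def n_theta(self) -> int:
        return int(round(90.0 / self.theta_width_deg))

    @property
    def phi_edges_deg(self) -> np.ndarray:
        return np.arange(-180.0, 180.0 + 0.5 * self.phi_width_deg, self.phi_width_deg)

    @property
    def n_phi(self) -> int:
        return int(round(360.0 / self.phi_width_deg))

    @property
    def energy_edges_kev(self) -> np.ndarray:
        n = int(np.ceil(self.energy_max_kev / self.energy_width_kev - 1e-12))
        return self.energy_width_kev * np.arange(n + 1)

    @property
    def n_energy(self) -> int:
        return len(self.energy_edges_kev) - 1

    @property
    def lateral_nyquist(self) -> float:
        """Axis Nyquist frequency of the lateral bin lattice, cycles/um."""
        return 0.5 / self.lateral_width_um

    @classmethod
    def alpha_default(cls, energy_max_kev: float = 5150.0) -> "BinSpec":
        """2-um lateral bins over the 160-um alpha detector."""
        return cls(2.0, 80.0, energy_max_kev)

    @classmethod
    def beta_default(cls, energy_max_kev: float = 640.0) -> "BinSpec":
        """4-um lateral bins over the 1024-um beta detector."""
        return cls(4.0, 512.0, energy_max_kev)


# ---------------------------------------------------------------------------
# list-mode tables
# ---------------------------------------------------------------------------


@dataclass
class ListModeTable:
    """Per-event estimated attribute vectors plus acquisition metadata.

    ``frame`` has the canonical columns ``x_d_um, y_d_um, s_x, s_y, E_keV``;
    metadata records at least the source description, depth, number of emitted
    particles and the RNG seed.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in LISTMODE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"list-mode table missing columns {missing}")
        self.frame = self.frame.loc[:, list(LISTMODE_COLUMNS)].astype(float).reset_index(drop=True)
        s2 = self.frame["s_x"].to_numpy() ** 2 + self.frame["s_y"].to_numpy() ** 2
        if np.any(s2 > 1.0 + 1e-12):
            raise ValueError("direction cosines with s_x^2 + s_y^2 > 1")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_arrays(cls, x_d, y_d, s_x, s_y, e_kev, meta: dict | None = None) -> "ListModeTable":
        frame = pd.DataFrame(
            {"x_d_um": x_d, "y_d_um": y_d, "s_x": s_x, "s_y": s_y, "E_keV": e_kev}
        )
        return cls(frame, dict(meta or {}))

    @classmethod
    def empty(cls, meta: dict | None = None) -> "ListModeTable":
        frame = pd.DataFrame({c: np.empty(0) for c in LISTMODE_COLUMNS})
        return cls(frame, dict(meta or {}))


def write_listmode(table: ListModeTable, path) -> None:
    """Write a list-mode table as CSV with a JSON metadata comment line."""
    with open(path, "w", newline="") as fh:
        if table.meta:
            fh.write("# " + json.dumps(table.meta, sort_keys=True, default=str) + "\n")
        table.frame.to_csv(fh, index=False, float_format="%.12g")


def read_listmode(path) -> ListModeTable:
    """Read a list-mode CSV written by :func:`write_listmode`.

    Raises a ``ValueError`` naming the offending column for malformed input.
    """
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first[1:].strip())
            except json.JSONDecodeError:
                meta = {"comment": first[1:].strip()}
            body = fh.read()
        else:
            body = first + fh.read()
    frame = pd.read_csv(io.StringIO(body))
    missing = [c for c in LISTMODE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"list-mode file {path!s} missing columns {missing}")
    for col in LISTMODE_COLUMNS:
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index
            row = int(bad[0]) if len(bad) else -1
            raise ValueError(f"non-numeric value in column {col!r}, row {row}") from exc
    return ListModeTable(frame, meta)


# ---------------------------------------------------------------------------
# PRF grids (sparse, per-depth COO over the binned attribute axes)
# ---------------------------------------------------------------------------


@dataclass
class PRFGrid:
    """Binned point response function per source depth.

    The grid is stored sparsely: parallel coordinate arrays over
    ``(depth, x-offset, y-offset[, theta][, phi][, E])`` with a probability
    mass per occupied bin.  Mass is detection probability per emitted
    particle, so the per-depth total equals the sensitivity S(z).

    ``sensitivity`` stores S(z) per depth; for histogrammed Monte Carlo data
    it is the in-range detected fraction, for the analytic alpha model it is
    the closed-form value.
    """

    attrs: AttributeSpec
    bins: BinSpec
    depths_um: np.ndarray
    sensitivity: np.ndarray
    iz: np.ndarray
    ix: np.ndarray
    iy: np.ndarray
    itheta: np.ndarray | None
    iphi: np.ndarray | None
    ie: np.ndarray | None
    mass: np.ndarray
    n_out_of_range: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if self.sensitivity.shape != self.depths_um.shape:
            raise ValueError("sensitivity must have one entry per depth")
        if np.any(self.mass < 0):
            raise ValueError("negative PRF mass")
        if self.attrs.has_direction and (self.itheta is None or self.iphi is None):
            raise ValueError("direction attributes requested but angular indices missing")
        if self.attrs.has_energy and self.ie is None:
            raise ValueError("energy attribute requested but energy indices missing")
        tot = self.mass_per_depth()
        if np.any(tot > 1.0 + 1e-9):
            raise ValueError("PRF mass per depth exceeds 1")

    # -- basic queries -------------------------------------------------------
    @property
    def n_depths(self) -> int:
        return int(self.depths_um.size)

    @property
    def nnz(self) -> int:
        return int(self.mass.size)

    def mass_per_depth(self) -> np.ndarray:
        return np.bincount(self.iz, weights=self.mass, minlength=self.n_depths)

    def nonlateral_key(self) -> tuple[np.ndarray, int]:
        """Ravel the non-position attribute indices into a single key array.

        Returns ``(key, n_keys)``; for q = 2 every entry has key 0.
        """
        dims = []
        idx = []
        if self.attrs.has_direction:
            dims += [self.bins.n_theta, self.bins.n_phi]
            idx += [self.itheta, self.iphi]
        if self.attrs.has_energy:
            dims += [self.bins.n_energy]
            idx += [self.ie]
        if not dims:
            return np.zeros(self.nnz, dtype=np.int64), 1
        key = np.ravel_multi_index([i.astype(np.int64) for i in idx], dims)
        return key, int(np.prod(dims))

    # -- marginalization -----------------------------------------------------
    def marginalize(self, attrs: AttributeSpec) -> "PRFGrid":
        """Sum out attributes absent from ``attrs`` (which must be a subset)."""
        if not attrs.is_subset_of(self.attrs):
            raise ValueError(f"{attrs.attributes} is not a subset of {self.attrs.attributes}")
        cols = [self.iz, self.ix, self.iy]
        dims = [self.n_depths, self.bins.n_lateral, self.bins.n_lateral]
        if attrs.has_direction:
            cols += [self.itheta, self.iphi]
            dims += [self.bins.n_theta, self.bins.n_phi]
        if attrs.has_energy:
            cols += [self.ie]
            dims += [self.bins.n_energy]
        key = np.ravel_multi_index([c.astype(np.int64) for c in cols], dims)
        uniq, inv = np.unique(key, return_inverse=True)
        mass = np.bincount(inv, weights=self.mass)
        out = np.unravel_index(uniq, dims)
        k = 3
        itheta = iphi = ie = None
        if attrs.has_direction:
            itheta, iphi = out[k].astype(np.int32), out[k + 1].astype(np.int32)
            k += 2
        if attrs.has_energy:
            ie = out[k].astype(np.int32)
        return PRFGrid(
            attrs=attrs,
            bins=self.bins,
            depths_um=self.depths_um,
            sensitivity=self.sensitivity,
            iz=out[0].astype(np.int32),
            ix=out[1].astype(np.int32),
            iy=out[2].astype(np.int32),
            itheta=itheta,
            iphi=iphi,
            ie=ie,
            mass=mass,
            n_out_of_range=self.n_out_of_range,
            meta=dict(self.meta),
        )

    # -- dense views ---------------------------------------------------------
    def to_dense(self, z_index: int) -> np.ndarray:
        """Dense array over the attribute axes at one depth (small grids only)."""
        shape = [self.bins.n_lateral, self.bins.n_lateral]
        cols = [self.ix, self.iy]
        if self.attrs.has_direction:
            shape += [self.bins.n_theta, self.bins.n_phi]
            cols += [self.itheta, self.iphi]
        if self.attrs.has_energy:
            shape += [self.bins.n_energy]
            cols += [self.ie]
        out = np.zeros(shape)
        sel = self.iz == z_index
        np.add.at(out, tuple(c[sel] for c in cols), self.mass[sel])
        return out

    def lateral_slices(self, z_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(keys, dense lateral images) of the non-position bins at one depth."""
        key, _ = self.nonlateral_key()
        sel = self.iz == z_index
        uniq, inv = np.unique(key[sel], return_inverse=True)
        n = self.bins.n_lateral
        out = np.zeros((uniq.size, n, n))
        np.add.at(out, (inv, self.ix[sel], self.iy[sel]), self.mass[sel])
        return uniq, out

    # -- persistence ---------------------------------------------------------
    def to_hdf5(self, group) -> None:
        group.attrs["attributes"] = json.dumps(self.attrs.attributes)
        group.attrs["bins"] = json.dumps(
            {
                "lateral_width_um": self.bins.lateral_width_um,
                "lateral_half_extent_um": self.bins.lateral_half_extent_um,
                "energy_max_kev": self.bins.energy_max_kev,
                "theta_width_deg": self.bins.theta_width_deg,
                "phi_width_deg": self.bins.phi_width_deg,
                "energy_width_kev": self.bins.energy_width_kev,
            }
        )
        group.attrs["meta"] = json.dumps(self.meta, sort_keys=True, default=str)
        group.create_dataset("depths_um", data=self.depths_um)
        group.create_dataset("sensitivity", data=self.sensitivity)
        for name in ("iz", "ix", "iy", "itheta", "iphi", "ie", "mass", "n_out_of_range"):
            val = getattr(self, name)
            if val is not None:
                group.create_dataset(name, data=val)

    @classmethod
    def from_hdf5(cls, group) -> "PRFGrid":
        attrs = AttributeSpec(tuple(json.loads(group.attrs["attributes"])))
        bins = BinSpec(**json.loads(group.attrs["bins"]))
        get = lambda k: group[k][...] if k in group else None  # noqa: E731
        return cls(
            attrs=attrs,
            bins=bins,
            depths_um=group["depths_um"][...],
            sensitivity=group["sensitivity"][...],
            iz=group["iz"][...],
            ix=group["ix"][...],
            iy=group["iy"][...],
            itheta=get("itheta"),
            iphi=get("iphi"),
            ie=get("ie"),
            mass=group["mass"][...],
            n_out_of_range=get("n_out_of_range"),
            meta=json.loads(group.attrs.get("meta", "{}")),
        )

    @staticmethod
    def stack(slices: Sequence["PRFGrid"]) -> "PRFGrid":
        """Concatenate single-depth grids (shared bins/attrs) into one grid."""
        if not slices:
            raise ValueError("no PRF slices to stack")
        first = slices[0]
        for s in slices[1:]:
            if s.attrs != first.attrs or s.bins != first.bins:
                raise ValueError("PRF slices have mismatched bins or attributes")
        depths = np.concatenate([s.depths_um for s in slices])
        if np.any(np.diff(depths) <= 0):
            raise ValueError("stacked depths must be strictly increasing")
        offs = np.cumsum([0] + [s.n_depths for s in slices[:-1]])
        cat = lambda name: (  # noqa: E731
            None
            if getattr(first, name) is None
            else np.concatenate([getattr(s, name) for s in slices])
        )
        iz = np.concatenate([s.iz + o for s, o in zip(slices, offs)]).astype(np.int32)
        oor = None
        if all(s.n_out_of_range is not None for s in slices):
            oor = np.concatenate([np.atleast_1d(s.n_out_of_range) for s in slices])
        return PRFGrid(
            attrs=first.attrs,
            bins=first.bins,
            depths_um=depths,
            sensitivity=np.concatenate([s.sensitivity for s in slices]),
            iz=iz,
            ix=cat("ix"),
            iy=cat("iy"),
            itheta=cat("itheta"),
            iphi=cat("iphi"),
            ie=cat("ie"),
            mass=cat("mass"),
            n_out_of_range=oor,
            meta=dict(first.meta),
        )


# ---------------------------------------------------------------------------
# histogramming
# ---------------------------------------------------------------------------


def _bin_index(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-open binning [low, high); returns (index, in_range_mask)."""
    idx = np.searchsorted(edges, values, side="right") - 1
    ok = (idx >= 0) & (idx <= edges.size - 2) & (values < edges[-1])
    return idx, ok


def histogram_listmode(
    table: ListModeTable,
    bins: BinSpec,
    attrs: AttributeSpec,
    n_emitted: int,
    depth_um: float | None = None,
    source_xy_um: tuple[float, float] = (0.0, 0.0),
) -> PRFGrid:
    """Bin a list-mode table into a single-depth PRF grid.

    Each row is converted to lateral offsets from the source position, angles
    (theta, phi) from the direction cosines, and energy, then accumulated with
    weight ``1/n_emitted`` so that the total in-range mass estimates the
    detection probability.  Out-of-range rows are counted, not dropped
    silently.
    """
    if n_emitted < len(table):
        raise ValueError(f"n_emitted={n_emitted} smaller than row count {len(table)}")
    if depth_um is None:
        depth_um = float(table.meta.get("depth_um", np.nan))
    if not np.isfinite(depth_um):
        raise ValueError("source depth must be given (argument or table metadata)")

    fr = table.frame
    x = fr["x_d_um"].to_numpy() - source_xy_um[0]
    y = fr["y_d_um"].to_numpy() - source_xy_um[1]
    sx = fr["s_x"].to_numpy()
    sy = fr["s_y"].to_numpy()
    e = fr["E_keV"].to_numpy()
    s2 = sx**2 + sy**2
    if np.any(s2 > 1.0 + 1e-12):
        raise ValueError("rows with |(s_x, s_y)| > 1")

    ix, okx = _bin_index(x, bins.lateral_edges_um)
    iy, oky = _bin_index(y, bins.lateral_edges_um)
    ok = okx & oky
    cols: dict[str, np.ndarray] = {}
    if attrs.has_direction:
        theta = np.degrees(np.arccos(np.sqrt(np.clip(1.0 - s2, 0.0, 1.0))))
        phi = np.degrees(np.arctan2(sy, sx))
        phi = np.where(phi >= 180.0, phi - 360.0, phi)
        it, okt = _bin_index(theta, bins.theta_edges_deg)
        ip, okp = _bin_index(phi, bins.phi_edges_deg)
        ok &= okt & okp
        cols["itheta"], cols["iphi"] = it, ip
    if attrs.has_energy:
        ie, oke = _bin_index(e, bins.energy_edges_kev)
        ok &= oke
        cols["ie"] = ie

    n_in = int(ok.sum())
    idx_cols = [ix[ok], iy[ok]]
    dims = [bins.n_lateral, bins.n_lateral]
    if attrs.has_direction:
        idx_cols += [cols["itheta"][ok], cols["iphi"][ok]]
        dims += [bins.n_theta, bins.n_phi]
    if attrs.has_energy:
        idx_cols += [cols["ie"][ok]]
        dims += [bins.n_energy]
    if n_in:
        key = np.ravel_multi_index([c.astype(np.int64) for c in idx_cols], dims)
        uniq, counts = np.unique(key, return_counts=True)
        out = np.unravel_index(uniq, dims)
        mass = counts / float(n_emitted)
    else:
        uniq = np.empty(0, dtype=np.int64)
        out = tuple(np.empty(0, dtype=np.int64) for _ in dims)
        mass = np.empty(0)
    k = 2
    itheta = iphi = ie_idx = None
    if attrs.has_direction:
        itheta, iphi = out[k].astype(np.int32), out[k + 1].astype(np.int32)
        k += 2
    if attrs.has_energy:
        ie_idx = out[k].astype(np.int32)
    return PRFGrid(
        attrs=attrs,
        bins=bins,
        depths_um=np.array([depth_um]),
        sensitivity=np.array([n_in / float(n_emitted)]),
        iz=np.zeros(uniq.size, dtype=np.int32),
        ix=out[0].astype(np.int32),
        iy=out[1].astype(np.int32),
        itheta=itheta,
        iphi=iphi,
        ie=ie_idx,
        mass=mass,
        n_out_of_range=np.array([len(table) - n_in]),
        meta={"n_emitted": int(n_emitted), **{k: v for k, v in table.meta.items()}},
    )
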