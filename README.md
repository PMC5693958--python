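# cpet — null functions of charged-particle emission tomography

Charged-particle emission tomography (CPET) reconstructs the 3-D distribution
of an alpha- or beta-emitting radioisotope in a tissue slab from
**single-projection** list-mode data: a planar particle-processing detector in
contact with the tissue estimates, for every detected particle, up to five
attributes — position `(x_d, y_d)`, lateral direction cosines `(s_x, s_y)`,
and residual energy `E`.  Because there is no rotation, CPET is extreme
limited-angle tomography, and the central question is which parts of an
object a given detector can see at all.

This package answers that question with null-function analysis.  For a linear
system `ū = L f` with point response function `prf(Â|R)`, any object splits
into orthogonal components

    f = f_meas + f_null,      L f_null = 0,

where `f_meas` is the projection onto eigenfunctions of the
projection/backprojection operator `L†L` with non-negligible eigenvalues.
Lateral shift invariance and rotational symmetry reduce `L†L` to a family of
small depth-coupling kernels

    K(ρ, z, z') = Σ_b  P_b(ρ, z) P̄_b(ρ, z'),

indexed by the radial spatial frequency ρ, where `P_b` is the lateral Fourier
transform of the PRF slice in non-position attribute bin `b`.  Solving the
N×N eigenproblem of `K(ρ, ·, ·)` per frequency (N = 20 depths here) gives
eigenvalues `μ_n(ρ)`; modes with `λ_n = μ_n/μ_max ≥ λ_min = 10⁻⁶` are
retained in `f_meas`.  The **scaled null norm** `‖f_null‖₂/‖f‖₂` measures the
invisible fraction of an object as the number of measured attributes
q = 2, 3, 4, 5 varies.

The package provides, for both modalities:

- **alpha (αET)** — an analytic straight-line forward model for a
  5.15-MeV Pu-239-like source (39.4-um range in water, Bragg–Kleeman
  range–energy law), with exact per-bin PRF integrals and an exact list-mode
  sampler as cross-check;
- **beta (BET)** — a condensed-history electron Monte Carlo in water
  (Katz–Penfold stopping power, Highland multiple scattering, F-18 spectrum)
  producing list-mode tables for point sources at 20 depths;
- kernel assembly, per-frequency eigenanalysis, phantom decomposition,
  forward/adjoint operators, and report tables (spectra, cross sections,
  norm vs q), orchestrated by `cpet.pipeline`.

## Worked example

`examples/alpha_null_sweep.py` builds the exact alpha PRF for the q = 5
detector, marginalizes it to the four detector configurations, and decomposes
the default 7-cylinder phantom:

```
 q  scaled_null_norm  normalized_inner_product
 2      8.110318e-01             -1.522592e-17
 3      1.407091e-05             -1.292621e-16
 4      1.139379e-15              4.269601e-17
 5      3.114295e-16              1.527667e-16
```

A position-only detector (q = 2) cannot see 81% of the object's L2 content —
with one projection and no energy or direction information, depth structure
is almost entirely in the null space.  Measuring residual energy (q = 3) or
direction (q = 4) in addition collapses the null norm to ~10⁻⁵ or below: the
straight-line alpha geometry ties each attribute combination to emission
depth tightly enough that the object is essentially fully measurable.  The
last column confirms `⟨f_meas, f_null⟩/‖f‖² = 0` to machine precision.

The beta analogue (`examples/beta_null_sweep.py`) shows the same structure
with the q = 5 norm smallest; because electrons scatter and beta spectra are
broad, all five attributes are needed before the null space nearly vanishes.
Other examples print sensitivity/PRF tables, raw transport summaries, and
eigenvalue spectra.

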