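"""Analytic alpha point response functions: sensitivity and binned PRF mass.

Builds the straight-line alpha forward model for the Pu-239-like source
(5.15 MeV, 39.4-um range in water) and shows that the exact per-bin
integration conserves the detected solid-angle fraction at every depth.
"""

import numpy as np

from cpet import AttributeSpec, BinSpec, RangeEnergyModel, alpha_prf_grid, sensitivity

model = RangeEnergyModel()
print(f"CSDA range of a 5.15-MeV alpha in water: {model.range_from_energy(5.15):.1f} um")
print(f"residual energy after 20 um of water:    {model.residual_energy(20.0)*1e3:.0f} keV")

bins = BinSpec.alpha_default()
depths = np.array([1.0, 9.0, 19.7, 29.0, 39.0])
prf = alpha_prf_grid(depths, AttributeSpec.position_energy(), bins, model)

print("\n z [um]   S(z) closed form   binned PRF mass")
for z, s, m in zip(depths, prf.sensitivity, prf.mass_per_depth()):
    print(f"  {z:5.1f}   {s:^16.6f}   {m:.6f}")
print(
    "\nS(z) = (1 - z/R0)/2 is the fraction of isotropic emissions whose straight\n"
    "path reaches the detector plane; the binned masses match it to float precision\n"
    "because the (theta, phi) cells form an exact partition of the detected solid angle."
)
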