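"""Condensed-history beta transport: list-mode data for an F-18 point source.

Simulates 20 000 beta particles from a point source at three depths in the
100-um slab and summarizes the detected events.  The same table format feeds
the histogramming and kernel pipeline.
"""

import numpy as np

from cpet import BetaSourceSpec, TransportParams, beta_slab, simulate_point_source

geom = beta_slab()
src = BetaSourceSpec.f18()
params = TransportParams()
n = 20_000

print(" depth [um]   detected   mean E at plane [keV]   mean exit angle [deg]")
for z in (5.0, 50.0, 95.0):
    t = simulate_point_source(z, n, src, params, geom, seed=17)
    fr = t.frame
    s2 = fr.s_x**2 + fr.s_y**2
    theta = np.degrees(np.arccos(np.sqrt(np.clip(1 - s2, 0, 1))))
    print(f"   {z:5.1f}      {len(t)/n:7.3f}   {fr.E_keV.mean():^21.1f}   {theta.mean():^20.1f}")
print(
    "\nDeeper sources lose more particles to absorption, and the survivors are the\n"
    "energetic, forward-going ones — the residual-energy and exit-angle\n"
    "distributions shift with source depth, which is exactly the information the\n"
    "energy and direction attributes contribute to tomography."
)
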