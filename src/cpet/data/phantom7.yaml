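# Default 7-cylinder test object.
# All lengths are fractions of the slab thickness, so the same object scales
# to the 40-um alpha and 100-um beta geometries.  Cylinders are z-axis
# aligned with uniform unit activity density; cx/cy are lateral centers,
# top is the shallowest depth.
cylinders:
  - {cx: -0.55, cy:  0.55, radius: 0.30, top: 0.10, height: 0.30, density: 1.0}
  - {cx:  0.55, cy:  0.55, radius: 0.20, top: 0.50, height: 0.25, density: 1.0}
  - {cx:  0.00, cy:  0.00, radius: 0.15, top: 0.20, height: 0.40, density: 1.0}
  - {cx: -0.60, cy: -0.50, radius: 0.10, top: 0.65, height: 0.20, density: 1.0}
  - {cx:  0.50, cy: -0.55, radius: 0.25, top: 0.05, height: 0.15, density: 1.0}
  - {cx: -0.05, cy: -0.65, radius: 0.12, top: 0.30, height: 0.55, density: 1.0}
  - {cx:  0.28, cy: -0.10, radius: 0.10, top: 0.15, height: 0.35, density: 1.0}
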