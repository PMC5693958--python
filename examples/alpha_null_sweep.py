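"""Alpha-ET four-detector comparison: scaled null norm vs q.

Builds the exact q = 5 PRF once, marginalizes it to the four detector
configurations (position; +energy; +direction; all five), and decomposes the
default 7-cylinder phantom for each.  Runs in well under a minute.
"""

from cpet import make_report, run_q_sweep

results = run_q_sweep("alpha")
report = make_report(results)
print(report["null_norms"][["q", "scaled_null_norm", "normalized_inner_product"]].to_string(index=False))
print(
    "\nThe scaled null norm ||f_null||/||f|| is the fraction of the object's L2\n"
    "content invisible to the detector.  Position-only data (q=2) miss most of the\n"
    "depth structure; adding residual energy or direction (q>=3) makes the null\n"
    "space of the straight-line alpha system essentially disappear.  The inner\n"
    "product column verifies that the two components are orthogonal."
)
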