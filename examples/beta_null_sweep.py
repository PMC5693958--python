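"""Beta (BET) four-detector comparison at reduced Monte Carlo statistics.

Simulates one list-mode data set (2e4 particles per depth here, ~1 minute;
the acceptance suite uses 1e5) and re-histograms it for the four detector
configurations.  At desk-scale statistics the Monte Carlo noise floor of the
eigenvalue spectra lies above the 1e-6 cutoff, so the q = 3 and q = 4 norms
are smaller than a converged large-n run would give; the structure — q = 2
large, norms non-increasing, q = 5 minimal — is what this script shows.
"""

from cpet import make_report, run_q_sweep

results = run_q_sweep("beta", n_particles_per_depth=20_000, seed=1)
report = make_report(results)
print(report["null_norms"][["q", "scaled_null_norm"]].to_string(index=False))
print(
    "\nPosition-only data (q=2) leave most of the object invisible; the norms are\n"
    "non-increasing as attributes are added, and with energy and direction\n"
    "measured the null space nearly vanishes — despite the continuous beta\n"
    "spectrum, the extra attributes recover depth resolution."
)
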