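"""Simulate ALEX traces, estimate correction factors, recover E_PR.

The generator injects 10% donor leakage and 5% acceptor direct excitation at
the raw-signal level; the correction stage must estimate both from
singly-labelled calibration species and remove them.
"""

import numpy as np

import alexfret as af
from alexfret import corrections as corr

# calibration: leakage from donor-only molecules, direct excitation from
# acceptor-only molecules (both simulated with the same optics)
factors, background = af.pipeline.calibrate_factors(seed=7)
print(f"estimated leakage        L = {factors.L:.4f} +/- {factors.se_L:.4f} (truth 0.10)")
print(f"estimated direct exc.    D = {factors.D:.4f} +/- {factors.se_D:.4f} (truth 0.05)")

# a non-phosphorylated kinase population: single conformation at E_PR 0.38
cfg = af.preset("H589-N", seed=8, n_molecules=200)
traces = af.simulate_traces(cfg)
summaries = corr.summarize_molecules(traces, factors, background)
doubles = [s for s in summaries if s.species == "double"]
epr = np.array([s.E_PR for s in doubles])
print(f"\n{len(doubles)} double-labelled molecules")
print(f"mean corrected E_PR = {epr.mean():.3f}  (generator truth 0.38)")
print(f"mean corrected S    = {np.mean([s.S for s in doubles]):.3f}  (calibrated to 0.57)")
# E_PR near the injected 0.38 shows leakage/direct-excitation bias was removed;
# the uncorrected ratio would land ~0.05 higher.
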