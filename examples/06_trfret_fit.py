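"""Time-resolved FRET: stretched-exponential reconvolution fitting.

Donor lifetime histograms from a heterogeneous ensemble are fitted with
I(t) = A exp(-(t/tau)^beta) convolved with the instrument response function.
A shorter fitted lifetime for the phosphorylated sample reports increased
energy transfer (donor quenching).
"""

import numpy as np

from alexfret import trfret as tr

t = np.linspace(0.0, 50.0, 2048)          # ns, TCSPC-style grid
irf = tr.gaussian_irf(t, t0=2.0, fwhm=0.3)

for label, tau_true in (("non-phosphorylated", 3.0), ("phosphorylated", 1.8)):
    decay = tr.simulate_decay(tau_true, beta=0.8, irf=irf, n_photons=10 ** 6,
                              time=t, seed=1)
    fit = tr.fit_stretched_exp(decay)
    print(f"{label:>19}: tau = {fit.tau:.3f} ns (truth {tau_true}), "
          f"beta = {fit.beta:.3f} (truth 0.8), "
          f"<tau> = {tr.mean_lifetime(fit.tau, fit.beta):.3f} ns, "
          f"chi2_red = {fit.goodness:.2f}")
# The fitted lifetimes preserve the ordering tau_N > tau_P: the phosphorylated
# (active) conformation brings the dyes closer and quenches the donor faster.
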