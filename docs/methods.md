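# Methods

## Forward model

Each molecule carries a donor, an acceptor, or both (`species_fractions`).
A double-labelled molecule occupies conformational states with proximity
ratios `true_E ∈ [0, 1]`; the state path is either static (one draw per
molecule from the state weights) or a two-state continuous-time Markov chain
with rates k12, k21 sampled once per ALEX cycle. When the mean dwell
1/(k12+k21) is shorter than a tenth of the frame time the chain is
unresolvable at the camera's duty cycle and each frame carries the
stationary-average E — the fast-exchange limit of intra-frame averaging,
matching the regime in which the conditions presets operate (no protracted
dwells, unimodal per-molecule distributions).

Noise-free per-cycle means, with `alive_D`/`alive_A` the bleaching
indicators and γ fixed to 1:

```
F_DD* = I_D0 (1 − E·alive_A) alive_D
F_DA* = I_D0 E alive_D alive_A + l·F_DD* + d·I_A0 alive_A
F_AA* = I_A0 alive_A
```

Acceptor bleaching sets the FRET term to zero thereafter, which de-quenches
the donor; donor bleaching extinguishes both donor-excited signals. Bleach
times are exponential with lifetimes `bleach_tau_D/A` (wall-clock time,
applied at cycle resolution). Per-channel backgrounds are added, the result
is Poisson-sampled, and the camera applies gain g, excess-noise factor F and
Gaussian read noise so the output variance is F²g²λ + σ_read² — the usual
EMCCD approximation; the full gain-register cascade is deliberately not
modelled since none of its structure beyond the variance inflation is
identifiable from trace-level data.

ALEX phase convention: even frame indices are donor excitation; one cycle is
a consecutive (Dex, Aex) pair; a `phase` flag covers the opposite
convention.

### Preset calibration

Defaults encode the study conditions: single states at E = 0.38 (H589-N),
0.49 (H589-P), 0.52 (L662-P) and a static 80/20 mixture of E = 0.28/0.52
(L662-N); 600 cycles of 100 ms frames; I_D0 = 1500 counts/frame so
pre-bleach traces clear the >1000-counts selection threshold; l = 0.10,
d = 0.05; backgrounds 20 counts/frame/channel; bleach lifetimes 45 s
(donor) and 30 s (acceptor), typical of oxygen-scavenged TIRF dyes over a
60 s trace; species fractions 0.70 double / 0.18 donor-only / 0.12
acceptor-only, a realistic dual-labelling yield. With γ = 1 the corrected
stoichiometry of a double-labelled molecule is analytically
I_D0/(I_D0+I_A0), so the acceptor-excitation brightness is set in closed
form to I_A0 = I_D0·(1−0.57)/0.57 ≈ 1131.6 to put the double-labelled S at
0.57; no numerical search is needed.

## Corrections

Leakage L is the median over donor-only molecules of per-molecule
ΣF_DA/ΣF_DD over pre-bleach frames (backgrounds subtracted); direct
excitation D likewise from acceptor-only molecules as ΣF_DA/ΣF_AA. Standard
errors are bootstrap over molecules (200 resamples, seeded). Backgrounds
are estimated from post-bleach baselines (median of F_DD after donor bleach
and of F_AA after acceptor bleach, pooled over molecules); with trace-table
input this replaces the local annulus estimate available at the movie
level.

Per-frame corrected quantities use F_FRET = F_DA − L·F_DD − D·F_AA;
E_PR = F_FRET/(F_FRET+F_DD) and S = (F_FRET+F_DD)/(F_FRET+F_DD+F_AA). The
per-molecule statistic is the mean of per-frame values over the
pre-first-bleach segment (median available as an option). Frames with a
nonpositive grand total are excluded and counted in `qc_flags`; E_PR
additionally requires a positive donor-excitation total (an acceptor-only
molecule has a well-defined S but no meaningful E_PR). S is computed with
the corrected numerator (F_FRET); since the correction removes exactly the
terms it adds, the population-mean S of doubles is independent of E.

Species are classified by the uncorrected S̄ over the pre-bleach segment
(s_lo = 0.2, s_hi = 0.8; donor-only above, acceptor-only below, double
between). Whole-trace sums would misclassify any double whose acceptor
bleaches early, so the pre-bleach restriction is load-bearing.

## Trace QC

Change points come from binary segmentation of the within-segment squared
error. The per-step penalty is 4·σ̂²·log n, with σ̂ the *largest* block-wise
robust noise estimate (median absolute successive difference over ~20-frame
blocks, stride 10): photon-counting traces are strongly heteroscedastic, and
a global noise estimate dominated by the quiet post-bleach baseline would
shatter the bright segment into spurious steps. The factor 4 accounts for
the maximization over split points and the recursion; bleach steps
(amplitude ≫ noise) exceed the penalty by orders of magnitude, while the
small step that acceptor bleaching leaves in the donor-excitation total
(l·E·I_D0 − d·I_A0, tens of counts) stays below it.

Acceptor bleach steps are detected on F_AA, which reports acceptor aliveness
directly. Donor steps are detected on the donor-excitation total
F_DD + F_DA — not on F_DD, where acceptor bleaching produces a de-quenching
up-step that would be miscounted — and any donor-total step within two
cycles of a detected acceptor step is attributed to the acceptor (a
dead-donor molecule still shows the direct-excitation pedestal drop when
its acceptor finally bleaches).

Selection accepts molecules with: pre-bleach donor-excitation signal (both
emission channels, background subtracted) of at least 1000 counts/cycle —
the counts threshold is interpreted this way and is configurable; at most
one bleach step per dye; no up-steps (aggregation signature); and at least
20 pre-bleach cycles. Every rejection carries a reason code
(`low_counts`, `multi_step_donor/acceptor`, `step_up`, `short_prebleach`),
making the policy auditable; re-running selection on the accepted subset is
a no-op. Anti-correlation is the Pearson r of the mean-detrended pre-bleach
F_DD/F_DA series; a static molecule's r is null-distributed (|r| ≲ 2/√n)
while conformational exchange drives it strongly negative.

## Population analysis

Gaussian mixtures are fitted to the raw per-molecule E_PR values (not to
histogram counts — binning is presentation-only) by EM with 20 seeded
restarts per candidate k ∈ {1, 2}; k is chosen by BIC, components are
reported sorted by mean, and the "peak" is the mean of the highest-weight
component. With several hundred accepted molecules the per-molecule E_PR
spread is dominated by shot noise over the pre-bleach segment, so component
SDs are small (~0.003) and trace-length heterogeneity makes the
distribution a scale mixture; on truly unimodal conditions BIC occasionally
prefers two components with coincident means, which leaves the peak
estimate unaffected. Replicate condition means are compared by one-way
ANOVA plus pairwise two-sided pooled-variance t-tests with Bonferroni
correction (factor = number of pairs). The Boltzmann utility is
f = 1/(1+exp(ΔG/RT)), R = 0.0019872 kcal/(mol·K), linking computed
activation free energies (+5.0 kcal/mol unphosphorylated, −8.0
phosphorylated) to expected equilibrium state weights.

## Imaging layer

Rendering paints each alive molecule as a 2-D Gaussian PSF (σ = 1.2 px
default) integrated exactly over pixels via error functions; pixel centers
sit at integer coordinates. The donor-channel stack carries F_DD on
donor-excitation (even) frames; the acceptor channel carries F_DA on even
and F_AA on odd frames; the acceptor view may be shifted/transformed to
exercise registration. Traces destined for rendering should be simulated
noise-free — shot noise and the camera act per pixel at render time.

Detection runs on the average of the first ten donor-excitation frames
(maximizing pre-bleach signal): difference-of-Gaussians band-pass
(σ = 1/3 px), local maxima above 5 robust SDs, 5×5 center-of-mass
refinement, minimum separation with the brighter spot winning. Channel
registration is a least-squares affine fit to mutual-nearest-neighbour spot
pairs, with a coarse median-offset pre-pass so channel shifts comparable to
the spot spacing cannot cross-pair. Photometry is the aperture sum
(r = 3 px) minus the annulus median (5–8 px) times the aperture area —
exactly invariant to any constant added to the field; an optional
PSF-enclosed-fraction correction compensates the ~4% aperture truncation.
Spots within 2·aperture radius of a neighbour or crossing the field edge
are excluded and reported.

## TR-FRET

Decays are I(t) = A·exp(−(t/τ)^β) discretely convolved with the normalized
IRF, plus a baseline, fitted by trust-region least squares on
(log A, log τ, β, baseline) with Neyman weights 1/√(counts+1), β restarted
from {0.5, 0.75, 1.0}. β = 1 nests the single exponential; the mean
lifetime is ⟨τ⟩ = (τ/β)Γ(1/β). Default grid 4096 bins over 50 ns
(tests use 2048 for speed); reduced χ² is reported.

## What the synthetic data does and does not show

The generator reproduces the distortions the analysis must remove —
crosstalk, direct excitation, background, bleaching, camera noise, species
mixtures, one- or two-state conformations — with exact ground truth, so
passing tests demonstrate that the estimators are unbiased and the pipeline
recovers injected population parameters (peaks to ±0.02, mixture weights to
a few percent) under realistic photon budgets. It does not model triplet
blinking (suppressed experimentally by oxygen scavenging), dye rotational
or photophysical heterogeneity, molecule-to-molecule brightness variation,
stage drift, or sCMOS-style structured noise; agreement on synthetic data
therefore validates the analysis, not the instrument. Problem sizes in the
tests (hundreds of molecules, 600 cycles; 10⁶-photon decays) match the
scale of the real experiments while keeping the full suite under a minute
of simulation time.

## Known limitations

* E_PR is a proximity ratio: no γ correction, no absolute distances.
* No dwell-time/kinetic analysis of the FRET trajectories (the fast-exchange
  regime leaves nothing resolvable at the camera frame time).
* The structural module's default Förster radius (60 Å) is a placeholder for
  the FlAsH/TAMRA-X pair; efficiency predictions should be read as
  direction-of-change. Comparing the real inactive/active crystal structures
  requires the user to supply the PDB files (4UWY, 3GQI); tests exercise the
  identical code path on synthetic structure pairs.
* Cycle-resolution bleaching: a bleach within a frame is applied at the next
  cycle boundary.
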