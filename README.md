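# alexfret

Single-molecule FRET analysis under alternating-laser excitation (ALEX),
built around the question of how a receptor tyrosine kinase domain changes
conformation on activation. Phosphorylation of the FGFR1 kinase domain
repositions its activation loop; with a donor dye (FlAsH on a tetracysteine
tag) and an acceptor dye (TAMRA-X on a genetically encoded handle) placed on
the mobile loop and the kinase insert, that transition appears as a shift of
the single-molecule proximity-ratio distribution. `alexfret` implements the
complete analysis for such experiments — and a physics-forward synthetic
data generator that makes every stage verifiable without any experimental
data.

## What it computes

Under ALEX, each immobilized molecule yields three signals per excitation
cycle: F_DD (donor channel, donor excitation), F_DA (acceptor channel, donor
excitation) and F_AA (acceptor channel, acceptor excitation). After
background subtraction, donor leakage *L* and acceptor direct excitation *D*
— estimated from donor-only and acceptor-only calibration molecules — are
removed:

```
F_FRET = F_DA − L·F_DD − D·F_AA
E_PR   = F_FRET / (F_FRET + F_DD)                    proximity ratio
S      = (F_FRET + F_DD) / (F_FRET + F_DD + F_AA)    stoichiometry
```

S sorts labelling species (≈1 donor-only, ≈0 acceptor-only, intermediate for
FRET pairs); E_PR is the γ-uncorrected apparent FRET efficiency. Around this
core the package provides:

* **`simulate`** — forward model of immobilized molecules under ALEX:
  one- or two-state conformations (static or two-state Markov exchange),
  leakage, direct excitation, backgrounds, exponential photobleaching of
  each dye, Poisson shot noise and an EMCCD-style camera. Named presets
  encode the study conditions (`H589-N`, `H589-P`, `L662-N`, `L662-P`,
  `DONOR-ONLY`, `ACCEPTOR-ONLY`).
* **`render` / `extract`** — paint traces into two-channel TIRF movie stacks
  (pixel-integrated Gaussian PSFs, multi-frame TIFF) and recover them:
  ALEX demultiplexing by frame parity, difference-of-Gaussians spot
  detection, affine channel registration, aperture/annulus photometry.
* **`qc`** — photobleaching change points by binary segmentation, the
  single-step single-molecule criterion, minimum-intensity selection,
  donor–acceptor anti-correlation.
* **`corrections`** — *L*/*D* estimation with bootstrap errors, species
  classification, per-molecule E_PR and S.
* **`populations`** — E_PR–S 2-D histograms, Gaussian-mixture fits with BIC
  model selection, replicate comparison by one-way ANOVA with Bonferroni
  post-hoc tests, and a Boltzmann utility converting activation free
  energies into equilibrium state populations.
* **`structure`** — Kabsch superposition of two kinase-domain structures on
  their stable lobes, per-residue Cα displacements (e.g. the activation-loop
  tyrosines Y653/Y654 between PDB entries 4UWY and 3GQI), and the Förster
  relation E = 1/(1+(r/R0)⁶).
* **`trfret`** — time-resolved FRET: stretched-exponential decays
  (I(t) = A·exp(−(t/τ)^β)) with IRF reconvolution fitting.

## Worked example

```python
import numpy as np
import alexfret as af
from alexfret import corrections as corr

factors, background = af.pipeline.calibrate_factors(seed=7)
cfg = af.preset("H589-N", seed=8, n_molecules=200)
summaries = corr.summarize_molecules(af.simulate_traces(cfg), factors, background)
doubles = [s for s in summaries if s.species == "double"]
print(np.mean([s.E_PR for s in doubles]), np.mean([s.S for s in doubles]))
```

Running `python examples/01_simulate_and_correct.py` (which does the above
with commentary) prints:

```
estimated leakage        L = 0.1001 +/- 0.0001 (truth 0.10)
estimated direct exc.    D = 0.0503 +/- 0.0001 (truth 0.05)

138 double-labelled molecules
mean corrected E_PR = 0.380  (generator truth 0.38)
mean corrected S    = 0.570  (calibrated to 0.57)
```

The generator injected 10% leakage and 5% direct excitation into the raw
signals; the pipeline estimated both from singly-labelled species to four
decimal places and recovered the true proximity ratio — uncorrected, the
same traces would read ~0.43. The other scripts in `examples/` walk through
trace QC, the four-condition population analysis (including the 80/20
conformational mixture of the non-phosphorylated L662 construct), the
movie-rendering round trip, structural displacement with Förster
predictions, and TR-FRET fitting.

A CLI mirrors the library for shell use, e.g.
`alexfret simulate --preset L662-N --seed 7 --out traces.tsv`,
`alexfret run --preset H589-N --preset H589-P --seed 7 --out run/`.

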