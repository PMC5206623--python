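"""Render a two-channel TIRF movie and re-extract the traces.

End-to-end check of the imaging layer: simulate traces, paint them onto a
camera field as pixel-integrated Gaussian PSFs (the acceptor channel is
shifted, as for a real dual-view), then detect spots, register the channels
and pull the traces back out with annulus background subtraction.
"""

import math

import numpy as np

import alexfret as af
from alexfret import extract as ex
from alexfret.render import Optics, render_movie, sample_positions

cfg = af.preset("H589-N", seed=5, n_molecules=15, n_cycles=40,
                background={"donor": 0.0, "acceptor": 0.0}, shot_noise=False,
                bleach_tau_D=math.inf, bleach_tau_A=math.inf)
traces = af.simulate_traces(cfg)
optics = Optics(field=(128, 128), channel_shift=(1.5, -0.8), background_per_px=2.0)
pos = sample_positions(len(traces), optics, np.random.default_rng(5), margin=12)
donor, acceptor = render_movie(traces, pos, optics,
                               camera=af.CameraModel(excess_noise=1.4,
                                                     read_noise_sd=3.0), seed=5)
print(f"rendered {donor.shape[0]} frames of {donor.shape[1]}x{donor.shape[2]} px "
      "per channel (even frames = donor excitation)")

dex_d, _ = ex.demultiplex_alex(donor, phase=0)
dex_a, _ = ex.demultiplex_alex(acceptor, phase=0)
dspots = ex.detect_spots(dex_d[:10].mean(axis=0), channel="donor")
aspots = ex.detect_spots(dex_a[:10].mean(axis=0), channel="acceptor")
tf = ex.register_channels(dspots, aspots)
print(f"detected {len(dspots)} donor / {len(aspots)} acceptor spots; "
      f"channel shift recovered as ({tf.b[0]:+.2f}, {tf.b[1]:+.2f}) px "
      f"(truth +1.50, -0.80), residual {tf.residual_rms:.2f} px")

spos = np.array([[s.x, s.y] for s in dspots])
etr, excluded = ex.extract_traces(donor, acceptor, spos, tf,
                                  psf_sigma=optics.psf_sigma)
errs = []
for t in etr:
    i = int(np.argmin(((pos - spos[t.molecule_id]) ** 2).sum(1)))
    if traces[i].F_DD_raw.mean() > 100:
        errs.append(abs(t.F_DD_raw.mean() - traces[i].F_DD_raw.mean())
                    / traces[i].F_DD_raw.mean())
print(f"extracted {len(etr)} traces; median |F_DD| error vs ground truth: "
      f"{100 * float(np.median(errs)):.1f}%")
# Sub-5% agreement means trace-level and movie-level analyses are interchangeable.
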