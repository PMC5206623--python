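"""Render simulated traces into two-channel TIRF movie stacks.

Each alive molecule is drawn as a 2-D Gaussian point-spread function
integrated over pixels (erf-based, so the PSF mass is exact per pixel).
Frame ordering encodes the ALEX alternation: even frame indices are donor
excitation, odd are acceptor excitation, so a trace of ``n_cycles`` cycles
becomes ``2*n_cycles`` frames per emission channel.  The donor-channel stack
carries F_DD on donor-excitation frames; the acceptor-channel stack carries
F_DA on donor-excitation frames and F_AA on acceptor-excitation frames.

Traces should be simulated noise-free (``shot_noise=False``, zero
background) when rendering: shot noise and the camera response are applied
per pixel here, on top of a uniform pixel background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import tifffile
from scipy.special import erf

from .simulate import AlexTrace, CameraModel

__all__ = ["Optics", "sample_positions", "psf_image", "render_movie", "write_movie"]


@dataclass
class Optics:
    """Imaging geometry for rendering."""

    psf_sigma: float = 1.2           # px
    field: tuple = (128, 128)        # (height, width) px
    background_per_px: float = 2.0   # photons/px/frame
    channel_shift: tuple = (0.0, 0.0)  # acceptor-channel offset (dx, dy) px
    min_separation: float = 8.0      # px, enforced by the position sampler

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")


def sample_positions(n: int, optics: Optics, rng: np.random.Generator | int | None = None,
                     margin: float = 10.0, max_tries: int = 20000) -> np.ndarray:
    """Random spot positions respecting the minimum separation (dart throwing)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h, w = optics.field
    pos: list = []
    tries = 0
    while len(pos) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n} spots at separation "
                               f"{optics.min_separation} in a {h}x{w} field")
        p = np.array([margin + rng.random() * (w - 2 * margin),
                      margin + rng.random() * (h - 2 * margin)])
        if all(np.hypot(*(p - q)) >= optics.min_separation for q in pos):
            pos.append(p)
    return np.array(pos)


def psf_image(x: float, y: float, total: float, sigma: float,
              shape: tuple) -> np.ndarray:
    """Pixel-integrated Gaussian PSF centred at (x, y), total mass ``total``.

    Pixel centers sit at integer coordinates; pixel (i, j) spans
    [j-0.5, j+0.5] x [i-0.5, i+0.5].
    """
    h, w = shape
    s = sigma * np.sqrt(2.0)
    xs = np.arange(w)
    ys = np.arange(h)
    fx = 0.5 * (erf((xs + 0.5 - x) / s) - erf((xs - 0.5 - x) / s))
    fy = 0.5 * (erf((ys + 0.5 - y) / s) - erf((ys - 0.5 - y) / s))
    return total * np.outer(fy, fx)


def render_movie(traces: Sequence[AlexTrace], positions: np.ndarray,
                 optics: Optics, camera: Optional[CameraModel] = None,
                 seed: int = 0, shot_noise: bool = True,
                 n_cycles: Optional[int] = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render traces into (donor_stack, acceptor_stack), each (2*n_cycles, H, W).

    ``positions`` are donor-channel (x, y) coordinates, one per trace; the
    acceptor channel sees the same molecules shifted by
    ``optics.channel_shift``.  Raises when positions fall outside the field.
    """
    camera = camera or CameraModel(gain=1.0, excess_noise=1.0, read_noise_sd=0.0)
    positions = np.asarray(positions, dtype=float)
    if len(positions) != len(traces):
        raise ValueError("need one position per trace")
    h, w = optics.field
    dx, dy = optics.channel_shift
    for x, y in positions:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"spot position ({x}, {y}) outside field {optics.field}")
        if not (0 <= x + dx < w and 0 <= y + dy < h):
            raise ValueError("shifted acceptor-channel position outside field")
    if n_cycles is None:
        if not traces:
            raise ValueError("n_cycles must be given when rendering an empty field")
        n_cycles = traces[0].n_cycles
    n_frames = 2 * n_cycles
    donor_mean = np.full((n_frames, h, w), optics.background_per_px, dtype=float)
    acc_mean = np.full((n_frames, h, w), optics.background_per_px, dtype=float)
    for tr, (x, y) in zip(traces, positions):
        for c in range(n_cycles):
            fd, fa = 2 * c, 2 * c + 1
            if tr.F_DD_raw[c] > 0:
                donor_mean[fd] += psf_image(x, y, tr.F_DD_raw[c], optics.psf_sigma, (h, w))
            if tr.F_DA_raw[c] > 0:
                acc_mean[fd] += psf_image(x + dx, y + dy, tr.F_DA_raw[c],
                                          optics.psf_sigma, (h, w))
            if tr.F_AA_raw[c] > 0:
                acc_mean[fa] += psf_image(x + dx, y + dy, tr.F_AA_raw[c],
                                          optics.psf_sigma, (h, w))
    rng = np.random.default_rng(seed)
    donor = camera.apply(donor_mean, rng, shot_noise)
    acceptor = camera.apply(acc_mean, rng, shot_noise)
    return donor, acceptor


def write_movie(stack: np.ndarray, path: str) -> None:
    """Write a frame stack as a multi-frame TIFF (frame index = time order)."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
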