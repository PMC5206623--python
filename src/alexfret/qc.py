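"""Single-molecule trace quality control.

Photobleaching of a dye manifests as an abrupt, irreversible intensity step;
a single step per dye certifies a single molecule.  Change points are found
by binary segmentation of the within-segment squared error with a BIC-like
per-step penalty — deterministic and adequate for step-shaped bleach events
(no dwell-time analysis is attempted).

Donor bleach steps are detected on the donor-excitation *total* (F_DD + F_DA)
rather than F_DD alone: acceptor bleaching de-quenches the donor and produces
an up-step in F_DD that would otherwise be miscounted, whereas the total is
nearly conserved across an acceptor bleach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .simulate import AlexTrace

__all__ = ["QcReport", "detect_steps", "anticorrelation", "select_molecules",
           "first_down_step", "prebleach_end"]


@dataclass
class QcReport:
    molecule_id: int
    bleach_frame_D: Optional[int]
    bleach_frame_A: Optional[int]
    n_steps_D: int
    n_steps_A: int
    mean_counts: float          # pre-bleach donor-excitation counts/cycle (both channels)
    anticorr_r: float           # Pearson r, nan if undefined
    accepted: bool
    reasons: list = field(default_factory=list)


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the median absolute successive difference (step-robust)."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (0.6744897501960817 * np.sqrt(2.0)))


def _max_local_noise(x: np.ndarray, n_blocks: int = 10) -> float:
    """Largest block-wise robust noise SD.

    Photon-counting traces are heteroscedastic: shot noise scales with the
    signal, so the pre-bleach segment is far noisier than the post-bleach
    baseline.  Penalizing with a global noise estimate would over-segment the
    bright segment; the maximum over blocks is robust to both the bleach step
    itself (median within block) and the quiet baseline.
    """
    n = len(x)
    size = min(max(n // n_blocks, 10), 20)
    step = max(size // 2, 1)
    ests = [_robust_noise_sd(x[i:i + size]) for i in range(0, max(n - size + 1, 1), step)]
    return max(ests) if ests else _robust_noise_sd(x)


def _sse(csum: np.ndarray, csum2: np.ndarray, lo: int, hi: int) -> float:
    """Within-mean SSE of x[lo:hi] from prefix sums."""
    n = hi - lo
    s = csum[hi] - csum[lo]
    s2 = csum2[hi] - csum2[lo]
    return s2 - s * s / n


def detect_steps(series: Sequence[float], penalty: Optional[float] = None) -> list[int]:
    """Change points of a piecewise-constant series by binary segmentation.

    A split at index ``k`` (first frame of the new segment) is accepted when
    it reduces the squared error by more than ``penalty``; the default penalty
    is ``sigma_hat**2 * log(n)`` per step, with ``sigma_hat`` estimated from
    successive differences.  Returns sorted, unique change points.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series must have at least 10 frames")
    if penalty is None:
        sd = _max_local_noise(x)
        penalty = max(sd * sd, 1e-12) * np.log(n) * 4.0
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def best_split(lo: int, hi: int):
        ks = np.arange(lo + 1, hi)
        if len(ks) == 0:
            return None, 0.0
        n1 = ks - lo
        n2 = hi - ks
        s1 = csum[ks] - csum[lo]
        s2 = csum[hi] - csum[ks]
        sse_split = ((csum2[hi] - csum2[lo]) - s1 * s1 / n1 - s2 * s2 / n2)
        gain = _sse(csum, csum2, lo, hi) - sse_split
        i = int(np.argmax(gain))
        return int(ks[i]), float(gain[i])

    points: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 4:
            continue
        k, gain = best_split(lo, hi)
        if k is not None and gain > penalty:
            points.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(set(points))


def _segment_means(x: np.ndarray, points: list[int]) -> list[float]:
    edges = [0] + list(points) + [len(x)]
    return [float(np.mean(x[a:b])) for a, b in zip(edges[:-1], edges[1:])]


def first_down_step(series: np.ndarray, penalty: Optional[float] = None,
                    drop_frac: float = 0.3) -> tuple[Optional[int], int, bool]:
    """First bleach-like down step of a series.

    Returns ``(first_down_point, n_steps, has_up_step)`` where a down step
    drops the segment mean by at least ``drop_frac`` of the pre-step level.
    """
    points = detect_steps(series, penalty)
    return _classify_steps(np.asarray(series, dtype=float), points, drop_frac)


def trace_steps(trace: AlexTrace, background: dict | None = None
                ) -> tuple[Optional[int], int, bool, Optional[int], int, bool]:
    """Bleach-step analysis of one trace.

    Acceptor steps are read from F_AA (direct report of acceptor aliveness).
    Donor steps are read from the donor-excitation total; steps there that
    coincide (within 2 cycles) with a detected acceptor step are attributed
    to the acceptor — a dead-donor molecule still shows the direct-excitation
    pedestal dropping when the acceptor finally bleaches.

    Returns ``(d_step, n_steps_D, up_D, a_step, n_steps_A, up_A)``.
    """
    bg_d = (background or {}).get("donor", 0.0)
    bg_a = (background or {}).get("acceptor", 0.0)
    donor_total = trace.F_DD_raw + trace.F_DA_raw - bg_d - bg_a
    faa = trace.F_AA_raw - bg_a
    a_pts = detect_steps(faa)
    d_pts = [p for p in detect_steps(donor_total)
             if not any(abs(p - q) <= 2 for q in a_pts)]
    a_step, n_a, up_a = _classify_steps(faa, a_pts)
    d_step, n_d, up_d = _classify_steps(donor_total, d_pts)
    return d_step, n_d, up_d, a_step, n_a, up_a


def _classify_steps(series: np.ndarray, points: list[int],
                    drop_frac: float = 0.3) -> tuple[Optional[int], int, bool]:
    if not points:
        return None, 0, False
    means = _segment_means(np.asarray(series, dtype=float), points)
    first_down = None
    has_up = False
    scale = max(abs(means[0]), 1.0)
    for i, p in enumerate(points):
        if means[i + 1] < means[i] - drop_frac * max(abs(means[i]), 0.1 * scale):
            if first_down is None:
                first_down = p
        elif means[i + 1] > means[i]:
            has_up = True
    return first_down, len(points), has_up


def prebleach_end(trace: AlexTrace, background: dict | None = None) -> int:
    """Last usable cycle index (exclusive): the earlier of the two detected bleaches."""
    d_step, _, _, a_step, _, _ = trace_steps(trace, background)
    ends = [e for e in (d_step, a_step) if e is not None]
    return min(ends) if ends else trace.n_cycles


def anticorrelation(f_dd: Sequence[float], f_da: Sequence[float],
                    end: Optional[int] = None) -> float:
    """Pearson r at lag 0 of the mean-detrended pre-bleach donor/acceptor signals.

    Anti-correlated fluctuations (r < 0) indicate that intensity moves between
    the channels through energy transfer rather than through shared noise.
    Returns nan for zero-variance input.
    """
    x = np.asarray(f_dd, dtype=float)[:end]
    y = np.asarray(f_da, dtype=float)[:end]
    if len(x) < 20:
        raise ValueError("need at least 20 paired frames")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r, _ = stats.pearsonr(x - x.mean(), y - y.mean())
    return float(r)


def select_molecules(traces: Sequence[AlexTrace],
                     min_mean_counts: float = 1000.0,
                     require_single_step: bool = True,
                     require_anticorr: bool = False,
                     min_prebleach_cycles: int = 20,
                     background: dict | None = None
                     ) -> tuple[list[AlexTrace], list[QcReport]]:
    """Apply the trace-selection policy and report a reason code per rejection.

    A molecule is accepted when its pre-bleach donor-excitation signal
    (both emission channels, background subtracted) averages at least
    ``min_mean_counts`` per cycle, each dye shows at most one bleach step, no
    up-steps (aggregation signature) are present, and the pre-bleach segment
    is long enough to analyse.  Re-running selection on the accepted subset
    changes nothing.
    """
    if len(traces) == 0:
        raise ValueError("no traces provided")
    bg = background or {}
    bg_d = bg.get("donor", 0.0)
    bg_a = bg.get("acceptor", 0.0)
    accepted: list[AlexTrace] = []
    reports: list[QcReport] = []
    for tr in traces:
        reasons: list[str] = []
        donor_total = tr.F_DD_raw + tr.F_DA_raw - bg_d - bg_a
        d_step, n_d, up_d, a_step, n_a, up_a = trace_steps(tr, bg)
        ends = [e for e in (d_step, a_step) if e is not None]
        end = min(ends) if ends else tr.n_cycles
        if end < min_prebleach_cycles:
            reasons.append("short_prebleach")
        mean_counts = float(np.mean(donor_total[:end])) if end > 0 else 0.0
        if mean_counts < min_mean_counts:
            reasons.append("low_counts")
        if require_single_step:
            if n_d > 1:
                reasons.append("multi_step_donor")
            if n_a > 1:
                reasons.append("multi_step_acceptor")
        if up_d or up_a:
            reasons.append("step_up")
        r = float("nan")
        if end >= 20:
            r = anticorrelation(tr.F_DD_raw, tr.F_DA_raw, end=end)
            if require_anticorr and not (r < 0):
                reasons.append("no_anticorrelation")
        ok = not reasons
        reports.append(QcReport(tr.molecule_id, d_step, a_step, n_d, n_a,
                                mean_counts, r, ok, reasons))
        if ok:
            accepted.append(tr)
    return accepted, reports
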