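"""Crosstalk / direct-excitation corrections and per-molecule E_PR and S.

Under alternating-laser excitation the acceptor channel under donor
excitation (F_DA) is contaminated by donor-emission leakage (a fraction L of
F_DD) and by direct excitation of the acceptor by the donor laser (a fraction
D of F_AA).  Both factors are estimated from singly-labelled species, for
which the FRET term vanishes, and then removed:

    F_FRET = F_DA - L*F_DD - D*F_AA
    E_PR   = F_FRET / (F_FRET + F_DD)                   (proximity ratio)
    S      = (F_FRET + F_DD) / (F_FRET + F_DD + F_AA)   (stoichiometry)

with all signals background subtracted.  E_PR is the gamma-uncorrected
proximity ratio; no absolute-distance conversion is attempted.  S separates
labelling species: ~1 for donor-only, ~0 for acceptor-only, intermediate for
doubly-labelled molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import qc as _qc
from .simulate import AlexTrace

__all__ = ["CorrectionFactors", "MoleculeSummary", "classify_species",
           "estimate_leakage", "estimate_direct_excitation", "compute_epr_s",
           "estimate_background", "summarize_molecules"]


@dataclass
class CorrectionFactors:
    L: float
    D: float
    n_donor_only: int = 0
    n_acceptor_only: int = 0
    se_L: float = 0.0
    se_D: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.L < 1.0) or not (0.0 <= self.D < 1.0):
            raise ValueError("correction factors must lie in [0, 1)")
        if self.se_L < 0 or self.se_D < 0:
            raise ValueError("standard errors must be nonnegative")


@dataclass
class MoleculeSummary:
    molecule_id: int
    E_PR: float
    S: float
    species: str
    n_frames_used: int
    qc_flags: set = field(default_factory=set)


def estimate_background(traces: Sequence[AlexTrace]) -> dict:
    """Per-channel background from post-bleach baselines.

    Donor-channel background is the median F_DD after the detected donor
    bleach; acceptor-channel background pools F_AA after acceptor bleach.
    Molecules that never bleach contribute nothing.  Returns zeros when no
    baseline frames exist.
    """
    donor_frames: list[np.ndarray] = []
    acc_frames: list[np.ndarray] = []
    for tr in traces:
        d_step, _, _ = _qc.first_down_step(tr.F_DD_raw + tr.F_DA_raw)
        a_step, _, _ = _qc.first_down_step(tr.F_AA_raw)
        if d_step is not None and d_step < tr.n_cycles - 5:
            donor_frames.append(tr.F_DD_raw[d_step + 2:])
        if a_step is not None and a_step < tr.n_cycles - 5:
            acc_frames.append(tr.F_AA_raw[a_step + 2:])
    bg_d = float(np.median(np.concatenate(donor_frames))) if donor_frames else 0.0
    bg_a = float(np.median(np.concatenate(acc_frames))) if acc_frames else 0.0
    return {"donor": max(bg_d, 0.0), "acceptor": max(bg_a, 0.0)}


def classify_species(traces: Sequence[AlexTrace], s_lo: float = 0.2,
                     s_hi: float = 0.8, background: dict | None = None,
                     ends: Sequence[int] | None = None) -> list[str]:
    """Label each molecule donor_only / acceptor_only / double by uncorrected S.

    The uncorrected per-molecule stoichiometry is the ratio of summed,
    background-subtracted donor-excitation signal to the total signal over
    the pre-first-bleach segment (a double-labelled molecule looks donor-only
    once its acceptor has bleached, so whole-trace sums would misclassify).
    ``ends`` supplies a precomputed pre-bleach end per trace; otherwise it is
    detected here.  All-zero traces are labelled ``"unclassified"``.
    """
    if not (0.0 <= s_lo < s_hi <= 1.0):
        raise ValueError("require 0 <= s_lo < s_hi <= 1")
    bg = background or {}
    bg_d = bg.get("donor", 0.0)
    bg_a = bg.get("acceptor", 0.0)
    if ends is None:
        ends = [_qc.prebleach_end(tr, bg) for tr in traces]
    labels = []
    for tr, end in zip(traces, ends):
        end = end if end and end > 0 else tr.n_cycles
        dex = float(np.sum(tr.F_DD_raw[:end] - bg_d) + np.sum(tr.F_DA_raw[:end] - bg_a))
        aex = float(np.sum(tr.F_AA_raw[:end] - bg_a))
        total = dex + aex
        if total <= 0:
            labels.append("unclassified")
            continue
        s_bar = dex / total
        if s_bar > s_hi:
            labels.append("donor_only")
        elif s_bar < s_lo:
            labels.append("acceptor_only")
        else:
            labels.append("double")
    return labels


def _per_molecule_ratio(traces: Sequence[AlexTrace], num, den,
                        bleach_series, background: dict,
                        min_molecules: int, what: str,
                        n_boot: int = 200, seed: int = 0
                        ) -> tuple[float, float, int]:
    ratios = []
    for tr in traces:
        series = bleach_series(tr)
        step, _, _ = _qc.first_down_step(series)
        end = step if step is not None else tr.n_cycles
        if end < 5:
            continue
        n = float(np.sum(num(tr)[:end]))
        d = float(np.sum(den(tr)[:end]))
        if d > 0:
            ratios.append(n / d)
    if len(ratios) < min_molecules:
        raise ValueError(
            f"need at least {min_molecules} usable {what} molecules for calibration "
            f"(got {len(ratios)}); provide a {what} calibration set")
    ratios = np.asarray(ratios)
    est = float(np.median(ratios))
    rng = np.random.default_rng(seed)
    boots = [np.median(rng.choice(ratios, size=len(ratios), replace=True))
             for _ in range(n_boot)]
    return est, float(np.std(boots)), len(ratios)


def estimate_leakage(donor_only: Sequence[AlexTrace], background: dict | None = None,
                     min_molecules: int = 10, seed: int = 0) -> tuple[float, float, int]:
    """Leakage L: median per-molecule F_DA/F_DD over pre-bleach frames of
    donor-only molecules, backgrounds subtracted.  Returns (L, bootstrap SE, n)."""
    bg = background or {}
    bg_d, bg_a = bg.get("donor", 0.0), bg.get("acceptor", 0.0)
    return _per_molecule_ratio(
        donor_only,
        num=lambda t: t.F_DA_raw - bg_a,
        den=lambda t: t.F_DD_raw - bg_d,
        bleach_series=lambda t: t.F_DD_raw,
        background=bg, min_molecules=min_molecules, what="donor-only", seed=seed)


def estimate_direct_excitation(acceptor_only: Sequence[AlexTrace],
                               background: dict | None = None,
                               min_molecules: int = 10, seed: int = 0
                               ) -> tuple[float, float, int]:
    """Direct excitation D: median per-molecule F_DA/F_AA over pre-bleach frames
    of acceptor-only molecules, backgrounds subtracted.  Returns (D, SE, n)."""
    bg = background or {}
    bg_a = bg.get("acceptor", 0.0)
    return _per_molecule_ratio(
        acceptor_only,
        num=lambda t: t.F_DA_raw - bg_a,
        den=lambda t: t.F_AA_raw - bg_a,
        bleach_series=lambda t: t.F_AA_raw,
        background=bg, min_molecules=min_molecules, what="acceptor-only", seed=seed)


def estimate_factors(donor_only: Sequence[AlexTrace],
                     acceptor_only: Sequence[AlexTrace],
                     background: dict | None = None, seed: int = 0
                     ) -> CorrectionFactors:
    """Convenience: estimate both factors from the two calibration sets."""
    L, se_L, n_d = estimate_leakage(donor_only, background, seed=seed)
    D, se_D, n_a = estimate_direct_excitation(acceptor_only, background, seed=seed)
    return CorrectionFactors(L=min(max(L, 0.0), 0.999), D=min(max(D, 0.0), 0.999),
                             n_donor_only=n_d, n_acceptor_only=n_a,
                             se_L=se_L, se_D=se_D)


def compute_epr_s(trace: AlexTrace, factors: CorrectionFactors,
                  background: dict | None = None,
                  prebleach_end: Optional[int] = None,
                  statistic: str = "mean",
                  species: str = "double"
                  ) -> tuple[MoleculeSummary, np.ndarray, np.ndarray]:
    """Corrected per-frame and per-molecule proximity ratio and stoichiometry.

    Per-molecule values are the ``statistic`` ("mean" or "median") of the
    per-frame values over the pre-first-bleach segment.  Frames whose total
    corrected signal is nonpositive are excluded and counted in
    ``qc_flags``.  Raises ValueError when no usable frames remain.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    bg = background or {}
    f_dd = trace.F_DD_raw - bg.get("donor", 0.0)
    f_da = trace.F_DA_raw - bg.get("acceptor", 0.0)
    f_aa = trace.F_AA_raw - bg.get("acceptor", 0.0)
    end = prebleach_end if prebleach_end is not None else trace.n_cycles
    f_dd, f_da, f_aa = f_dd[:end], f_da[:end], f_aa[:end]

    f_fret = f_da - factors.L * f_dd - factors.D * f_aa
    dex_total = f_fret + f_dd
    total = dex_total + f_aa
    # E_PR needs a positive donor-excitation total; S only a positive grand
    # total (an acceptor-only molecule has a well-defined S but no E_PR)
    epr = np.where(dex_total > 0, f_fret / np.where(dex_total > 0, dex_total, 1.0), np.nan)
    s = np.where(total > 0, dex_total / np.where(total > 0, total, 1.0), np.nan)

    flags = set()
    usable_s = np.isfinite(s)
    usable_e = np.isfinite(epr)
    n_bad = int(len(s) - usable_s.sum())
    if n_bad:
        flags.add(f"excluded_frames:{n_bad}")
    if usable_s.sum() == 0:
        raise ValueError(f"molecule {trace.molecule_id}: zero usable frames")
    agg = np.nanmean if statistic == "mean" else np.nanmedian
    summary = MoleculeSummary(
        molecule_id=trace.molecule_id,
        E_PR=float(agg(epr[usable_e])) if usable_e.any() else float("nan"),
        S=float(agg(s[usable_s])),
        species=species,
        n_frames_used=int(usable_s.sum()),
        qc_flags=flags,
    )
    return summary, epr, s


def summarize_molecules(traces: Sequence[AlexTrace], factors: CorrectionFactors,
                        background: dict | None = None,
                        reports: Optional[Sequence["_qc.QcReport"]] = None,
                        s_lo: float = 0.2, s_hi: float = 0.8,
                        statistic: str = "mean") -> list[MoleculeSummary]:
    """Per-molecule corrected summaries for a batch of traces.

    Species labels come from uncorrected stoichiometry; the pre-bleach segment
    comes from the matching QC report when provided, otherwise it is detected
    here.  Molecules with no usable frames are dropped.
    """
    by_id = {r.molecule_id: r for r in reports} if reports is not None else {}
    ends = []
    for tr in traces:
        rep = by_id.get(tr.molecule_id)
        if rep is not None:
            bl = [e for e in (rep.bleach_frame_D, rep.bleach_frame_A) if e is not None]
            ends.append(min(bl) if bl else tr.n_cycles)
        else:
            ends.append(_qc.prebleach_end(tr, background))
    labels = classify_species(traces, s_lo=s_lo, s_hi=s_hi, background=background,
                              ends=ends)
    out = []
    for tr, sp, end in zip(traces, labels, ends):
        if end < 1:
            continue
        try:
            summ, _, _ = compute_epr_s(tr, factors, background,
                                       prebleach_end=end, statistic=statistic,
                                       species=sp)
        except ValueError:
            continue
        out.append(summ)
    return out
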