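"""Tidy-table and key-value serialization for traces and correction factors."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .corrections import CorrectionFactors, MoleculeSummary
from .simulate import AlexTrace, TraceTruth

__all__ = ["traces_to_frame", "frame_to_traces", "write_traces", "read_traces",
           "write_factors", "read_factors", "summaries_to_frame"]

_TRUTH_COLS = ("species", "true_E", "bleach_cycle_D", "bleach_cycle_A")


def traces_to_frame(traces: Sequence[AlexTrace]) -> pd.DataFrame:
    """One row per molecule per cycle; truth columns included when present."""
    rows = []
    for tr in traces:
        n = tr.n_cycles
        rec = {
            "molecule_id": np.full(n, tr.molecule_id),
            "cycle": np.arange(n),
            "F_DD_raw": tr.F_DD_raw,
            "F_DA_raw": tr.F_DA_raw,
            "F_AA_raw": tr.F_AA_raw,
        }
        if tr.truth is not None:
            rec["species"] = np.full(n, tr.truth.species)
            rec["true_E"] = tr.truth.true_E
            rec["bleach_cycle_D"] = np.full(n, -1 if tr.truth.bleach_cycle_D is None
                                            else tr.truth.bleach_cycle_D)
            rec["bleach_cycle_A"] = np.full(n, -1 if tr.truth.bleach_cycle_A is None
                                            else tr.truth.bleach_cycle_A)
        rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[AlexTrace]:
    has_truth = all(c in df.columns for c in _TRUTH_COLS)
    traces = []
    for mid, g in df.groupby("molecule_id", sort=True):
        g = g.sort_values("cycle")
        truth = None
        if has_truth:
            bd = int(g["bleach_cycle_D"].iloc[0])
            ba = int(g["bleach_cycle_A"].iloc[0])
            truth = TraceTruth(species=str(g["species"].iloc[0]),
                               true_E=g["true_E"].to_numpy(float),
                               bleach_cycle_D=None if bd < 0 else bd,
                               bleach_cycle_A=None if ba < 0 else ba,
                               bleach_time_D=math.inf, bleach_time_A=math.inf)
        traces.append(AlexTrace(int(mid),
                                g["F_DD_raw"].to_numpy(float),
                                g["F_DA_raw"].to_numpy(float),
                                g["F_AA_raw"].to_numpy(float),
                                truth=truth))
    return traces


def write_traces(traces: Sequence[AlexTrace], path: str) -> None:
    traces_to_frame(traces).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_traces(path: str) -> list[AlexTrace]:
    return frame_to_traces(pd.read_csv(path, sep="\t"))


def write_factors(factors: CorrectionFactors, path: str) -> None:
    with open(path, "w") as fh:
        for k in ("L", "D", "se_L", "se_D", "n_donor_only", "n_acceptor_only"):
            fh.write(f"{k} = {getattr(factors, k)}\n")


def read_factors(path: str) -> CorrectionFactors:
    kv = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                kv[k.strip()] = v.strip()
    return CorrectionFactors(L=float(kv["L"]), D=float(kv["D"]),
                             se_L=float(kv.get("se_L", 0)), se_D=float(kv.get("se_D", 0)),
                             n_donor_only=int(kv.get("n_donor_only", 0)),
                             n_acceptor_only=int(kv.get("n_acceptor_only", 0)))


def summaries_to_frame(summaries: Sequence[MoleculeSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "molecule_id": s.molecule_id, "E_PR": s.E_PR, "S": s.S,
        "species": s.species, "n_frames_used": s.n_frames_used,
        "qc_flags": ";".join(sorted(s.qc_flags)),
    } for s in summaries])
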