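"""Structural comparison of kinase-domain conformations and Förster predictions.

The inactive and active (phosphorylated) FGFR1 kinase-domain crystal
structures differ chiefly in the activation loop (A-loop), whose
repositioning moves the critical tyrosines Y653/Y654 by tens of ångströms.
This module superposes two structures on their stable scaffold (Kabsch
least-squares, excluding the mobile loops from the alignment set), measures
per-residue Cα displacements in the common frame, and converts dye-pair
distances into FRET efficiencies through the Förster relation
``E = 1 / (1 + (r/R0)^6)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import gemmi
import numpy as np

__all__ = ["ResidueSelection", "load_ca_coordinates", "kabsch_superpose",
           "residue_displacement", "forster_efficiency",
           "A_LOOP_SPAN", "KI_SPAN", "DEFAULT_R0"]

# FGFR1 kinase-domain mobile regions, author numbering
A_LOOP_SPAN = (640, 670)
KI_SPAN = (575, 595)
DEFAULT_R0 = 60.0  # Å, placeholder for the FlAsH/TAMRA-X pair (not measured)


@dataclass
class ResidueSelection:
    """Residues to align on or measure, in author numbering."""

    chain: str = "A"
    residues: Sequence[int] = ()
    atom: str = "CA"

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError("residue selection must be nonempty")


def load_ca_coordinates(path: str, chain: str = "A", atom: str = "CA"
                        ) -> Dict[int, np.ndarray]:
    """Author-numbered residue -> atom coordinate (Å) from a PDB/mmCIF file."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    coords: Dict[int, np.ndarray] = {}
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            a = res.find_atom(atom, "*")
            if a is not None:
                coords[res.seqid.num] = np.array([a.pos.x, a.pos.y, a.pos.z])
    if not coords:
        raise ValueError(f"no {atom} atoms found in chain {chain!r} of {path}")
    return coords


def kabsch_superpose(coords_ref: np.ndarray, coords_mov: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_mov`` onto ``coords_ref``.

    Returns ``(R, t, rmsd)`` with a proper rotation (det = +1; reflections are
    disallowed even when they would fit better) such that
    ``coords_mov @ R.T + t`` best matches ``coords_ref``.
    """
    P = np.asarray(coords_ref, dtype=float)
    Q = np.asarray(coords_mov, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 paired points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = Q0.T @ P0
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return R, t, rmsd


def _exclude(resnum: int, spans: Sequence[Tuple[int, int]]) -> bool:
    return any(lo <= resnum <= hi for lo, hi in spans)


@dataclass
class DisplacementResult:
    per_residue: Dict[int, float]
    mean: float
    rmsd_align: float
    n_align: int
    missing: list = field(default_factory=list)


def residue_displacement(coords_a: Dict[int, np.ndarray],
                         coords_b: Dict[int, np.ndarray],
                         measure: Sequence[int],
                         align_on: Optional[Sequence[int]] = None,
                         exclude_spans: Sequence[Tuple[int, int]] = (A_LOOP_SPAN, KI_SPAN),
                         ) -> DisplacementResult:
    """Per-residue displacement (Å) between two conformations in a common frame.

    Structure B is superposed onto structure A using ``align_on`` residues
    (default: all residues resolved in both structures, minus the mobile
    spans — A-loop and kinase-insert — so loop motion is measured relative to
    the stable lobes).  Residues of ``measure`` missing from either model are
    listed in ``missing`` and excluded with a warning.
    """
    import warnings
    common = sorted(set(coords_a) & set(coords_b))
    if align_on is None:
        align_on = [r for r in common if not _exclude(r, exclude_spans)]
    align_on = [r for r in align_on if r in coords_a and r in coords_b]
    if len(align_on) < 3:
        raise ValueError("need at least 3 alignment residues common to both structures")
    P = np.array([coords_a[r] for r in align_on])
    Q = np.array([coords_b[r] for r in align_on])
    R, t, rmsd = kabsch_superpose(P, Q)

    per_res: Dict[int, float] = {}
    missing = []
    for r in measure:
        if r not in coords_a or r not in coords_b:
            missing.append(r)
            continue
        b_moved = R @ coords_b[r] + t
        per_res[r] = float(np.linalg.norm(coords_a[r] - b_moved))
    if missing:
        warnings.warn(f"residues missing from one model, excluded: {missing}")
    if not per_res:
        raise ValueError("no measurable residues present in both structures")
    return DisplacementResult(per_residue=per_res,
                              mean=float(np.mean(list(per_res.values()))),
                              rmsd_align=rmsd, n_align=len(align_on),
                              missing=missing)


def forster_efficiency(r: float, R0: float = DEFAULT_R0) -> float:
    """FRET efficiency at donor-acceptor distance ``r`` for Förster radius ``R0``.

    E = 1/(1 + (r/R0)^6); E(R0) = 0.5 by definition of the Förster radius.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or R0 <= 0:
        raise ValueError("distances must be positive")
    out = 1.0 / (1.0 + (r / R0) ** 6)
    return float(out) if out.ndim == 0 else out
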