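"""Forward simulation of immobilized single molecules under alternating-laser excitation.

The generator emits, per molecule and per ALEX cycle, the three raw signals a
two-colour TIRF experiment records:

* ``F_DD`` -- donor channel under donor excitation,
* ``F_DA`` -- acceptor channel under donor excitation,
* ``F_AA`` -- acceptor channel under acceptor excitation.

The noise-free means follow the standard ALEX forward model with proximity
ratio ``E`` (gamma fixed to 1)::

    F_DD* = I_D0 * (1 - E) * alive_D
    F_DA* = I_D0 * E * alive_D * alive_A  +  l * F_DD*  +  d * I_A0 * alive_A
    F_AA* = I_A0 * alive_A

where ``l`` is donor-emission leakage into the acceptor channel and ``d`` the
direct excitation of the acceptor by the donor laser -- exactly the two
distortions the downstream correction stage must remove.  Photobleaching of
the acceptor de-quenches the donor (``E -> 0`` thereafter); donor bleaching
extinguishes both donor-excited signals.  Per-channel backgrounds are added,
then Poisson shot noise and an EMCCD-style camera (gain, excess noise, read
noise, offset) are applied.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "CameraModel",
    "Exchange",
    "SimulationConfig",
    "TraceTruth",
    "AlexTrace",
    "PRESET_NAMES",
    "preset",
    "markov_state_path",
    "simulate_traces",
]

SPECIES = ("donor_only", "acceptor_only", "double")


@dataclass(frozen=True)
class CameraModel:
    """EMCCD-style camera response.

    Output counts for an expected photon number ``n`` are
    ``offset + gain*Poisson(n) + N(0, sqrt(read^2 + (F^2-1)*gain^2*n))`` so the
    total variance matches the usual excess-noise approximation
    ``F^2 * gain^2 * n + read^2``.  The full gain-register cascade is not
    modelled.
    """

    gain: float = 1.0
    excess_noise: float = math.sqrt(2.0)
    read_noise_sd: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("camera gain must be > 0")
        if self.excess_noise < 1:
            raise ValueError("excess_noise must be >= 1")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    def apply(self, photons: np.ndarray, rng: np.random.Generator,
              shot_noise: bool = True) -> np.ndarray:
        """Apply shot noise and camera response to expected photon counts."""
        lam = np.clip(np.asarray(photons, dtype=float), 0.0, None)
        if not shot_noise:
            return self.offset + self.gain * lam
        n = rng.poisson(lam).astype(float)
        sd = np.sqrt(self.read_noise_sd ** 2
                     + (self.excess_noise ** 2 - 1.0) * self.gain ** 2 * n)
        out = self.offset + self.gain * n
        if np.any(sd > 0):
            out = out + rng.normal(0.0, 1.0, size=n.shape) * sd
        return out


@dataclass(frozen=True)
class Exchange:
    """Conformational exchange between the two FRET states.

    ``mode='static'``: each molecule stays in one state drawn from the state
    weights.  ``mode='markov'``: a two-state continuous-time Markov chain with
    rates ``k12`` (state 0 -> 1) and ``k21`` (state 1 -> 0), sampled once per
    ALEX cycle.  When the mean dwell ``1/(k12+k21)`` is shorter than a tenth
    of the frame time the chain is unresolvable and each frame reports the
    stationary-average E (fast-exchange limit).
    """

    mode: str = "static"
    k12: float = 0.0
    k21: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("static", "markov"):
            raise ValueError(f"exchange mode must be 'static' or 'markov', got {self.mode!r}")
        if self.k12 < 0 or self.k21 < 0:
            raise ValueError("exchange rates must be nonnegative")


@dataclass
class SimulationConfig:
    """Full parameterization of the ALEX forward model."""

    n_molecules: int = 400
    n_cycles: int = 600
    frame_time: float = 0.1  # seconds per excitation frame; a cycle is two frames
    species_fractions: dict = field(
        default_factory=lambda: {"donor_only": 0.18, "acceptor_only": 0.12, "double": 0.70})
    states: Sequence[tuple] = ((0.5, 1.0),)  # (true_E, weight)
    exchange: Exchange = field(default_factory=Exchange)
    I_D0: float = 1500.0   # mean donor-excitation counts/frame, double label, E=0
    I_A0: float = 1131.6   # mean acceptor-excitation counts/frame
    l_true: float = 0.10
    d_true: float = 0.05
    bleach_tau_D: float = math.inf  # seconds
    bleach_tau_A: float = math.inf
    background: dict = field(default_factory=lambda: {"donor": 0.0, "acceptor": 0.0})
    camera: CameraModel = field(default_factory=CameraModel)
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1 or self.n_cycles < 1:
            raise ValueError("n_molecules and n_cycles must be >= 1")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        frac = self.species_fractions
        if set(frac) != set(SPECIES):
            raise ValueError(f"species_fractions must have keys {SPECIES}")
        if any(v < 0 for v in frac.values()):
            raise ValueError("species fractions must be nonnegative")
        if abs(sum(frac.values()) - 1.0) > 1e-12:
            raise ValueError("species_fractions must sum to 1")
        if not self.states:
            raise ValueError("at least one FRET state required")
        for e, w in self.states:
            if not (0.0 <= e <= 1.0):
                raise ValueError(f"true_E must lie in [0, 1], got {e}")
            if w < 0:
                raise ValueError("state weights must be nonnegative")
        if abs(sum(w for _, w in self.states) - 1.0) > 1e-9:
            raise ValueError("state weights must sum to 1")
        if not (0.0 <= self.l_true < 1.0) or not (0.0 <= self.d_true < 1.0):
            raise ValueError("l_true and d_true must lie in [0, 1)")
        if self.I_D0 < 0 or self.I_A0 < 0:
            raise ValueError("brightnesses must be nonnegative")
        if self.bleach_tau_D <= 0 or self.bleach_tau_A <= 0:
            raise ValueError("bleach lifetimes must be positive (inf = no bleaching)")
        if any(v < 0 for v in self.background.values()):
            raise ValueError("backgrounds must be nonnegative")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TraceTruth:
    """Ground-truth annotations attached to a simulated trace."""

    species: str
    true_E: np.ndarray            # effective E per cycle (before bleach gating)
    bleach_cycle_D: Optional[int]  # first cycle with the dye dark, None = never
    bleach_cycle_A: Optional[int]
    bleach_time_D: float           # continuous bleach time, seconds (inf = never)
    bleach_time_A: float


@dataclass
class AlexTrace:
    """Per-molecule ALEX time series of the three raw signals."""

    molecule_id: int
    F_DD_raw: np.ndarray
    F_DA_raw: np.ndarray
    F_AA_raw: np.ndarray
    truth: Optional[TraceTruth] = None

    def __post_init__(self) -> None:
        if not (len(self.F_DD_raw) == len(self.F_DA_raw) == len(self.F_AA_raw)):
            raise ValueError("all three series must have the same length")
        for arr in (self.F_DD_raw, self.F_DA_raw, self.F_AA_raw):
            if not np.all(np.isfinite(arr)):
                raise ValueError("trace counts must be finite")

    @property
    def n_cycles(self) -> int:
        return len(self.F_DD_raw)


# ---------------------------------------------------------------------------
# Presets

PRESET_NAMES = ("H589-N", "H589-P", "L662-N", "L662-P", "DONOR-ONLY", "ACCEPTOR-ONLY")


def _preset_path(name: str):
    fname = name.lower().replace("-", "_") + ".yaml"
    return resources.files("alexfret.presets").joinpath(fname)


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Load a named study-condition preset.

    The four condition presets encode the population parameters of the
    labelled FGFR1 kinase-domain constructs: H589-N (single state E=0.38),
    H589-P (E=0.49), L662-N (two states, E=0.28 at weight 0.8 and E=0.52 at
    weight 0.2) and L662-P (E=0.52).  DONOR-ONLY and ACCEPTOR-ONLY are the
    singly-labelled calibration species used to estimate leakage and direct
    excitation.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")
    raw = yaml.safe_load(_preset_path(name).read_text())
    raw.pop("comment", None)
    states = tuple((float(e), float(w)) for e, w in raw.pop("states"))
    camera = CameraModel(**raw.pop("camera"))
    exchange = Exchange(**raw.pop("exchange"))
    for key in ("bleach_tau_D", "bleach_tau_A"):
        if isinstance(raw.get(key), str):
            raw[key] = math.inf
    cfg = SimulationConfig(states=states, camera=camera, exchange=exchange,
                           seed=seed, **raw)
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg


# ---------------------------------------------------------------------------
# Two-state Markov dynamics

def markov_state_path(k12: float, k21: float, dt: float, n: int,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Sample a two-state CTMC at regular intervals ``dt``.

    The initial state is drawn from the stationary distribution
    ``P(state 1) = k12/(k12+k21)``.  Returns an int8 array of {0, 1}.
    """
    if k12 < 0 or k21 < 0:
        raise ValueError("rates must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ktot = k12 + k21
    if ktot == 0:
        return np.zeros(n, dtype=np.int8)
    p1 = k12 / ktot
    state = int(rng.random() < p1)
    # Gillespie jump chain, then sample on the regular grid.
    total_t = n * dt
    jump_times = []
    jump_states = []
    t = 0.0
    s = state
    while t < total_t:
        rate = k12 if s == 0 else k21
        if rate == 0:
            break
        t += rng.exponential(1.0 / rate)
        s = 1 - s
        jump_times.append(t)
        jump_states.append(s)
    if not jump_times:
        return np.full(n, state, dtype=np.int8)
    grid = np.arange(n) * dt
    idx = np.searchsorted(np.asarray(jump_times), grid, side="right")
    states_after = np.concatenate(([state], np.asarray(jump_states, dtype=np.int8)))
    return states_after[idx].astype(np.int8)


# ---------------------------------------------------------------------------
# Trace simulation

def _effective_E(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-cycle effective E for one double-labelled molecule."""
    states = np.array([e for e, _ in cfg.states])
    weights = np.array([w for _, w in cfg.states])
    ex = cfg.exchange
    if ex.mode == "static" or len(states) == 1:
        idx = rng.choice(len(states), p=weights)
        return np.full(cfg.n_cycles, states[idx])
    ktot = ex.k12 + ex.k21
    cycle_time = 2.0 * cfg.frame_time
    if ktot > 0 and 1.0 / ktot < cfg.frame_time / 10.0:
        # unresolvably fast: each frame averages over the stationary ensemble
        p1 = ex.k12 / ktot
        e_bar = (1 - p1) * states[0] + p1 * states[1]
        return np.full(cfg.n_cycles, e_bar)
    path = markov_state_path(ex.k12, ex.k21, cycle_time, cfg.n_cycles, rng)
    return states[path]


def simulate_traces(cfg: SimulationConfig) -> list[AlexTrace]:
    """Simulate ``cfg.n_molecules`` ALEX traces with full ground truth.

    Seeded runs are bit-reproducible.  Acceptor photobleaching sets E to zero
    thereafter (donor de-quenching); donor photobleaching extinguishes F_DD
    and the FRET term.
    """
    rng = np.random.default_rng(cfg.seed)
    n_mol, n_cyc = cfg.n_molecules, cfg.n_cycles
    fracs = np.array([cfg.species_fractions[s] for s in SPECIES])
    species_idx = rng.choice(len(SPECIES), size=n_mol, p=fracs)
    cycle_time = 2.0 * cfg.frame_time
    bg_d = cfg.background.get("donor", 0.0)
    bg_a = cfg.background.get("acceptor", 0.0)

    traces: list[AlexTrace] = []
    t_grid = np.arange(n_cyc) * cycle_time
    for m in range(n_mol):
        sp = SPECIES[species_idx[m]]
        has_D = sp in ("donor_only", "double")
        has_A = sp in ("acceptor_only", "double")
        tb_D = rng.exponential(cfg.bleach_tau_D) if (has_D and math.isfinite(cfg.bleach_tau_D)) else math.inf
        tb_A = rng.exponential(cfg.bleach_tau_A) if (has_A and math.isfinite(cfg.bleach_tau_A)) else math.inf
        alive_D = (t_grid < tb_D) & has_D
        alive_A = (t_grid < tb_A) & has_A
        if sp == "double":
            e_path = _effective_E(cfg, rng)
        else:
            e_path = np.zeros(n_cyc)
        e_c = e_path * alive_A  # acceptor bleach de-quenches the donor
        f_dd = cfg.I_D0 * (1.0 - e_c) * alive_D
        f_da = (cfg.I_D0 * e_c * alive_D
                + cfg.l_true * f_dd
                + cfg.d_true * cfg.I_A0 * alive_A)
        f_aa = cfg.I_A0 * alive_A

        F_DD = cfg.camera.apply(f_dd + bg_d, rng, cfg.shot_noise)
        F_DA = cfg.camera.apply(f_da + bg_a, rng, cfg.shot_noise)
        F_AA = cfg.camera.apply(f_aa + bg_a, rng, cfg.shot_noise)

        def _bleach_cycle(tb: float, present: bool) -> Optional[int]:
            if not present or not math.isfinite(tb):
                return None
            c = int(math.ceil(tb / cycle_time))
            return c if c < n_cyc else None

        truth = TraceTruth(
            species=sp,
            true_E=e_path,
            bleach_cycle_D=_bleach_cycle(tb_D, has_D),
            bleach_cycle_A=_bleach_cycle(tb_A, has_A),
            bleach_time_D=tb_D if has_D else math.inf,
            bleach_time_A=tb_A if has_A else math.inf,
        )
        traces.append(AlexTrace(m, F_DD, F_DA, F_AA, truth=truth))
    return traces
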