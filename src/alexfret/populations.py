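"""Population-level analysis of corrected E_PR / S values.

Per-molecule proximity ratios are summarized as E_PR-S 2-D histograms and
fitted with one- or two-component Gaussian mixtures; the number of
components is chosen by BIC.  The mixture is fitted to the raw per-molecule
values, not to histogram counts, so binning is presentation-only.  A small
Boltzmann utility converts an activation free-energy difference into the
equilibrium active-state fraction expected at a given temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Sequence

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = ["PopulationFit", "ConditionComparison", "histogram2d_epr_s",
           "fit_gmm", "compare_conditions", "boltzmann_fraction"]

R_KCAL = 0.0019872  # gas constant, kcal/(mol*K)


@dataclass
class PopulationFit:
    condition: str
    n_molecules: int
    epr_values: np.ndarray
    bin_edges: np.ndarray
    histogram: np.ndarray
    k_selected: int
    components: list          # (mean, sd, weight), sorted by mean
    bic: Dict[int, float]
    peak_epr: float           # mean of the highest-weight component

    @property
    def weights(self) -> list:
        return [w for _, _, w in self.components]


@dataclass
class ConditionComparison:
    means: Dict[str, float]
    sds: Dict[str, float]
    replicate_means: Dict[str, list]
    anova_F: float
    anova_p: float
    pairwise_p: Dict[tuple, float]        # raw two-sided t-test p-values
    pairwise_p_adj: Dict[tuple, float]    # Bonferroni-adjusted


def histogram2d_epr_s(epr: Sequence[float], s: Sequence[float],
                      epr_bins: np.ndarray | int = 40,
                      s_bins: np.ndarray | int = 40,
                      epr_range: tuple = (-0.1, 1.1),
                      s_range: tuple = (0.0, 1.0)):
    """E_PR-S 2-D histogram with its two marginal 1-D histograms.

    Returns ``(H, epr_edges, s_edges, epr_marginal, s_marginal)``; the
    marginals are exactly the row/column sums of H and conserve the total
    molecule count.
    """
    epr = np.asarray(epr, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(epr) == 0:
        raise ValueError("no molecules to histogram")
    if np.isscalar(epr_bins):
        epr_bins = np.linspace(*epr_range, int(epr_bins) + 1)
    if np.isscalar(s_bins):
        s_bins = np.linspace(*s_range, int(s_bins) + 1)
    H, xe, ye = np.histogram2d(np.clip(epr, epr_bins[0], epr_bins[-1]),
                               np.clip(s, s_bins[0], s_bins[-1]),
                               bins=[epr_bins, s_bins])
    return H, xe, ye, H.sum(axis=1), H.sum(axis=0)


def fit_gmm(epr_values: Sequence[float], k_candidates: Sequence[int] = (1, 2),
            n_starts: int = 20, seed: int = 0, condition: str = "",
            epr_bins: np.ndarray | int = 40) -> PopulationFit:
    """Gaussian-mixture fit of per-molecule E_PR values with BIC selection.

    EM is restarted ``n_starts`` times per candidate k (seeded); components
    are reported sorted by mean, and ``peak_epr`` is the mean of the
    highest-weight (dominant) component.  Requires >= 50 values when any
    candidate k exceeds 1.
    """
    x = np.asarray(epr_values, dtype=float)
    x = x[np.isfinite(x)]
    if max(k_candidates) > 1 and len(x) < 50:
        raise ValueError("need at least 50 values for multi-component fits")
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    X = x.reshape(-1, 1)
    bic: Dict[int, float] = {}
    fits: Dict[int, GaussianMixture] = {}
    for k in sorted(k_candidates):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=n_starts, random_state=seed,
                             reg_covar=1e-8)
        gm.fit(X)
        bic[k] = float(gm.bic(X))
        fits[k] = gm
    k_sel = min(bic, key=bic.get)
    gm = fits[k_sel]
    comps = sorted(
        [(float(m[0]), float(np.sqrt(c[0, 0])), float(w))
         for m, c, w in zip(gm.means_, gm.covariances_, gm.weights_)],
        key=lambda t: t[0])
    peak = max(comps, key=lambda t: t[2])[0]
    if np.isscalar(epr_bins):
        epr_bins = np.linspace(-0.1, 1.1, int(epr_bins) + 1)
    hist, _ = np.histogram(np.clip(x, epr_bins[0], epr_bins[-1]), bins=epr_bins)
    return PopulationFit(condition=condition, n_molecules=len(x), epr_values=x,
                         bin_edges=np.asarray(epr_bins), histogram=hist,
                         k_selected=k_sel, components=comps, bic=bic,
                         peak_epr=peak)


def compare_conditions(replicate_means: Dict[str, Sequence[float]]
                       ) -> ConditionComparison:
    """One-way ANOVA across conditions plus Bonferroni-adjusted pairwise t-tests.

    Input maps a condition label to its replicate mean E_PR values.
    Conditions with fewer than 2 replicates are excluded with a warning.
    """
    import warnings
    groups = {}
    for cond, vals in replicate_means.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            warnings.warn(f"condition {cond!r} has < 2 replicates; excluded")
            continue
        groups[cond] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions with >= 2 replicates")
    names = list(groups)
    F, p = stats.f_oneway(*(groups[c] for c in names))
    pairs = list(combinations(names, 2))
    raw = {}
    for a, b in pairs:
        _, tp = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        raw[(a, b)] = float(tp)
    adj = {k: min(1.0, v * len(pairs)) for k, v in raw.items()}
    return ConditionComparison(
        means={c: float(np.mean(groups[c])) for c in names},
        sds={c: float(np.std(groups[c], ddof=1)) for c in names},
        replicate_means={c: list(map(float, groups[c])) for c in names},
        anova_F=float(F), anova_p=float(p),
        pairwise_p=raw, pairwise_p_adj=adj)


def boltzmann_fraction(delta_G: float, T: float = 298.0) -> float:
    """Equilibrium fraction of the active state from ΔG = G_active − G_inactive.

    f = 1 / (1 + exp(ΔG / (R·T))) with R = 0.0019872 kcal/(mol·K); ΔG in
    kcal/mol, T in kelvin.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (1.0 + math.exp(delta_G / (R_KCAL * T)))
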