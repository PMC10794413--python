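"""Kinetic-network model and steady-state thermodynamics.

A conformational cycle is modelled as a continuous-time Markov chain on a
small state network -- for Hsp90 a four-state ring 0-1-2-3-0 in which the
"diagonal" transitions (0<->2, 1<->3) are structurally absent.  Whether the
chain satisfies detailed balance (equilibrium) or carries a net cyclic flux
(non-equilibrium steady state) is quantified by the cycle free energy

    dG = -sum_edges ln(k_fwd / k_bwd)    [units of k_B*T, k_B*T == 1 here]

together with per-edge net fluxes and the Schnakenberg entropy production
rate.  A |dG| above 1 k_B*T is treated as clearly directional; smaller
magnitudes are within what equilibrium control measurements produce.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RING_STRUCTURAL_ZEROS",
    "RateMatrix",
    "CycleSpec",
    "CiSet",
    "ThermoSummary",
    "stationary_distribution",
    "detailed_balance_residuals",
    "cycle_free_energy",
    "net_flux",
    "entropy_production",
    "build_cycle_rates",
    "rescale_rates",
    "rates_from_probabilities",
    "probabilities_from_rates",
    "average_ci",
    "delta_g_with_errors",
]

#: Transitions absent from the four-state ring (the "diagonal" rates).
RING_STRUCTURAL_ZEROS = frozenset({(0, 2), (2, 0), (1, 3), (3, 1)})

#: Point estimates with |dG| above this many k_B*T count as directional.
DIRECTIONALITY_THRESHOLD = 1.0


@dataclass(frozen=True)
class RateMatrix:
    """Per-second transition rate constants ``k[i, j]`` (from i to j).

    Diagonal entries are zero by convention (exit rates are row sums).
    ``structural_zeros`` are ordered pairs pinned to exactly zero, e.g. the
    ring's forbidden diagonal transitions.
    """

    k: np.ndarray
    structural_zeros: frozenset = frozenset()

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        object.__setattr__(self, "k", k)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("rate matrix must be square")
        if np.any(k < 0):
            raise ValueError("rates must be non-negative")
        if np.any(np.diag(k) != 0):
            raise ValueError("diagonal rate entries must be zero")
        for i, j in self.structural_zeros:
            if k[i, j] != 0:
                raise ValueError(f"structural zero ({i},{j}) has rate {k[i, j]}")

    @property
    def n_states(self) -> int:
        return self.k.shape[0]

    @classmethod
    def ring(cls, rates: dict[tuple[int, int], float], n_states: int = 4,
             structural_zeros: frozenset | None = None) -> "RateMatrix":
        """Build a matrix from an edge->rate mapping (missing edges are 0)."""
        k = np.zeros((n_states, n_states))
        for (i, j), v in rates.items():
            k[i, j] = v
        if structural_zeros is None and n_states == 4:
            structural_zeros = RING_STRUCTURAL_ZEROS
        return cls(k, structural_zeros or frozenset())

    def exit_rates(self) -> np.ndarray:
        return self.k.sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "states": list(range(self.n_states)),
            "units": "1/s",
            "k": self.k.tolist(),
            "structural_zeros": sorted(self.structural_zeros),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "RateMatrix":
        return cls(np.asarray(d["k"], dtype=float),
                   frozenset(tuple(p) for p in d.get("structural_zeros", [])))


@dataclass(frozen=True)
class CycleSpec:
    """Ordered states of a directed cycle (closes back to the first state).

    The default orientation 0->1->2->3->0 matches the conformational
    progression open -> open -> closed -> closed -> open.
    """

    states: tuple = (0, 1, 2, 3)

    def __post_init__(self):
        states = tuple(int(s) for s in self.states)
        object.__setattr__(self, "states", states)
        if len(states) < 3:
            raise ValueError("a cycle needs at least 3 states")
        if len(set(states)) != len(states):
            raise ValueError("cycle states must be distinct")

    def edges(self):
        """Directed edges including the closing edge."""
        s = self.states
        return [(s[i], s[(i + 1) % len(s)]) for i in range(len(s))]

    def reversed(self) -> "CycleSpec":
        return CycleSpec(tuple(reversed(self.states)))

    def validate_against(self, rates: RateMatrix) -> None:
        for i, j in self.edges():
            if (i, j) in rates.structural_zeros or (j, i) in rates.structural_zeros:
                raise ValueError(f"cycle edge ({i},{j}) is a structural zero")


@dataclass(frozen=True)
class CiSet:
    """Per-rate 95% confidence-interval half-widths, units 1/s.

    ``n`` counts the replicate fits that were averaged into these widths
    (1 for a single fit; >=2 after replicate merging).
    """

    half_widths: np.ndarray
    n: int = 1

    def __post_init__(self):
        hw = np.asarray(self.half_widths, dtype=float)
        object.__setattr__(self, "half_widths", hw)
        if np.any(hw < 0):
            raise ValueError("CI half-widths must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @classmethod
    def zeros(cls, n_states: int) -> "CiSet":
        return cls(np.zeros((n_states, n_states)), n=1)


@dataclass(frozen=True)
class ThermoSummary:
    """Cycle free energy with error bounds, fluxes and entropy production."""

    delta_g: float               # k_B*T
    delta_g_lo: float            # k_B*T, lower bound
    delta_g_hi: float            # k_B*T, upper bound
    edge_fluxes: dict            # (i, j) -> net flux pi_i k_ij - pi_j k_ji, 1/s
    entropy_production: float    # k_B/s
    directional: bool
    cycle: CycleSpec = field(default_factory=CycleSpec)

    def __post_init__(self):
        if not (self.delta_g_lo <= self.delta_g <= self.delta_g_hi):
            raise ValueError("delta_g bounds do not bracket the estimate")

    def to_dict(self) -> dict:
        return {
            "delta_g_kBT": self.delta_g,
            "delta_g_lo_kBT": self.delta_g_lo,
            "delta_g_hi_kBT": self.delta_g_hi,
            "edge_fluxes_per_s": {f"{i}->{j}": v for (i, j), v in self.edge_fluxes.items()},
            "entropy_production_kB_per_s": self.entropy_production,
            "directional": bool(self.directional),
            "cycle": list(self.cycle.states),
            "directionality_threshold_kBT": DIRECTIONALITY_THRESHOLD,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _check_irreducible(rates: RateMatrix) -> None:
    n, labels = connected_components(rates.k > 0, directed=True, connection="strong")
    if n > 1:
        comps = [sorted(np.flatnonzero(labels == c).tolist()) for c in range(n)]
        raise ValueError(f"rate matrix is reducible; components: {comps}")


def stationary_distribution(rates: RateMatrix) -> np.ndarray:
    """Unique stationary distribution of the continuous-time chain.

    Solves ``pi @ Q = 0`` with ``sum(pi) = 1`` where Q is the generator.
    Raises for reducible chains, naming the disconnected components.
    """
    _check_irreducible(rates)
    k = rates.k
    q = k - np.diag(k.sum(axis=1))
    a = np.vstack([q.T, np.ones(rates.n_states)])
    b = np.zeros(rates.n_states + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(pi @ q).max()
    if resid > 1e-9:
        raise RuntimeError(f"stationary solve residual {resid:.3g} exceeds 1e-9")
    return pi


def _check_pi(pi: np.ndarray, n: int) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (n,):
        raise ValueError(f"populations have shape {pi.shape}, expected ({n},)")
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("populations must be non-negative and sum to 1")
    return pi


def _undirected_edges(rates: RateMatrix):
    k = rates.k
    n = rates.n_states
    return [(i, j) for i in range(n) for j in range(i + 1, n)
            if k[i, j] > 0 or k[j, i] > 0]


def detailed_balance_residuals(rates: RateMatrix, pi) -> dict:
    """Per unordered edge: ``pi_i k_ij - pi_j k_ji`` (1/s); zero at equilibrium."""
    pi = _check_pi(pi, rates.n_states)
    k = rates.k
    return {(i, j): pi[i] * k[i, j] - pi[j] * k[j, i]
            for i, j in _undirected_edges(rates)}


def cycle_free_energy(rates: RateMatrix, cycle: CycleSpec | None = None,
                      floor: float | None = None) -> float:
    """Cycle free energy ``-sum ln(k_fwd/k_bwd)`` in k_B*T.

    ``floor`` (1/s) replaces rates below it before taking ratios; with
    ``floor=None`` a zero rate on the cycle is an error, mirroring the fact
    that the free energy of a cycle with no backward transitions is
    mathematically undefined.
    """
    if cycle is None:
        cycle = CycleSpec(tuple(range(rates.n_states)))
    cycle.validate_against(rates)
    total = 0.0
    for i, j in cycle.edges():
        kf, kb = rates.k[i, j], rates.k[j, i]
        if floor is not None:
            kf, kb = max(kf, floor), max(kb, floor)
        if kf <= 0 or kb <= 0:
            raise ValueError(
                f"undefined free energy, no backward transitions on edge ({i},{j})")
        total += math.log(kf / kb)
    return -total


def net_flux(rates: RateMatrix, pi, stationarity_tol: float = 1e-6) -> dict:
    """Per-edge net probability flux ``pi_i k_ij - pi_j k_ji`` (1/s).

    At stationarity on a single ring the flux is identical on every edge.
    A non-stationary ``pi`` triggers a warning; the flux is still reported.
    """
    pi = _check_pi(pi, rates.n_states)
    k = rates.k
    q = k - np.diag(k.sum(axis=1))
    if np.abs(pi @ q).max() > stationarity_tol:
        warnings.warn("populations are not stationary for these rates; "
                      "fluxes are reported but not steady-state fluxes",
                      stacklevel=2)
    return {(i, j): pi[i] * k[i, j] - pi[j] * k[j, i]
            for i, j in _undirected_edges(rates)}


def entropy_production(rates: RateMatrix, pi, floor: float | None = None) -> float:
    """Schnakenberg entropy production rate in k_B/s.

    ``(1/2) sum_ij (pi_i k_ij - pi_j k_ji) ln(pi_i k_ij / (pi_j k_ji))``;
    non-negative, zero iff detailed balance holds.  An edge carrying flux
    with a zero reverse rate is infinite unless ``floor`` is given.
    """
    pi = _check_pi(pi, rates.n_states)
    k = rates.k.copy()
    if floor is not None:
        active = (k > 0) | (k.T > 0)
        np.fill_diagonal(active, False)
        k[active] = np.maximum(k[active], floor)
    total = 0.0
    for i, j in _undirected_edges(rates):
        fwd, bwd = pi[i] * k[i, j], pi[j] * k[j, i]
        if fwd == 0 and bwd == 0:
            continue
        if fwd == 0 or bwd == 0:
            raise ValueError(
                f"edge ({i},{j}) carries flux with a zero reverse rate; "
                "entropy production diverges (enable flooring)")
        total += (fwd - bwd) * math.log(fwd / bwd)
    return max(total, 0.0)


def build_cycle_rates(base: RateMatrix, target_delta_g: float,
                      driven_edge: tuple[int, int] = (2, 3),
                      cycle: CycleSpec | None = None) -> RateMatrix:
    """Inject a cycle affinity into a detailed-balance base matrix.

    Multiplies the forward rate on ``driven_edge`` by ``exp(-target_delta_g)``
    so that the resulting cycle free energy equals ``target_delta_g`` exactly.
    """
    if cycle is None:
        cycle = CycleSpec(tuple(range(base.n_states)))
    base_dg = cycle_free_energy(base, cycle)
    if abs(base_dg) > 1e-9:
        raise ValueError(f"base matrix is not in detailed balance (dG={base_dg:.3g})")
    if target_delta_g == 0:
        return base
    if tuple(driven_edge) not in cycle.edges():
        raise ValueError(f"driven edge {driven_edge} is not a forward edge of {cycle.states}")
    k = base.k.copy()
    i, j = driven_edge
    k[i, j] *= math.exp(-target_delta_g)
    return RateMatrix(k, base.structural_zeros)


def rescale_rates(rates: RateMatrix, frame_rate: float,
                  max_exit_prob: float = 0.5) -> RateMatrix:
    """Globally rescale so the largest per-frame exit probability is capped.

    The cycle free energy is invariant under a global scaling of all rates,
    so this changes time units of the kinetics without touching dG.
    Matrices already under the cap are returned unchanged.
    """
    worst = rates.exit_rates().max() / frame_rate
    if worst <= max_exit_prob:
        return rates
    return RateMatrix(rates.k * (max_exit_prob / worst), rates.structural_zeros)


def rates_from_probabilities(p: np.ndarray, frame_rate: float,
                             structural_zeros: frozenset = frozenset()) -> RateMatrix:
    """Convert a per-frame transition-probability matrix to per-second rates.

    Linear conversion ``k_ij = P_ij * frame_rate`` (valid for rates well
    below the frame rate, which holds for all conditions treated here).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("transition probabilities must be non-negative")
    k = p * frame_rate
    np.fill_diagonal(k, 0.0)
    for i, j in structural_zeros:
        k[i, j] = 0.0
    return RateMatrix(k, structural_zeros)


def probabilities_from_rates(rates: RateMatrix, frame_rate: float) -> np.ndarray:
    """Per-frame transition matrix ``P_ij = k_ij/frame_rate`` with diagonal filler."""
    p = rates.k / frame_rate
    stay = 1.0 - p.sum(axis=1)
    if np.any(stay < 0):
        raise ValueError("frame rate too low for rates (off-diagonal row sum > 1)")
    np.fill_diagonal(p, stay)
    return p


def average_ci(ci_lengths, n: int | None = None):
    """Average replicate confidence-interval lengths.

    ``(1/sqrt(n)) * sqrt(sum_i length_i^2 / (n - 1))`` -- the per-replicate
    95% CIs treated as standard errors of the mean and pooled.  Accepts a
    list of scalars or of equal-shaped arrays (one entry per replicate).
    """
    lengths = np.asarray(ci_lengths, dtype=float)
    if n is None:
        n = lengths.shape[0]
    if n < 2:
        raise ValueError("CI averaging is undefined for a single replicate (n=1)")
    if lengths.shape[0] != n:
        raise ValueError("n does not match the number of replicate CI sets")
    if np.any(lengths < 0):
        raise ValueError("CI lengths must be non-negative")
    out = np.sqrt((lengths ** 2).sum(axis=0) / (n - 1)) / math.sqrt(n)
    return float(out) if np.ndim(out) == 0 else out


def delta_g_with_errors(mean_rates: RateMatrix, ci: CiSet,
                        cycle: CycleSpec | None = None,
                        floor: float | None = None,
                        threshold: float = DIRECTIONALITY_THRESHOLD) -> ThermoSummary:
    """Cycle free energy of the mean rates with CI-propagated bounds.

    Bounds evaluate the cycle free energy at the rate combinations
    ``k +/- half_width`` that extremise it.  Each edge term
    ``-ln(k_fwd/k_bwd)`` is monotone in both rates, so the extremes sit at
    the corners: the lower bound takes every forward rate high and backward
    rate low, the upper bound the opposite (equivalent to exhaustive
    enumeration over all sign assignments).
    """
    if cycle is None:
        cycle = CycleSpec(tuple(range(mean_rates.n_states)))
    dg = cycle_free_energy(mean_rates, cycle, floor=floor)

    def _dg_at(sign_fwd: int, sign_bwd: int) -> float:
        total = 0.0
        for i, j in cycle.edges():
            kf = mean_rates.k[i, j] + sign_fwd * ci.half_widths[i, j]
            kb = mean_rates.k[j, i] + sign_bwd * ci.half_widths[j, i]
            if floor is not None:
                kf, kb = max(kf, floor), max(kb, floor)
            if kf <= 0 or kb <= 0:
                raise ValueError(
                    f"CI shift makes rate on edge ({i},{j}) non-positive; "
                    "enable flooring")
            total += math.log(kf / kb)
        return -total

    lo = _dg_at(+1, -1)
    hi = _dg_at(-1, +1)
    pi = stationary_distribution(mean_rates)
    fluxes = net_flux(mean_rates, pi)
    ep = entropy_production(mean_rates, pi, floor=floor)
    return ThermoSummary(delta_g=dg, delta_g_lo=lo, delta_g_hi=hi,
                         edge_fluxes=fluxes, entropy_production=ep,
                         directional=abs(dg) > threshold, cycle=cycle)
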