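"""Synthetic smFRET data with known ground truth.

Two generators:

* :func:`simulate_dataset` -- stochastic four-state ring kinetics observed
  through degenerate FRET emissions (states 0/1 low, 2/3 high;
  E_low = 0.1 +/- 0.05, E_high = 0.8 +/- 0.05), the validation campaign's
  data model: 200 traces of 200 frames at 2 Hz per condition, with a
  configurable cycle free energy.
* :func:`generate_trigger_dataset` -- the deterministic laser-trigger
  pattern used as an experimental control for artificial directionality:
  a repeating loop of long-high / long-low / short-high / short-low FRET
  blocks (10 and 3 frames at 0.5 s per frame, i.e. lifetimes 5 s and
  1.5 s) plus Gaussian noise.

Both return the trace set together with a :class:`GroundTruth` holding the
true state path of every trace, the true rate matrix and the true cycle
free energy, so parameter recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import photometry
from .kinetics import (
    CycleSpec,
    RateMatrix,
    cycle_free_energy,
    probabilities_from_rates,
    rescale_rates,
    stationary_distribution,
)

__all__ = [
    "SimulationConfig",
    "TriggerConfig",
    "GroundTruth",
    "hsp90_like_rates",
    "uniform_ring_rates",
    "condition_presets",
    "simulate_state_sequence",
    "emit_fret_trace",
    "simulate_dataset",
    "generate_trigger_dataset",
    "TRIGGER_STRUCTURAL_ZEROS",
]

#: state -> emission class for the degenerate four-state model
STATE_CLASSES = (0, 0, 1, 1)

#: The triggered loop alternates FRET levels every block, so same-level
#: transitions (within the open pair or within the closed pair) are absent.
TRIGGER_STRUCTURAL_ZEROS = frozenset({(0, 1), (1, 0), (2, 3), (3, 2)})


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the stochastic four-state campaign generator."""

    rates: RateMatrix
    n_traces: int = 200
    n_frames: int = 200
    frame_rate: float = 2.0                 # Hz
    e_means: tuple = (0.1, 0.8)             # per emission class
    e_sds: tuple = (0.05, 0.05)
    clip: tuple = (-0.2, 1.2)               # efficiency clipping bounds
    seed: int = 0
    emit_intensities: bool = False
    stoichiometry: float = 0.5
    total_photons: float = 1000.0
    factors: photometry.CorrectionFactors = field(
        default_factory=photometry.CorrectionFactors)

    def __post_init__(self):
        if self.n_traces < 1 or self.n_frames < 1:
            raise ValueError("n_traces and n_frames must be >= 1")
        if not all(0.0 <= m <= 1.0 for m in self.e_means):
            raise ValueError("efficiency means must lie in [0, 1]")
        if not all(s > 0 for s in self.e_sds):
            raise ValueError("efficiency SDs must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass(frozen=True)
class TriggerConfig:
    """Parameters of the deterministic laser-trigger generator.

    ``pattern_order`` lists (FRET level, block length in frames) phases;
    the default follows the triggered loop long-high -> long-low ->
    short-high -> short-low.  ``random_phase`` starts each trace at a
    random point of the loop, as asynchronously recorded molecules do.
    """

    short_block: int = 3
    long_block: int = 10
    frame_duration: float = 0.5             # s
    n_traces: int = 349
    n_frames: int = 200
    noise_sd: float = 0.05
    e_means: tuple = (0.1, 0.8)
    pattern_order: tuple = (("high", "long"), ("low", "long"),
                            ("high", "short"), ("low", "short"))
    random_phase: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.short_block < 1 or self.long_block < 1:
            raise ValueError("block lengths must be >= 1")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_duration

    def block_frames(self, length: str) -> int:
        return self.long_block if length == "long" else self.short_block

    @property
    def period(self) -> int:
        return sum(self.block_frames(ln) for _, ln in self.pattern_order)


#: canonical 4-state labels of the trigger phases: open (low) pair {0,1}
#: with 0 long-lived, closed (high) pair {2,3} with 3 long-lived
_TRIGGER_LABELS = {("low", "long"): 0, ("low", "short"): 1,
                   ("high", "short"): 2, ("high", "long"): 3}


@dataclass
class GroundTruth:
    """Everything needed to score parameter recovery on synthetic data."""

    state_sequences: np.ndarray          # (n_traces, n_frames) int
    rates: RateMatrix                    # true per-second rates
    delta_g: float | None                # true cycle free energy, k_B*T
    e_means: tuple
    e_sds: tuple
    seed: int
    populations: np.ndarray = None       # true occupancies

    def __post_init__(self):
        if self.populations is None:
            counts = np.bincount(self.state_sequences.ravel(),
                                 minlength=self.rates.n_states)
            self.populations = counts / counts.sum()


def hsp90_like_rates(target_delta_g: float = 0.0, frame_rate: float = 2.0,
                     long_exit: float = 0.1, short_exit: float = 1.0,
                     driven_edge: tuple[int, int] = (2, 3)) -> RateMatrix:
    """Hsp90-like ring preset: long-lived states 0 and 3, short-lived 1 and 2.

    The detailed-balance base splits each state's exit rate evenly over its
    two ring neighbours, giving populations ~(0.45, 0.05, 0.05, 0.45) --
    roughly half the molecules locked in the long-lived states.  A nonzero
    target free energy is injected on the driven edge (2, 3) (the
    transition whose change drives directionality) as a symmetric split,
    forward rate times exp(-dG/2) and backward rate times exp(+dG/2), and
    the whole matrix is then rescaled globally, if needed, to keep
    per-frame exit probabilities at or below 0.5 (a global rescale leaves
    the cycle free energy and the populations untouched).

    For driven targets the base ``long_exit`` should be chosen so that the
    *rescaled* matrix keeps long-lived dwell times near the ~10 s Hsp90
    regime; the campaign preset uses 0.2/s for the -2 k_BT condition.
    """
    lo, hi = long_exit / 2.0, short_exit / 2.0
    base = RateMatrix.ring({(0, 1): lo, (0, 3): lo, (1, 0): hi, (1, 2): hi,
                            (2, 1): hi, (2, 3): hi, (3, 0): lo, (3, 2): lo})
    k = base.k.copy()
    i, j = driven_edge
    k[i, j] *= math.exp(-target_delta_g / 2.0)
    k[j, i] *= math.exp(target_delta_g / 2.0)
    driven = RateMatrix(k, base.structural_zeros)
    return rescale_rates(driven, frame_rate, max_exit_prob=0.5)


def uniform_ring_rates(target_delta_g: float = 0.0, frame_rate: float = 2.0,
                       base_rate: float = 0.5) -> RateMatrix:
    """Uniform ring preset: equal state populations at any drive.

    The cycle affinity is split evenly over the four ring edges with a
    symmetric forward/backward share per edge, keeping the stationary
    distribution exactly uniform; the matrix is rescaled globally to cap
    per-frame exit probabilities at 0.5.
    """
    per_edge = -target_delta_g / 4.0
    fwd = base_rate * math.exp(per_edge / 2.0)
    bwd = base_rate * math.exp(-per_edge / 2.0)
    rates = {}
    for i, j in CycleSpec().edges():
        rates[(i, j)] = fwd
        rates[(j, i)] = bwd
    return rescale_rates(RateMatrix.ring(rates), frame_rate, max_exit_prob=0.5)


def condition_presets(frame_rate: float = 2.0) -> dict[str, tuple[RateMatrix, float]]:
    """The five-condition validation campaign: name -> (rates, true dG)."""
    return {
        "dg0": (hsp90_like_rates(0.0, frame_rate), 0.0),
        # long_exit 0.2/s so the rescaled driven matrix keeps ~10 s dwells
        "dg-2_hsp90": (hsp90_like_rates(-2.0, frame_rate, long_exit=0.2), -2.0),
        "dg-2_uniform": (uniform_ring_rates(-2.0, frame_rate), -2.0),
        "dg-3": (uniform_ring_rates(-3.0, frame_rate), -3.0),
        "dg-10": (uniform_ring_rates(-10.0, frame_rate), -10.0),
    }


def simulate_state_sequence(rates: RateMatrix, n_frames: int, frame_rate: float,
                            rng: np.random.Generator | int | None = None,
                            initial_state: int | None = None) -> np.ndarray:
    """Discrete-time Markov state path at the camera frame rate.

    Per-frame transition probabilities are ``k_ij / frame_rate`` off the
    diagonal; the initial state is drawn from the stationary distribution
    unless given.  Raises if the frame rate is too low for the rates.
    """
    rng = np.random.default_rng(rng)
    p = probabilities_from_rates(rates, frame_rate)  # raises if infeasible
    cum = np.cumsum(p, axis=1)
    if initial_state is None:
        pi = stationary_distribution(rates)
        initial_state = int(rng.choice(rates.n_states, p=pi))
    states = np.empty(n_frames, dtype=np.int64)
    s = initial_state
    u = rng.random(n_frames)
    for t in range(n_frames):
        states[t] = s
        s = int(np.searchsorted(cum[s], u[t], side="right"))
    return states


def emit_fret_trace(states: np.ndarray, config: SimulationConfig,
                    rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Observe a state path through the degenerate Gaussian emission model.

    States 0/1 emit the low-efficiency class, 2/3 the high one; Gaussian
    noise on efficiency, clipped to the configured bounds.  With
    ``emit_intensities`` the three ALEX channels are synthesised by
    inverting the photometric corrections at the configured factors.
    """
    rng = np.random.default_rng(rng)
    states = np.asarray(states)
    if states.min() < 0 or states.max() >= len(STATE_CLASSES):
        raise ValueError(f"unknown state label in sequence: "
                         f"{sorted(set(states) - set(range(len(STATE_CLASSES))))}")
    classes = np.asarray(STATE_CLASSES)[states]
    means = np.asarray(config.e_means)[classes]
    sds = np.asarray(config.e_sds)[classes]
    e = np.clip(means + sds * rng.standard_normal(len(states)), *config.clip)
    frame_duration = 1.0 / config.frame_rate
    out = pd.DataFrame({
        "frame": np.arange(len(states)),
        "time_s": np.arange(len(states)) * frame_duration,
        "E": e,
    })
    if config.emit_intensities:
        # intensity synthesis needs E strictly below 1
        e_syn = np.clip(e, None, 0.999)
        i_dd, i_da, i_aa = photometry.synthesize_intensities(
            e_syn, config.stoichiometry, config.factors, config.total_photons)
        out["I_DD"], out["I_DA"], out["I_AA"] = i_dd, i_da, i_aa
    return out


def simulate_dataset(config: SimulationConfig) -> tuple[list[pd.DataFrame], GroundTruth]:
    """Generate the full trace set of one campaign condition."""
    rng = np.random.default_rng(config.seed)
    seqs = np.empty((config.n_traces, config.n_frames), dtype=np.int64)
    traces = []
    for i in range(config.n_traces):
        seqs[i] = simulate_state_sequence(config.rates, config.n_frames,
                                          config.frame_rate, rng)
        df = emit_fret_trace(seqs[i], config, rng)
        df.attrs["trace_id"] = i
        traces.append(df)
    try:
        dg = cycle_free_energy(config.rates)
    except ValueError:
        dg = None
    gt = GroundTruth(state_sequences=seqs, rates=config.rates, delta_g=dg,
                     e_means=config.e_means, e_sds=config.e_sds,
                     seed=config.seed)
    return traces, gt


def trigger_pattern(config: TriggerConfig) -> tuple[np.ndarray, np.ndarray]:
    """One period of the trigger loop: (state labels, FRET levels) per frame."""
    labels, levels = [], []
    level_mean = {"low": config.e_means[0], "high": config.e_means[1]}
    for level, length in config.pattern_order:
        lab = _TRIGGER_LABELS.get((level, length))
        if lab is None:
            raise ValueError(f"unrecognised trigger phase {(level, length)}")
        n = config.block_frames(length)
        labels.extend([lab] * n)
        levels.extend([level_mean[level]] * n)
    return np.asarray(labels, dtype=np.int64), np.asarray(levels)


def _trigger_true_rates(config: TriggerConfig) -> RateMatrix:
    """Loop rates = inverse programmed block durations on the loop edges."""
    k = np.zeros((4, 4))
    order = [_TRIGGER_LABELS[p] for p in config.pattern_order]
    for idx, (level, length) in enumerate(config.pattern_order):
        i = order[idx]
        j = order[(idx + 1) % len(order)]
        k[i, j] = 1.0 / (config.block_frames(length) * config.frame_duration)
    return RateMatrix(k, TRIGGER_STRUCTURAL_ZEROS)


def generate_trigger_dataset(config: TriggerConfig) -> tuple[list[pd.DataFrame], GroundTruth]:
    """Deterministic trigger-loop traces plus Gaussian efficiency noise.

    The period is ``2*(short_block + long_block)`` frames (13 s at the
    defaults).  The cycle free energy of the programmed loop is undefined
    (there are no backward transitions), recorded as None.
    """
    rng = np.random.default_rng(config.seed)
    labels, levels = trigger_pattern(config)
    period = config.period
    reps = -(-config.n_frames // period) + 1
    seqs = np.empty((config.n_traces, config.n_frames), dtype=np.int64)
    traces = []
    tiled_lab = np.tile(labels, reps)
    tiled_lev = np.tile(levels, reps)
    t = np.arange(config.n_frames) * config.frame_duration
    for i in range(config.n_traces):
        off = int(rng.integers(period)) if config.random_phase else 0
        seqs[i] = tiled_lab[off:off + config.n_frames]
        e = tiled_lev[off:off + config.n_frames]
        if config.noise_sd > 0:
            e = e + config.noise_sd * rng.standard_normal(config.n_frames)
        df = pd.DataFrame({"frame": np.arange(config.n_frames), "time_s": t, "E": e})
        df.attrs["trace_id"] = i
        traces.append(df)
    gt = GroundTruth(state_sequences=seqs, rates=_trigger_true_rates(config),
                     delta_g=None, e_means=config.e_means,
                     e_sds=(config.noise_sd, config.noise_sd), seed=config.seed)
    return traces, gt
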