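"""Model-free state allocation and dwell-time statistics.

The control analysis for the laser-triggered data: smooth the single
intensity (or efficiency) signal with a Savitzky-Golay filter, allocate
each frame to the high or low apparent state relative to the per-trace
mean of the smoothed signal, run-length encode into dwells, and split each
level's dwells into short- and long-lived sub-states -- turning a two-level
signal into the four-state sequence without any Markov model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "DwellSet",
    "run_lengths",
    "savgol_smooth",
    "split_durations",
    "allocate_states",
    "dwell_histogram",
    "classify_dwells_by_lifetime",
]


@dataclass
class DwellSet:
    """Dwell durations (s) per apparent state, plus a binned histogram.

    Durations are positive integer multiples of ``frame_duration``; the
    default histogram bin width is one frame (0.5 s).
    """

    dwells: dict                      # state label -> list of durations (s)
    frame_duration: float = 0.5
    bin_width: float | None = None    # defaults to one frame

    def __post_init__(self):
        if self.bin_width is None:
            self.bin_width = self.frame_duration
        if self.bin_width <= 0 or self.frame_duration <= 0:
            raise ValueError("bin width and frame duration must be positive")
        for state, ds in self.dwells.items():
            ds = np.asarray(ds, dtype=float)
            mult = ds / self.frame_duration
            if np.any(ds <= 0) or not np.allclose(mult, np.round(mult)):
                raise ValueError(
                    f"dwells of state {state} are not positive multiples of "
                    "the frame duration")
            self.dwells[state] = ds

    def histogram(self, state) -> tuple[np.ndarray, np.ndarray]:
        """(counts, bin_edges) at the configured bin width.

        Bins are centred on integer multiples of the bin width, so a dwell
        of exactly k frames falls in the bin whose centre is k frames.
        """
        d = self.dwells[state]
        top = int(np.ceil(d.max() / self.bin_width)) + 1 if len(d) else 1
        edges = (np.arange(0, top + 1) + 0.5) * self.bin_width
        counts, edges = np.histogram(d, bins=edges)
        return counts, edges

    def modal_dwell(self, state) -> float:
        """Centre of the most populated histogram bin, in seconds."""
        counts, edges = self.histogram(state)
        i = int(np.argmax(counts))
        return float(0.5 * (edges[i] + edges[i + 1]))


def run_lengths(seq) -> list[tuple[int, int]]:
    """Run-length encode a label sequence into (label, length) pairs."""
    seq = np.asarray(seq)
    if len(seq) == 0:
        raise ValueError("empty sequence")
    change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(seq)]])
    return [(int(seq[s]), int(e - s)) for s, e in zip(starts, ends)]


def savgol_smooth(signal, window: int = 5, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares smoothing (default 5-frame window).

    Edges use a polynomial fit over the first/last window (so a signal that
    is itself a polynomial of degree <= ``polyorder`` passes through
    unchanged); output length equals input length.
    """
    signal = np.asarray(signal, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(signal):
        raise ValueError("window longer than signal")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    return savgol_filter(signal, window_length=window, polyorder=polyorder,
                         mode="interp")


def allocate_states(smoothed) -> np.ndarray:
    """Binary state per frame: 1 where above the trace mean, else 0.

    The midline is the mean of the smoothed signal of this trace; frames
    exactly on the midline go to the low state (deterministic tie-break).
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if len(smoothed) == 0:
        raise ValueError("empty sequence")
    if smoothed.max() == smoothed.min():
        raise ValueError("no midline separation: signal is constant")
    return (smoothed > smoothed.mean()).astype(np.int64)


def dwell_histogram(states, frame_duration: float = 0.5,
                    bin_width: float | None = None,
                    drop_truncated: bool = True) -> DwellSet:
    """Run-length dwell durations per state.

    The first and last dwell of a trace are truncated by the observation
    window (their true length is unobserved) and are excluded by default.
    """
    runs = run_lengths(states)
    if drop_truncated:
        runs = runs[1:-1]
    dwells: dict = {}
    for label, length in runs:
        dwells.setdefault(label, []).append(length * frame_duration)
    return DwellSet(dwells={k: v for k, v in sorted(dwells.items())},
                    frame_duration=frame_duration, bin_width=bin_width)


def split_durations(durations, min_separation: float = 1.5) -> float:
    """Deterministic short/long boundary for a pooled dwell sample.

    Chooses the cut of the log-duration axis that maximises the
    between-class variance (Otsu's criterion on the sorted sample) and
    returns the geometric mean of the two class centres.  Raises when the
    classes differ by less than ``min_separation``-fold -- an effectively
    unimodal distribution in which degenerate states cannot be resolved.
    """
    d = np.sort(np.asarray(durations, dtype=float))
    if len(d) < 2 or d[0] == d[-1]:
        raise ValueError("cannot split degenerate states: "
                         "dwell distribution is unimodal")
    x = np.log(d)
    total_mean = x.mean()
    csum = np.cumsum(x)
    n = len(x)
    idx = np.arange(1, n)
    valid = d[1:] > d[:-1]          # cut only between distinct values
    m_lo = csum[:-1] / idx
    m_hi = (csum[-1] - csum[:-1]) / (n - idx)
    between = idx * (m_lo - total_mean) ** 2 + (n - idx) * (m_hi - total_mean) ** 2
    between[~valid] = -np.inf
    best = int(np.argmax(between))
    lo, hi = math.exp(m_lo[best]), math.exp(m_hi[best])
    if hi / lo < min_separation:
        raise ValueError("cannot split degenerate states: "
                         "dwell distribution is unimodal")
    return float(math.sqrt(lo * hi))


def estimate_lifetime_boundary(dwells: DwellSet,
                               min_separation: float = 1.5) -> float:
    """Short/long boundary estimated from a DwellSet's pooled durations."""
    pooled = np.concatenate([d for d in dwells.dwells.values()])
    if len(pooled) == 0:
        raise ValueError("cannot split degenerate states: no dwells")
    return split_durations(pooled, min_separation)


def classify_dwells_by_lifetime(states, frame_duration: float = 0.5,
                                boundary: float | None = None,
                                lifetimes: tuple | None = None) -> np.ndarray:
    """Label a two-level sequence with four states via dwell lifetimes.

    Each dwell is short or long relative to ``boundary`` (seconds); if
    ``lifetimes=(short, long)`` is given instead, the boundary is their
    geometric mean (sqrt(1.5*5) ~ 2.74 s for the triggered pattern); if
    neither is given the boundary is estimated from the dwell histogram.
    Labels: (low, long)=0, (low, short)=1, (high, short)=2, (high, long)=3,
    so the long-lived members of each level are states 0 and 3.  Truncated
    first/last dwells are labelled by their observed length.
    """
    states = np.asarray(states)
    if boundary is None and lifetimes is not None:
        boundary = float(np.sqrt(lifetimes[0] * lifetimes[1]))
    if boundary is None:
        # truncated boundary dwells would contaminate the short mode
        boundary = estimate_lifetime_boundary(
            dwell_histogram(states, frame_duration, drop_truncated=True))
    runs = run_lengths(states)
    durations = np.array([ln * frame_duration for _, ln in runs])
    if np.all(durations > boundary):
        warnings.warn("boundary below every dwell: all dwells labelled long",
                      stacklevel=2)
    elif np.all(durations <= boundary):
        warnings.warn("boundary above every dwell: all dwells labelled short",
                      stacklevel=2)
    label_of = {(0, 1): 0, (0, 0): 1, (1, 0): 2, (1, 1): 3}
    out = np.empty(len(states), dtype=np.int64)
    pos = 0
    for (level, length), dur in zip(runs, durations):
        out[pos:pos + length] = label_of[(level, int(dur > boundary))]
        pos += length
    return out
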