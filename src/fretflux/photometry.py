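"""ALEX photometry: corrected FRET efficiency and stoichiometry.

Alternating laser excitation yields three intensity channels per frame:
I_DD (donor excitation, donor emission), I_DA (donor excitation, acceptor
emission) and I_AA (acceptor excitation, acceptor emission).  The acceptor
signal is corrected for donor leakage (alpha), acceptor direct excitation
(delta) and detection/excitation imbalances (gamma, beta) following the
multi-lab standard convention:

    F_corr = I_DA - alpha * I_DD - delta * I_AA
    E      = F_corr / (gamma * I_DD + F_corr)
    S      = (gamma * I_DD + F_corr) / (gamma * I_DD + F_corr + I_AA / beta)

The defaults are the factors used for the Hsp90 data set
(alpha=0.16, delta=0.12, gamma=1.09, beta=0.86).  ``synthesize_intensities``
is the exact algebraic inverse, used by the trace simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrectionFactors",
    "FretTrace",
    "EfficiencyTrace",
    "correct_alex",
    "synthesize_intensities",
    "apparent_efficiency",
]


@dataclass(frozen=True)
class CorrectionFactors:
    """Dimensionless ALEX correction factors (defaults: the Hsp90 values)."""

    alpha: float = 0.16   # donor leakage into the acceptor channel
    delta: float = 0.12   # direct excitation of the acceptor
    gamma: float = 1.09   # detection/quantum-yield imbalance
    beta: float = 0.86    # excitation imbalance

    def __post_init__(self):
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be non-negative")

    @classmethod
    def unit(cls) -> "CorrectionFactors":
        """No corrections (alpha=delta=0, gamma=beta=1)."""
        return cls(alpha=0.0, delta=0.0, gamma=1.0, beta=1.0)


@dataclass
class FretTrace:
    """Three-channel intensity time series of one molecule."""

    i_dd: np.ndarray
    i_da: np.ndarray
    i_aa: np.ndarray
    frame_duration: float = 0.5   # s
    trace_id: str | int = 0

    def __post_init__(self):
        self.i_dd = np.asarray(self.i_dd, dtype=float)
        self.i_da = np.asarray(self.i_da, dtype=float)
        self.i_aa = np.asarray(self.i_aa, dtype=float)
        if not (len(self.i_dd) == len(self.i_da) == len(self.i_aa)):
            raise ValueError("intensity channels must have equal length")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")

    def __len__(self) -> int:
        return len(self.i_dd)


@dataclass
class EfficiencyTrace:
    """Corrected per-frame FRET efficiency E and stoichiometry S.

    ``valid`` flags frames with well-defined corrections; invalid frames
    (zero denominators) hold NaN and are excluded downstream, their count
    is ``n_invalid``.
    """

    e: np.ndarray
    s: np.ndarray
    valid: np.ndarray = field(default=None)
    frame_duration: float = 0.5
    trace_id: str | int = 0

    def __post_init__(self):
        self.e = np.asarray(self.e, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.e)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())

    def __len__(self) -> int:
        return len(self.e)


def correct_alex(trace: FretTrace,
                 factors: CorrectionFactors = CorrectionFactors()) -> EfficiencyTrace:
    """Corrected FRET efficiency and stoichiometry from a 3-channel trace.

    Frames with vanishing denominators are flagged invalid (NaN), not
    imputed; the count is available as ``EfficiencyTrace.n_invalid``.
    """
    f = factors
    f_corr = trace.i_da - f.alpha * trace.i_dd - f.delta * trace.i_aa
    den_e = f.gamma * trace.i_dd + f_corr
    den_s = den_e + trace.i_aa / f.beta
    valid = (den_e != 0) & (den_s != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(valid, f_corr / den_e, np.nan)
        s = np.where(valid, den_e / den_s, np.nan)
    return EfficiencyTrace(e=e, s=s, valid=valid,
                           frame_duration=trace.frame_duration,
                           trace_id=trace.trace_id)


def synthesize_intensities(e, s, factors: CorrectionFactors = CorrectionFactors(),
                           total_photons: float = 1000.0):
    """Invert the ALEX corrections: intensities that map back to (E, S).

    Exact algebraic inverse of :func:`correct_alex` at the same factors,
    scaled so the three channels sum to ``total_photons`` per frame.
    Requires E < 1 and 0 < S < 1.
    """
    e = np.asarray(e, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(total_photons <= 0):
        raise ValueError("total_photons must be positive")
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("stoichiometry must lie strictly between 0 and 1")
    if np.any(e >= 1):
        raise ValueError("efficiency must be below 1 for intensity synthesis")
    f = factors
    # Work at I_DD = 1, then rescale. F = gamma*E/(1-E); I_AA from S.
    f_corr = f.gamma * e / (1.0 - e)
    den_e = f.gamma + f_corr
    i_aa = f.beta * den_e * (1.0 - s) / s
    i_da = f_corr + f.alpha + f.delta * i_aa
    i_dd = np.ones_like(i_da)
    scale = total_photons / (i_dd + i_da + i_aa)
    return i_dd * scale, i_da * scale, i_aa * scale


def apparent_efficiency(trace: FretTrace) -> EfficiencyTrace:
    """Uncorrected proximity ratio ``I_DA / (I_DD + I_DA)`` (QC diagnostic)."""
    den = trace.i_dd + trace.i_da
    valid = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(valid, trace.i_da / den, np.nan)
    s = np.full_like(e, np.nan)
    return EfficiencyTrace(e=e, s=s, valid=valid,
                           frame_duration=trace.frame_duration,
                           trace_id=trace.trace_id)
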