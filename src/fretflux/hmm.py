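"""Ensemble hidden Markov modelling with degenerate (tied) emissions.

The four conformational states of the ring are only pairwise
distinguishable by FRET efficiency: states 0/1 share the low-efficiency
emission, states 2/3 the high one.  The HMM therefore ties emission
parameters across states within an emission class, while every state keeps
its own row of the transition matrix -- the kinetics are what separates
degenerate states.  One shared transition matrix, one shared set of tied
Gaussian emissions and one shared initial distribution are trained on the
whole trace ensemble by Baum-Welch (likelihood summed over traces), with
structurally forbidden transitions pinned to exactly zero throughout.

Emissions may be one-dimensional (corrected FRET efficiency) or
two-dimensional (donor and acceptor channels) -- both are diagonal
Gaussians per class, selected by the observation columns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from .dwell import run_lengths as _run_lengths
from .dwell import split_durations as _split_durations
from .kinetics import (
    RING_STRUCTURAL_ZEROS,
    CiSet,
    CycleSpec,
    RateMatrix,
    ThermoSummary,
    delta_g_with_errors,
    rates_from_probabilities,
)

__all__ = [
    "HmmModel",
    "HmmFitResult",
    "fit_ensemble_hmm",
    "viterbi_paths",
    "forward_loglik",
    "select_model_bic",
    "bootstrap_rate_cis",
    "recovered_delta_g",
    "align_states",
    "permute_states",
]

_SD_FLOOR = 1e-4


@dataclass
class HmmModel:
    """A tied-emission Gaussian HMM shared by an ensemble of traces."""

    transmat: np.ndarray                 # (n, n), rows sum to 1
    startprob: np.ndarray                # (n,)
    means: np.ndarray                    # (n_classes, d)
    sds: np.ndarray                      # (n_classes, d)
    tying: tuple = (0, 0, 1, 1)          # state -> emission class
    structural_zeros: frozenset = RING_STRUCTURAL_ZEROS

    def __post_init__(self):
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        n = self.n_states
        if self.transmat.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition-matrix rows must sum to 1")
        for i, j in self.structural_zeros:
            if self.transmat[i, j] != 0:
                raise ValueError(f"structural zero ({i},{j}) violated")

    @property
    def n_states(self) -> int:
        return len(self.tying)

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]

    @property
    def ndim(self) -> int:
        return self.means.shape[1]

    def emission_logprob(self, obs: np.ndarray) -> np.ndarray:
        """Log emission density per frame and hidden state, shape (..., n)."""
        obs = np.atleast_2d(np.asarray(obs, dtype=float))
        z = (obs[..., None, :] - self.means) / self.sds      # (..., C, d)
        logp = -0.5 * (z ** 2) - np.log(self.sds) - 0.5 * math.log(2 * math.pi)
        per_class = logp.sum(axis=-1)                        # (..., C)
        return per_class[..., list(self.tying)]

    def n_free_parameters(self) -> int:
        """Free parameters for BIC: transitions + tied emissions + start."""
        allowed = np.ones_like(self.transmat, dtype=bool)
        for i, j in self.structural_zeros:
            allowed[i, j] = False
        n_trans = int((allowed.sum(axis=1) - 1).sum())       # row-sum constraint
        n_emis = self.n_classes * 2 * self.ndim              # mean + sd per class
        return n_trans + n_emis + (self.n_states - 1)

    def to_dict(self) -> dict:
        return {
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "emission_means": self.means.tolist(),
            "emission_sds": self.sds.tolist(),
            "tying": list(self.tying),
            "structural_zeros": sorted(self.structural_zeros),
        }


@dataclass
class HmmFitResult:
    """Trained ensemble model plus everything derived from it."""

    model: HmmModel
    log_likelihood: float
    bic: float
    n_free_parameters: int
    viterbi: list                          # per-trace state arrays
    populations_viterbi: np.ndarray
    populations_stationary: np.ndarray
    frame_rate: float | None = None
    rate_matrix: RateMatrix | None = None
    ci: CiSet | None = None
    n_restarts: int = 1
    n_iter: int = 0
    converged: bool = True
    seed: int | None = None
    n_frames_total: int = 0

    @property
    def total_observation_time(self) -> float | None:
        if self.frame_rate is None:
            return None
        return self.n_frames_total / self.frame_rate

    def to_dict(self) -> dict:
        d = {
            "model": self.model.to_dict(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_free_parameters": self.n_free_parameters,
            "populations_viterbi": self.populations_viterbi.tolist(),
            "populations_stationary": self.populations_stationary.tolist(),
            "n_restarts": self.n_restarts,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
            "n_frames_total": self.n_frames_total,
            "frame_rate": self.frame_rate,
        }
        if self.rate_matrix is not None:
            d["rate_matrix"] = self.rate_matrix.to_dict()
        return d


# ---------------------------------------------------------------------------
# observation handling

def as_observations(traces, columns=("E",)) -> list[np.ndarray]:
    """Extract (T, d) observation arrays from DataFrames or raw arrays."""
    out = []
    for tr in traces:
        if isinstance(tr, pd.DataFrame):
            arr = tr.loc[:, list(columns)].to_numpy(dtype=float)
        else:
            arr = np.asarray(tr, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
        out.append(arr)
    return out


def _batch_by_length(obs_list):
    groups = {}
    for idx, o in enumerate(obs_list):
        groups.setdefault(len(o), []).append(idx)
    for length, idxs in groups.items():
        yield idxs, np.stack([obs_list[i] for i in idxs])


# ---------------------------------------------------------------------------
# forward/backward (scaled), E-step

def _scaled_emissions(model, x):
    logb = model.emission_logprob(x)                  # (N, T, n)
    m = logb.max(axis=2)
    b = np.exp(logb - m[:, :, None])
    return b, m


def _forward_batch(model, b):
    n_tr, n_t, n = b.shape
    alpha = np.empty_like(b)
    c = np.empty((n_tr, n_t))
    a = model.startprob * b[:, 0]
    c[:, 0] = a.sum(axis=1)
    if np.any(c[:, 0] <= 0):
        bad = int(np.argmax(c[:, 0] <= 0))
        raise FloatingPointError(f"zero likelihood at frame 0 of trace {bad}")
    alpha[:, 0] = a / c[:, 0, None]
    tm = model.transmat
    for t in range(1, n_t):
        a = (alpha[:, t - 1] @ tm) * b[:, t]
        c[:, t] = a.sum(axis=1)
        if np.any(c[:, t] <= 0):
            bad = int(np.argmax(c[:, t] <= 0))
            raise FloatingPointError(f"zero likelihood at frame {t} of trace {bad}")
        alpha[:, t] = a / c[:, t, None]
    return alpha, c


def _backward_batch(model, b, c):
    n_tr, n_t, n = b.shape
    beta = np.empty_like(b)
    beta[:, -1] = 1.0
    tm_t = model.transmat.T
    for t in range(n_t - 2, -1, -1):
        beta[:, t] = ((beta[:, t + 1] * b[:, t + 1]) @ tm_t) / c[:, t + 1, None]
    return beta


def forward_loglik(model: HmmModel, traces, columns=("E",)) -> float:
    """Total scaled-forward log-likelihood of the ensemble under the model."""
    total = 0.0
    obs = as_observations(traces, columns)
    for _, x in _batch_by_length(obs):
        b, m = _scaled_emissions(model, x)
        _, c = _forward_batch(model, b)
        total += float(np.log(c).sum() + m.sum())
    return total


def _e_step(model, obs_list):
    n = model.n_states
    d = model.ndim
    loglik = 0.0
    xi_sum = np.zeros((n, n))
    start_acc = np.zeros(n)
    w = np.zeros(n)
    wx = np.zeros((n, d))
    wx2 = np.zeros((n, d))
    n_traces = 0
    for _, x in _batch_by_length(obs_list):
        b, m = _scaled_emissions(model, x)
        alpha, c = _forward_batch(model, b)
        beta = _backward_batch(model, b, c)
        loglik += float(np.log(c).sum() + m.sum())
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        start_acc += gamma[:, 0].sum(axis=0)
        n_traces += x.shape[0]
        w += gamma.sum(axis=(0, 1))
        wx += np.einsum("ntk,ntd->kd", gamma, x)
        wx2 += np.einsum("ntk,ntd->kd", gamma, x ** 2)
        # xi_t = alpha_t (x) A (x) b_{t+1} beta_{t+1} / c_{t+1}; the constant
        # A factor is folded in once, after the sums over t and traces
        bb = b * beta                                    # (N, T, n)
        for t in range(x.shape[1] - 1):
            xi_sum += np.einsum("ni,nj->ij", alpha[:, t],
                                bb[:, t + 1] / c[:, t + 1, None])
    xi_sum *= model.transmat
    return loglik, xi_sum, start_acc / n_traces, w, wx, wx2


def _m_step(model, xi_sum, start, w, wx, wx2, pseudocount=0.0):
    n = model.n_states
    tm = xi_sum.copy()
    if pseudocount:
        # symmetric Dirichlet prior over each row's allowed transitions:
        # with tied emissions the likelihood is nearly flat along the
        # attribution of within-class transitions, and the prior selects
        # the least extreme point of that ridge; entries backed by real
        # transition counts are unaffected at this magnitude
        tm += pseudocount
    for i, j in model.structural_zeros:
        tm[i, j] = 0.0
    rows = tm.sum(axis=1)
    for i in range(n):
        if rows[i] > 0:
            tm[i] = tm[i] / rows[i]
        else:
            tm[i] = model.transmat[i]
    # tied emission update: pool responsibilities over each class
    tying = np.asarray(model.tying)
    means = np.empty_like(model.means)
    sds = np.empty_like(model.sds)
    for c in range(model.n_classes):
        sel = tying == c
        wc = w[sel].sum()
        if wc <= 0:
            means[c], sds[c] = model.means[c], model.sds[c]
            continue
        mu = wx[sel].sum(axis=0) / wc
        var = wx2[sel].sum(axis=0) / wc - mu ** 2
        means[c] = mu
        sds[c] = np.sqrt(np.maximum(var, _SD_FLOOR ** 2))
    start = np.clip(start, 0, None)
    start /= start.sum()
    return replace(model, transmat=tm, startprob=start, means=means, sds=sds)


def _run_em(model, obs_list, tol, max_iter, pseudocount=0.0):
    prev = -np.inf
    history = []
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        loglik, xi_sum, start, w, wx, wx2 = _e_step(model, obs_list)
        history.append(loglik)
        if loglik - prev < tol and n_iter > 1:
            converged = True
            break
        prev = loglik
        model = _m_step(model, xi_sum, start, w, wx, wx2, pseudocount)
    return model, history, n_iter, converged


# ---------------------------------------------------------------------------
# initialization

def _pooled(obs_list):
    return np.concatenate([o for o in obs_list], axis=0)


def _level_split(pooled):
    """Two-level split of the pooled signal; returns (lo_mean, hi_mean, thresh).

    Deterministic Otsu threshold (maximum between-class variance) on the
    sorted sample.
    """
    x = np.sort(pooled[:, 0])
    n = len(x)
    if x[0] == x[-1]:
        raise ValueError("degenerate emissions: signal has no variance to split")
    csum = np.cumsum(x)
    idx = np.arange(1, n)
    m_lo = csum[:-1] / idx
    m_hi = (csum[-1] - csum[:-1]) / (n - idx)
    between = idx * (m_lo - x.mean()) ** 2 + (n - idx) * (m_hi - x.mean()) ** 2
    between[x[1:] <= x[:-1]] = -np.inf
    best = int(np.argmax(between))    # low class = x[:best+1]
    lo, hi = m_lo[best], m_hi[best]
    if hi - lo < 1e-12:
        raise ValueError("degenerate emissions: signal has no variance to split")
    return lo, hi, 0.5 * (x[best] + x[best + 1])


def _segmentation_init(obs_list, tying, structural_zeros):
    """Kinetics-aware starting point: threshold the signal into two levels,
    split each level's dwells into short and long, and count transitions.

    State convention of the initial labels: (low, long)=0, (low, short)=1,
    (high, short)=2, (high, long)=3 -- consistent with the ring layout in
    which states 0 and 3 are the long-lived members of their classes.
    """
    n = len(tying)
    tying_arr = np.asarray(tying)
    pooled = _pooled(obs_list)
    lo, hi, thr = _level_split(pooled)

    # per-level short/long dwell boundary; truncated first/last runs carry
    # no length information and would contaminate the short mode
    durations = {0: [], 1: []}
    runs_per_trace = []
    for o in obs_list:
        level = (o[:, 0] > thr).astype(int)
        runs = _run_lengths(level)
        runs_per_trace.append((level, runs))
        for lv, ln in runs[1:-1]:
            durations[lv].append(ln)
    bounds = {}
    for lv in (0, 1):
        d = np.asarray(durations[lv], dtype=float)
        try:
            bounds[lv] = _split_durations(d)
        except ValueError:
            bounds[lv] = float(np.median(d)) if len(d) else 1.0

    label_of = {(0, 1): 0, (0, 0): 1, (1, 0): 2, (1, 1): 3}  # (level, is_long)
    counts = np.full((n, n), 0.05)
    start = np.full(n, 1.0)
    for o, (level, runs) in zip(obs_list, runs_per_trace):
        labels = np.empty(len(level), dtype=int)
        pos = 0
        for lv, ln in runs:
            labels[pos:pos + ln] = label_of[(lv, int(ln > bounds[lv]))]
            pos += ln
        start[labels[0]] += 1
        for a, bb in zip(labels[:-1], labels[1:]):
            if a != bb and (a, bb) in structural_zeros:
                continue
            counts[a, bb] += 1
    for i, j in structural_zeros:
        counts[i, j] = 0.0
    tm = counts / counts.sum(axis=1, keepdims=True)
    # run-length labels cannot observe within-class transitions, which
    # leaves those entries at the pseudocount; spread a little probability
    # over every allowed off-diagonal so EM starts inside the simplex
    # rather than creeping in from its boundary
    allowed_off = np.ones((n, n), dtype=bool)
    np.fill_diagonal(allowed_off, False)
    for i, j in structural_zeros:
        allowed_off[i, j] = False
    for i in range(n):
        off = np.flatnonzero(allowed_off[i])
        tm[i, off] += 0.05 / len(off)
        tm[i] /= tm[i].sum()
    start /= start.sum()

    n_classes = int(tying_arr.max()) + 1
    d = pooled.shape[1]
    means = np.empty((n_classes, d))
    sds = np.empty((n_classes, d))
    level_class = (pooled[:, 0] > thr).astype(int)
    for c in range(n_classes):
        sel = level_class == c if n_classes == 2 else slice(None)
        block = pooled[sel]
        means[c] = block.mean(axis=0)
        sds[c] = np.maximum(block.std(axis=0), _SD_FLOOR)
    return HmmModel(transmat=tm, startprob=start, means=means, sds=sds,
                    tying=tuple(tying), structural_zeros=structural_zeros)


def _random_init(obs_list, tying, structural_zeros, rng):
    n = len(tying)
    tying_arr = np.asarray(tying)
    pooled = _pooled(obs_list)
    lo, hi, thr = _level_split(pooled)
    n_classes = int(tying_arr.max()) + 1
    d = pooled.shape[1]
    base = np.linspace(lo, hi, n_classes)
    means = np.empty((n_classes, d))
    sds = np.empty((n_classes, d))
    spread = max((hi - lo) / 4.0, 10 * _SD_FLOOR)
    for c in range(n_classes):
        means[c] = base[c] + 0.1 * spread * rng.standard_normal(d)
        sds[c] = spread
    # uniform small off-diagonal probabilities, mildly perturbed per
    # restart: with tied emissions the likelihood ridge along within-class
    # attribution is nearly flat, and a strongly asymmetric start would
    # simply be frozen in by EM
    allowed = np.ones((n, n), dtype=bool)
    for i, j in structural_zeros:
        allowed[i, j] = False
    tm = np.zeros((n, n))
    for i in range(n):
        off = [j for j in range(n) if j != i and allowed[i, j]]
        stay = rng.uniform(0.75, 0.9)
        tm[i, i] = stay
        jitter = rng.uniform(0.8, 1.2, size=len(off))
        probs = jitter / jitter.sum()
        for j, p in zip(off, probs):
            tm[i, j] = (1 - stay) * p
    start = rng.dirichlet(np.full(n, 5.0))
    return HmmModel(transmat=tm, startprob=start, means=means, sds=sds,
                    tying=tuple(tying), structural_zeros=structural_zeros)


# ---------------------------------------------------------------------------
# public fitting API

def fit_ensemble_hmm(traces, n_states: int = 4, tying=(0, 0, 1, 1),
                     structural_zeros: frozenset = RING_STRUCTURAL_ZEROS,
                     columns=("E",), frame_rate: float | None = None,
                     n_restarts: int = 10, seed: int | None = None,
                     tol: float = 1e-6, max_iter: int = 500,
                     burn_iters: int = 40,
                     transition_pseudocount: float = 1.0,
                     init_model: HmmModel | None = None) -> HmmFitResult:
    """Train the tied-emission ensemble HMM by Baum-Welch.

    One shared transition matrix, tied emissions and initial distribution
    across all traces.  Restart 0 starts from a segmentation-based guess
    (two-level thresholding plus a short/long dwell split); further
    restarts are random.  Each restart runs ``burn_iters`` iterations; the
    best by likelihood is then run to convergence (``tol`` on the
    log-likelihood increment, at most ``max_iter`` iterations).
    """
    if len(traces) < 1:
        raise ValueError("need at least one trace")
    if len(tying) != n_states:
        raise ValueError("tying must assign every state to an emission class")
    obs_list = as_observations(traces, columns)
    pooled = _pooled(obs_list)
    if float(pooled.std()) < 1e-12:
        raise ValueError("degenerate emissions: no variance in signal")
    rng = np.random.default_rng(seed)

    has_seg = False
    if init_model is not None:
        candidates = [init_model]
    else:
        candidates = []
        # the dwell-segmentation start is specific to the 4-state layout
        # with two emission classes (low pair / high pair)
        if tuple(tying) == (0, 0, 1, 1):
            try:
                candidates.append(_segmentation_init(obs_list, tying,
                                                     structural_zeros))
                has_seg = True
            except ValueError:
                pass
        while len(candidates) < n_restarts:
            candidates.append(_random_init(obs_list, tying,
                                           structural_zeros, rng))

    # short-run all restarts, then polish the leaders to convergence: optima
    # with nearly equal likelihood can imply very different kinetics, so the
    # ranking after the burn-in alone is not trusted
    burned = []
    for idx, cand in enumerate(candidates):
        m, history, _, _ = _run_em(cand, obs_list, tol,
                                   min(burn_iters, max_iter),
                                   transition_pseudocount)
        burned.append((history[-1], idx, m))
    burned.sort(key=lambda t: t[0], reverse=True)
    # polish the likelihood leaders plus the segmentation-informed start
    # (index 0), whose head start on the kinetics is worth keeping even
    # when its burn-in likelihood trails the random restarts
    polish = burned[:min(3, len(burned))]
    if has_seg and all(idx != 0 for _, idx, _ in polish):
        polish.append(next(t for t in burned if t[1] == 0))
    model, history, n_iter, converged = None, [-np.inf], 0, False
    for _, _, m in polish:
        m2, h2, it2, conv2 = _run_em(m, obs_list, tol, max_iter,
                                     transition_pseudocount)
        if h2[-1] > history[-1]:
            model, history, n_iter, converged = m2, h2, it2, conv2

    vit = viterbi_paths(model, obs_list)
    occ = np.bincount(np.concatenate(vit), minlength=n_states)
    pop_vit = occ / occ.sum()
    pop_stat = _stationary_of_transmat(model.transmat)
    n_frames_total = sum(len(o) for o in obs_list)
    m = model.n_free_parameters()
    bic = -2.0 * history[-1] + m * math.log(n_frames_total)
    rate_matrix = None
    if frame_rate is not None:
        rate_matrix = rates_from_probabilities(model.transmat, frame_rate,
                                               structural_zeros)
    return HmmFitResult(model=model, log_likelihood=history[-1], bic=bic,
                        n_free_parameters=m, viterbi=vit,
                        populations_viterbi=pop_vit,
                        populations_stationary=pop_stat,
                        frame_rate=frame_rate, rate_matrix=rate_matrix,
                        n_restarts=len(candidates), n_iter=n_iter,
                        converged=converged, seed=seed,
                        n_frames_total=n_frames_total)


def _stationary_of_transmat(tm: np.ndarray) -> np.ndarray:
    n = tm.shape[0]
    a = np.vstack([tm.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def viterbi_paths(model: HmmModel, traces, columns=("E",)) -> list[np.ndarray]:
    """Most probable hidden-state path per trace (deterministic)."""
    obs_list = traces if (traces and isinstance(traces[0], np.ndarray)
                          and traces[0].ndim == 2) \
        else as_observations(traces, columns)
    with np.errstate(divide="ignore"):
        log_tm = np.log(model.transmat)
        log_start = np.log(model.startprob)
    out = [None] * len(obs_list)
    for idxs, x in _batch_by_length(obs_list):
        logb = model.emission_logprob(x)               # (N, T, n)
        if np.any(np.all(np.isneginf(logb), axis=2)):
            n_bad, t_bad = np.argwhere(np.all(np.isneginf(logb), axis=2))[0]
            raise FloatingPointError(
                f"frame {t_bad} of trace {idxs[n_bad]} has zero likelihood "
                "under every state")
        n_tr, n_t, n = logb.shape
        delta = log_start + logb[:, 0]
        psi = np.empty((n_tr, n_t, n), dtype=np.int8)
        for t in range(1, n_t):
            cand = delta[:, :, None] + log_tm          # (N, i, j)
            psi[:, t] = cand.argmax(axis=1)
            delta = cand.max(axis=1) + logb[:, t]
        states = np.empty((n_tr, n_t), dtype=np.int64)
        states[:, -1] = delta.argmax(axis=1)
        for t in range(n_t - 2, -1, -1):
            states[:, t] = psi[np.arange(n_tr), t + 1, states[:, t + 1]]
        for k, idx in enumerate(idxs):
            out[idx] = states[k]
    return out


def select_model_bic(traces, candidates: dict, columns=("E",), **fit_kwargs):
    """Fit every candidate spec and pick the one minimising BIC.

    ``candidates`` maps a name to keyword arguments for
    :func:`fit_ensemble_hmm` (e.g. n_states/tying/structural_zeros).
    Returns ``(best_name, fits, table)`` with the full BIC table.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate spec")
    fits, rows = {}, []
    for name, kw in candidates.items():
        merged = {**fit_kwargs, **kw}
        try:
            fit = fit_ensemble_hmm(traces, columns=columns, **merged)
        except (ValueError, FloatingPointError) as exc:
            warnings.warn(f"candidate {name!r} failed to fit: {exc}",
                          stacklevel=2)
            continue
        fits[name] = fit
        rows.append({"candidate": name, "n_states": fit.model.n_states,
                     "log_likelihood": fit.log_likelihood,
                     "n_free_parameters": fit.n_free_parameters,
                     "bic": fit.bic, "converged": fit.converged})
    if not fits:
        raise RuntimeError("no candidate model converged")
    table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    best = table.iloc[0]["candidate"]
    return best, fits, table


def bootstrap_rate_cis(fit: HmmFitResult, traces, n_boot: int = 100,
                       seed: int | None = None, columns=("E",),
                       max_iter: int = 100) -> CiSet:
    """95% CIs per rate from trace-level bootstrap refits.

    Resamples traces with replacement, refits from the trained model as a
    warm start, and takes per-rate percentile intervals of the refitted
    rates.  Seeded and reproducible.
    """
    if fit.frame_rate is None:
        raise ValueError("fit must carry a frame rate to bootstrap rates")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if len(traces) < 2:
        raise ValueError("bootstrap needs at least 2 traces")
    rng = np.random.default_rng(seed)
    obs_list = as_observations(traces, columns)
    samples = np.empty((n_boot, fit.model.n_states, fit.model.n_states))
    for b in range(n_boot):
        idx = rng.integers(len(obs_list), size=len(obs_list))
        resample = [obs_list[i] for i in idx]
        refit = fit_ensemble_hmm(resample, n_states=fit.model.n_states,
                                 tying=fit.model.tying,
                                 structural_zeros=fit.model.structural_zeros,
                                 frame_rate=fit.frame_rate,
                                 init_model=fit.model, max_iter=max_iter,
                                 tol=1e-5)
        samples[b] = refit.rate_matrix.k
    lo = np.percentile(samples, 2.5, axis=0)
    hi = np.percentile(samples, 97.5, axis=0)
    return CiSet(half_widths=(hi - lo) / 2.0, n=1)


def recovered_delta_g(fit: HmmFitResult, cycle: CycleSpec | None = None,
                      floor: float | str | None = "auto",
                      threshold: float = 1.0) -> ThermoSummary:
    """Cycle free energy (with CI bounds if present) from a trained fit.

    ``floor="auto"`` floors rates at 1/(total observed time): a transition
    never observed in T seconds of data cannot be resolved below 1/T, and
    without a floor a zero backward rate leaves the free energy undefined.
    """
    if fit.rate_matrix is None:
        raise ValueError("fit carries no rate matrix (frame_rate not given)")
    if floor == "auto":
        floor = 1.0 / fit.total_observation_time
    ci = fit.ci if fit.ci is not None else CiSet.zeros(fit.model.n_states)
    return delta_g_with_errors(fit.rate_matrix, ci, cycle=cycle,
                               floor=floor, threshold=threshold)


# ---------------------------------------------------------------------------
# label-switching resolution

def _symmetry_permutations(tying, structural_zeros):
    """State permutations preserving the tying partition and zero pattern."""
    n = len(tying)
    zeros = set(structural_zeros)
    for perm in itertools.permutations(range(n)):
        if any(tying[perm[i]] != tying[i] for i in range(n)):
            continue
        if {(perm[i], perm[j]) for i, j in zeros} != zeros:
            continue
        yield perm


def permute_states(fit: HmmFitResult, perm) -> HmmFitResult:
    """Relabel hidden states: new state ``perm[i]`` is old state ``i``."""
    perm = tuple(perm)
    inv = np.argsort(perm)
    model = fit.model
    new_model = replace(
        model,
        transmat=model.transmat[np.ix_(inv, inv)],
        startprob=model.startprob[inv],
    )
    new_rates = None
    if fit.rate_matrix is not None:
        new_rates = RateMatrix(fit.rate_matrix.k[np.ix_(inv, inv)],
                               fit.rate_matrix.structural_zeros)
    new_ci = None
    if fit.ci is not None:
        new_ci = CiSet(fit.ci.half_widths[np.ix_(inv, inv)], n=fit.ci.n)
    perm_arr = np.asarray(perm)
    return replace(fit, model=new_model,
                   viterbi=[perm_arr[v] for v in fit.viterbi],
                   populations_viterbi=fit.populations_viterbi[inv],
                   populations_stationary=fit.populations_stationary[inv],
                   rate_matrix=new_rates, ci=new_ci)


def align_states(fit: HmmFitResult, true_sequences) -> HmmFitResult:
    """Resolve label switching against known ground-truth state paths.

    Degenerate states are only defined up to the model's symmetry group
    (permutations preserving the emission tying and the structural-zero
    pattern); the permutation maximising frame-wise Viterbi agreement with
    the ground truth is applied.
    """
    true_sequences = [np.asarray(s) for s in true_sequences]
    best_perm, best_score = None, -1
    for perm in _symmetry_permutations(fit.model.tying,
                                       fit.model.structural_zeros):
        perm_arr = np.asarray(perm)
        score = sum(int((perm_arr[v] == t).sum())
                    for v, t in zip(fit.viterbi, true_sequences))
        if score > best_score:
            best_perm, best_score = perm, score
    return permute_states(fit, best_perm)
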