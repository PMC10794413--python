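# Methods

## Model

A molecule's conformational dynamics are modelled as a continuous-time
Markov chain on a four-state ring 0–1–2–3–0. States 0 and 1 are "open"
(low FRET), 2 and 3 "closed" (high FRET); the cross transitions 0↔2 and
1↔3 are structural zeros (in the motivating Hsp90 data these rates are
indistinguishable from zero). Observation is stroboscopic at the camera
frame rate f: the chain is sampled once per frame and each frame emits a
FRET efficiency from its state's emission class. Because the two states
within a class share the emission distribution exactly, the open pair and
the closed pair are *degenerate* — distinguishable only through kinetics.

Thermodynamics of the stationary chain:

- cycle free energy ΔG = −Σ ln(k_ij/k_ji) over the ring's directed edges,
  in units of k_BT (k_BT ≡ 1 internally). ΔG = 0 iff the Kolmogorov
  criterion holds; reversing the cycle orientation flips the sign exactly,
  and the sign carries no information beyond the cycle direction.
- per-edge net flux J_ij = π_i k_ij − π_j k_ji at the stationary π; on a
  single ring all edges carry the same net flux.
- entropy production rate (Schnakenberg form)
  σ = ½ Σ_ij (π_i k_ij − π_j k_ji) ln[(π_i k_ij)/(π_j k_ji)] ≥ 0, zero iff
  detailed balance.

A measurement is called **directional** when |ΔG| > 1 k_BT. That
threshold reflects the spread of equilibrium control measurements
(roughly +0.3 to −0.9 k_BT) and is configurable.

### Rate flooring

ΔG is undefined when a cycle edge has no observed backward transitions.
Estimated rates are therefore floored, before evaluating ΔG, at
ε = 1/(total observed time): a rate below one event per observation
window is not resolvable, and the floor makes verdicts on strongly driven
data (e.g. the deterministic trigger control, which has *no* backward
transitions) finite and explicit. Flooring is off by default in the
low-level `cycle_free_energy` and on (`floor="auto"`) in the fitted-model
path `recovered_delta_g`.

### Error propagation

Each fit yields per-rate 95% CIs (trace-level bootstrap, default 100
resamples). ΔG bounds evaluate the cycle sum at the CI-shifted rate
combinations that extremise it; each edge term is monotone in both rates,
so the corner assignment equals exhaustive enumeration (tested against
it). Replicates are merged by treating per-replicate CI lengths as
standard errors: mean rates across replicates, pooled CI length
(1/√n)·√(Σ lengths²/(n−1)), then ΔG of the mean rates ± pooled CI. The
pooling formula divides by n−1 and is deliberately an error for n = 1.

## Synthetic data generator

`simulate_dataset` draws, per trace, an initial state from the stationary
distribution and a discrete-time path with per-frame transition
probabilities p_ij = k_ij/f (the generator refuses rate matrices whose
off-diagonal row sums exceed the frame rate). Emissions are Gaussian on
efficiency — class means 0.1/0.8, SDs 0.05/0.05 — clipped to [−0.2, 1.2]
(corrected experimental efficiencies exceed [0, 1] under noise; an
unclipped tail would be unrealistic). Optionally the three ALEX intensity
channels are synthesised by inverting the photometric corrections at the
configured factors. Defaults are the validation-campaign conditions:
200 traces × 200 frames at 2 Hz per condition.

What the generator deliberately does *not* emulate: photobleaching,
blinking, diffusing-molecule photon statistics, camera/EMCCD noise, or
frame-averaging of intra-frame transitions (the chain is sampled exactly
at frame boundaries, matching the HMM's own assumption). Passing the
recovery tests therefore demonstrates correctness of the inference chain
under the stated noise model, not robustness to every artefact of real
movies; the photometric-correction and dwell-analysis stages are the
parts exercised by real-data peculiarities.

### Campaign presets

The five validation conditions are (units 1/s, ring edges only):

- **ΔG = 0 (Hsp90-like)** — detailed-balance base with long-lived states
  0 and 3 (exit rate 0.1) and short-lived 1 and 2 (exit 1.0), each state's
  exit split evenly over its two neighbours; populations
  ≈ (0.45, 0.05, 0.05, 0.45), i.e. roughly half the molecules in the
  long-lived states, dwell times 10 s vs 1 s.
- **ΔG = −2 (Hsp90-like)** — same structure with base long exit 0.2; the
  affinity is injected on edge (2,3) — the transition whose acceleration
  drives directionality — as a symmetric split (k₂₃·e^{+1}, k₃₂·e^{−1}),
  then the whole matrix is rescaled so the largest per-frame exit
  probability is 0.5. A global rescale changes only the time unit: ΔG and
  the populations are invariant. The base long exit is chosen so the
  *rescaled* matrix keeps ~10 s long-state dwells; driving the forward
  rate alone by e² would, after the feasibility rescale, stretch the
  long dwells to a third of the trace length and make the condition
  unidentifiable at 200 frames.
- **ΔG = −2 (uniform), −3, −10** — uniform ring (equal populations at any
  drive) with the affinity split evenly over all four edges and
  symmetrically within each edge, rescaled the same way. Concentrating
  −10 k_BT on one edge is not observable at 2 Hz: the driven rate would
  reach ~10⁴/s and the rescale would freeze every other transition.

## Ensemble HMM

One transition matrix (structural zeros pinned to exactly 0 throughout
training, decoding and serialisation), one tied emission set and one
initial distribution are shared across all traces; the likelihood is the
product over traces. Emissions are diagonal Gaussians per class in 1 or 2
observation dimensions (corrected efficiency by default; donor/acceptor
channels selectable via `columns`). The tied M-step pools
responsibilities over the states of a class, so tied parameters are
bit-identical by construction. Emission SDs are floored at 1e-4.

**Estimation is MAP, not plain ML.** The M-step adds a symmetric
Dirichlet pseudocount (+1 per allowed transition entry, configurable via
`transition_pseudocount`). Rationale: with tied emissions the likelihood
is nearly flat along the attribution of within-class transitions (the
emission signal cannot see a 0→1 or 2→3 jump directly), while ΔG varies
strongly along that ridge; the weak prior selects the least extreme ridge
point and is negligible wherever real transition counts exist (tens to
thousands per edge in the campaign conditions).

**Initialisation and restarts.** Restart 0 is segmentation-informed:
two-level Otsu split of the pooled signal, per-level short/long dwell
split (Otsu on log durations of interior runs — truncated boundary runs
are excluded, since they would contaminate the short mode), transition
counts from the resulting 4-state labels, plus a small uniform blend over
allowed transitions (run-length labels cannot witness within-class
jumps). Both splits are deterministic. Remaining restarts
use uniform small off-diagonal probabilities with ±20% jitter —
deliberately symmetric, again because an asymmetric start would be frozen
into the flat ridge. All restarts run a 40-iteration burn-in; the top
three by likelihood plus the segmentation candidate are run to
convergence (Δ lnL < 1e-6, at most 500 iterations; non-convergence is
flagged on the result, never silently accepted) and the best final
likelihood wins.

**Derived quantities.** Per-second rates are k_ij = P_ij·f (linear
conversion; rates are far below the frame rate in all conditions
treated). Populations are reported both as Viterbi-path occupancy and as
the stationary distribution of the fitted transition matrix — they answer
different questions: Viterbi occupancy is the idealised-path census
(reliable when states are kinetically well separated, e.g. the trigger
control), while the stationary distribution reflects the model itself
(more robust when Viterbi smooths over brief within-class visits). BIC is
−2 lnL + m ln(N frames) with m = free transition entries (allowing the
diagonal, excluding structural zeros and row-sum constraints) + 2
emission parameters per class per dimension + (n−1) start probabilities;
the count is exposed for audit. Bootstrap CIs refit resampled trace sets
from the trained model as warm start.

**Label switching.** Degenerate states are identified only up to the
model's symmetry group — permutations preserving the tying partition and
the structural-zero pattern (for the ring: identity and the simultaneous
swap (01)(23), which reverses the cycle orientation). When ground truth
is available, `align_states` picks the permutation maximising frame-wise
Viterbi agreement; ΔG comparisons use |ΔG| since the sign is orientation.

**Known behaviour.** On the synthetic campaign the recovered |ΔG| of
driven conditions tends to *over*estimate the programmed magnitude by up
to ~1.7× (never, in the seeds examined, underestimating by more than a
few percent), and the detailed-balance condition recovers |ΔG| typically
below 0.4 k_BT with occasional draws near 1 — both are the intrinsic
scatter of the maximum-(posterior-)likelihood point along the
weakly-identified within-class ridge at 40 000 frames, not an
implementation artefact: EM initialised at the true parameters reproduces
the same values. Bootstrap CIs are the honest statement of that
uncertainty.

## Trigger control

The laser-trigger generator replays the deterministic loop long-high →
long-low → short-high → short-low (the two text descriptions of the
published pattern disagree on the starting phase; the figure-side order
is the default and the order is configurable) with 10- and 3-frame blocks
at 0.5 s/frame — a 26-frame, 13 s period — plus Gaussian efficiency
noise; each trace starts at a random phase. State labels: long-low = 0,
short-low = 1, short-high = 2, long-high = 3, so the long-lived states
are 0 and 3 as in the ring convention. Ground-truth rates are the inverse
programmed block durations on the loop's edges. Because the loop
alternates FRET level every block, the HMM for this dataset uses
structural zeros on the *same-level* pairs (0↔1, 2↔3) instead of the ring
zeros — the ring zeros would forbid the loop's actual edges. The
programmed loop has no backward transitions, so its ΔG is undefined
(recorded as None); fitted backward rates land at the resolution floor,
reproducing the expected "very large |ΔG|" verdict on triggered data.

## Dwell analysis

Savitzky–Golay smoothing (window 5 frames, polynomial order 2 — the order
is unstated in the source protocol; edges use the standard
first/last-window polynomial so polynomial signals are fixed points),
per-trace midline allocation (frames exactly on the midline go low —
deterministic and measure-zero), run-length encoding into dwells with the
truncated first/last dwell excluded from histograms (their true length is
unobserved), 0.5 s histogram bins centred on whole frames, and short/long
classification at the geometric mean of the two lifetimes
(√(1.5·5) ≈ 2.74 s by default, or estimated by a deterministic
maximum-between-class-variance split of the log durations; a split is
refused when the two dwell classes differ by less than 1.5-fold, since
degenerate states cannot then be resolved).

## Statistics

Cross-condition comparisons are two-sided independent t-tests with
step-down Šidák (Holm–Šidák) adjustment,
p_adj(i) = 1 − (1 − p_(i))^(m−i+1) with monotonicity enforcement; pairs
with fewer than two replicates are skipped with a warning.

## Problem sizes

The validation campaign runs five conditions at 200 traces × 200 frames
(40 000 frames each) and the trigger control at 349 traces × 200 frames,
chosen to match the published simulation protocol; the test suite
exercises reduced sizes (20–60 traces) for unit-level checks and the full
sizes in the acceptance tests.
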