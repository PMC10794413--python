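# fretflux

Detecting and quantifying **broken detailed balance** in single-molecule
FRET recordings of conformational dynamics.

Many molecular machines are drawn as unidirectional cycles, but whether a
conformational cycle is actually *directed* — i.e. driven by an energy
source such as ATP hydrolysis — cannot be decided from ensemble
measurements, because state populations are constant both in equilibrium
and in a non-equilibrium steady state. Single-molecule FRET time traces
can decide it: a system in **detailed balance** satisfies
π<sub>i</sub>k<sub>ij</sub> = π<sub>j</sub>k<sub>ji</sub> on every edge,
while a **steady state** carries a net cyclic flux. The motivating system
is the Hsp90 chaperone dimer, whose open/closed dynamics occupy four
kinetic states on a ring 0–1–2–3–0: two open states (0, 1) and two closed
states (2, 3) that are *degenerate* in FRET efficiency and separable only
by their kinetics.

The central statistic is the free energy dissipated per cycle,

$$\Delta G_\circlearrowleft \;=\; -\sum_{\text{edges}} \ln\!\frac{k_{ij}}{k_{ji}} \quad [k_\mathrm{B}T],$$

zero iff the Kolmogorov criterion holds (detailed balance); its sign only
encodes the cycle's direction. Experiments without an energy source
scatter within roughly ±1 k<sub>B</sub>T, so |ΔG| > 1 k<sub>B</sub>T is
treated as clearly directional. Per-edge net fluxes
π<sub>i</sub>k<sub>ij</sub> − π<sub>j</sub>k<sub>ji</sub> and the
Schnakenberg entropy production rate are reported alongside.

The package provides the full analysis chain and its validation campaign:

- **`fretflux.kinetics`** — rate-matrix model of the ring, stationary
  distributions, detailed-balance residuals, cycle free energy, net flux,
  entropy production, confidence-interval propagation and the
  replicate-averaging rule
  $\overline{\mathrm{CI}} = \tfrac{1}{\sqrt n}\sqrt{\sum_i \mathrm{CI}_i^2/(n-1)}$.
- **`fretflux.photometry`** — ALEX three-channel corrections (leakage
  α = 0.16, direct excitation δ = 0.12, γ = 1.09, β = 0.86) to corrected
  FRET efficiency E and stoichiometry S, plus the exact inverse used by
  the simulator.
- **`fretflux.simulate`** — synthetic ground-truth data: stochastic
  four-state ring traces with degenerate Gaussian emissions
  (E<sub>low</sub> = 0.1 ± 0.05, E<sub>high</sub> = 0.8 ± 0.05; 200 traces
  × 200 frames at 2 Hz per condition) at configurable cycle ΔG, and the
  deterministic laser-trigger control (3- and 10-frame blocks at
  0.5 s/frame, i.e. 1.5 s vs 5 s lifetimes).
- **`fretflux.hmm`** — the ensemble hidden Markov model: one shared
  transition matrix with structural zeros on the forbidden diagonal
  transitions (0↔2, 1↔3), emissions tied exactly across degenerate state
  pairs, MAP Baum–Welch over the whole trace ensemble, BIC model
  selection, Viterbi decoding, and bootstrap rate CIs.
- **`fretflux.dwell`** — model-free control analysis: Savitzky–Golay
  smoothing (5-frame window), per-trace midline state allocation,
  dwell-time histograms (0.5 s bins) and short/long lifetime
  classification that resolves four states from a two-level signal.
- **`fretflux.pipeline` / `fretflux.cli`** — campaign orchestration,
  replicate merging, Holm–Šídák-corrected pairwise t-tests, and the
  `fretflux` command with verbs `simulate`, `trigger`, `fit`, `thermo`,
  `benchmark`, `compare`.

## Worked example

```python
import numpy as np
import fretflux as ff

rates = ff.uniform_ring_rates(-2.0)          # driven ring, uniform populations
print("true dG:", round(ff.cycle_free_energy(rates), 3))

traces, truth = ff.simulate_dataset(
    ff.SimulationConfig(rates=rates, n_traces=60, n_frames=200, seed=7))
fit = ff.fit_ensemble_hmm(traces, frame_rate=2.0, n_restarts=6, seed=7)
thermo = ff.recovered_delta_g(fit)
print("recovered dG: %.2f k_BT" % thermo.delta_g)
print("directional:", thermo.directional)
print("populations:", np.round(fit.populations_stationary, 3))
print("entropy production: %.3f k_B/s" % thermo.entropy_production)
```

prints

```
true dG: -2.0
recovered dG: -2.48 k_BT
directional: True
populations: [0.164 0.318 0.317 0.2  ]
entropy production: 0.171 k_B/s
```

The generator's ring dissipates 2 k<sub>B</sub>T per cycle; from 60 noisy
traces the ensemble HMM recovers −2.48 k<sub>B</sub>T — the right
magnitude and orientation, flagged directional because |ΔG| exceeds the
1 k<sub>B</sub>T control envelope — together with near-uniform state
populations (truth: 0.25 each) and a positive entropy production rate.
At the full campaign scale (200 traces) the estimate tightens further.

Externally recorded trace tables (CSV with `frame, time_s` and either `E`
or `I_DD, I_DA, I_AA`) run through the same pipeline:

```sh
fretflux fit traces/*.csv --frame-rate 2 --n-boot 100 --out fit.json
```

which applies the photometric corrections, fits the tied-emission HMM and
reports ΔG with bootstrap error bounds and the directionality verdict.

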