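# rodspr

Space-resolved modeling and statistics of **single photon responses (SPRs)
in retinal rod outer segments**.

Rod photoreceptors count photons: one photoisomerized rhodopsin (R\*) on
one of ~10³ stacked disks triggers local cGMP hydrolysis, closes
cyclic-nucleotide-gated (CNG) channels in the nearby plasma membrane, and
suppresses ~1 pA of the circulating dark current. Where on the disk stack
the photon lands — near the rim vs the disk centre, near the base vs the
tip of the outer segment — and how neuromodulators such as bicarbonate
reshape the cascade, both change the SPR's size and kinetics. This package
provides, for quantitative work on that problem:

* a **homogenized cGMP/Ca²⁺ reaction–diffusion solver** on the simplified
  outer-segment domain (cylinder interior with transversal-only diffusion,
  concentrated shell and incisure conduits, concentrated activated-disk
  sink), discretized with prism/triangle/rectangle finite elements and
  integrated by the Wilson-theta method, with deterministic or stochastic
  (continuous-time Markov chain) R\* shutoff and lateral PDE\* spread on
  the disk membrane;
* an independent axisymmetric **finite-difference oracle** for
  cross-verification;
* **response-shape metrics**: peak, time to peak `t_p`, integration time
  `T_i` (integral/peak), recovery time constant τ from `A·exp(−t/τ)` fitted
  80→20% of peak, 20–60% rising slope with an `r² > 0.8` gate, flash
  sensitivity `i₀.₅` from `r/r_max = 1 − exp(−k·i)`;
* the **compound-Poisson amplitude mixture**
  `p(r) = Σ_k e^{−m} m^k/k! · N(r; k·a, σ₀² + k·σ₁²)`
  with unbinned-ML and histogram fitting, per-trial template amplitudes,
  and a **Monte-Carlo Kolmogorov–Smirnov** goodness-of-fit test at fixed
  fitted parameters;
* a **synthetic dim-flash experiment generator** (Poisson trials, slit
  optics for edge/middle and base/tip stimulation, Bessel-type recording
  filter, ground-truth ledger) so the whole analysis chain is testable
  without recordings;
* named **scenarios**: bicarbonate as calibrated cyclase multipliers, and
  homogeneous "rod-b"/"rod-t" surrogates for the base and tip of a toad
  outer segment.

## Worked example

```python
from rodspr import (SimulationConfig, SPRSolver, PhotoisomerizationEvent,
                    species_preset, compute_metrics)
from rodspr.geometry import MeshResolution

geom, params = species_preset("salamander")   # 11 um disks, 23 incisures
solver = SPRSolver(geom, params, MeshResolution(8, 46, 12))
print(f"dark current: {solver.dark.j_dark:.1f} pA")

event = PhotoisomerizationEvent(disk_index=geom.n_disks // 2,
                                radial_position=0.0, angular_position=0.0)
trace = solver.run(SimulationConfig(dt=5.0, t_end=8000.0), event)
m = compute_metrics(trace)
print(f"SPR peak {m.r_peak:.2f} pA, t_p {m.t_p:.0f} ms, "
      f"T_i {m.T_i:.0f} ms, tau {m.tau_rec:.0f} ms")
```

prints

```
dark current: 25.0 pA
SPR peak 0.70 pA, t_p 1205 ms, T_i 2384 ms, tau 1417 ms
```

— a single photon suppresses 0.70 pA of the 25 pA circulating current,
peaking at 1.2 s and recovering with τ ≈ 1.4 s, the dim-flash behaviour of
a large salamander rod. Applying the bundled calibrated bicarbonate
scenario (`rodspr.scenarios.load_scenario("bicarb_salamander_calibrated")`)
raises the dark current by 13% and shortens τ by 16.5%.

For the statistics stack:

```python
from rodspr.synthetic import EnsembleSpec, generate_trial_ensemble
from rodspr.spr_stats import estimate_ensemble_amplitudes, \
    fit_amplitude_histogram, monte_carlo_ks_pvalue

traces, truth = generate_trial_ensemble(EnsembleSpec(n_trials=100, seed=0))
sample = estimate_ensemble_amplitudes(traces)
fit, diag = fit_amplitude_histogram(sample)
ks = monte_carlo_ks_pvalue(sample.amplitudes, fit, n_mc=100_000, seed=0)
print(f"m={fit.m:.2f}, a={fit.a:.2f} pA, sigma0={fit.sigma0:.2f}, "
      f"p={ks.p_value:.2f}")
```

prints `m=0.96, a=0.69 pA, sigma0=0.08, p=0.97` — recovering the
generating mixture (0.8 photoisomerizations/trial, 0.7 pA per photon,
within sampling error at 100 trials) with a Monte-Carlo KS p-value of
0.97 (no significant disagreement between data and mixture).

A thin CLI wraps the same functions: `rodspr simulate`, `rodspr synth`,
`rodspr analyze`, `rodspr compare` (see `--help`).

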