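# Methods

## The model

A rod outer segment (ROS) is modeled as a cylinder of radius `R` and length
`L` (µm), stacked with ~10³ membranous disks. The two cytosolic second
messengers, cGMP and Ca²⁺, obey a homogenized reaction–diffusion system in
which the fine disk-stack geometry appears only through effective
coefficients:

* **Interior.** The cytosol occupies the interdiskal gaps, a volume fraction
  `ε₀ = gap / (gap + disk_thickness)` of the cylinder (default 0.5 with
  14 nm gaps and disks). Diffusion in the interior is *transversal only*
  (radial/angular): the disks block axial diffusion.
* **Outer shell.** The thin cytosol between disk rims and the plasma
  membrane collapses onto the cylindrical boundary as a concentrated
  capacity `σ_R` (default 0.015 µm) carrying full two-dimensional diffusion
  in `(φ, z)`. This is the main axial conduit of the cell together with:
* **Incisures.** Each radial slot in the disk rim becomes a vertical
  rectangle (radial extent = incisure depth, capacity = slot width, default
  0.05 µm) with diffusion in `(r, z)`. Incisure angular positions must lie
  on mesh lines; depths are snapped to ring radii so the rectangles conform
  to prism faces.
* **Activated disk.** The photoisomerized disk becomes a horizontal
  cross-section carrying (i) the concentrated hydrolysis sink
  `k_hyd · E*(x, t) · cG` and (ii) a concentrated capacity equal to its two
  adjacent interdiskal gaps (`2 × gap`) with its own transversal diffusion.
  Term (ii) matters: with zero interior axial diffusion, the activated
  plane is a quasi-2-D compartment that exchanges with the bulk only
  through the shell and incisure conduits; without its own capacity the
  concentrated sink has no well-behaved refinement limit.

Reactions: cyclase synthesis `α(Ca) = α_min + (α_max − α_min)/(1 +
(Ca/K_cyc)^m_cyc)` and dark hydrolysis `β_d · cG` act on every cytosolic
capacity; CNG-channel Ca²⁺ entry (fraction `f_Ca` of the local CNG current,
2 charges per ion) and saturable exchanger extrusion (`J_ex^sat ·
Ca/(Ca+K_ex)`, 1 net charge per ion) act as surface sources on the shell;
fast buffering scales Ca²⁺ accumulation by `B_Ca`. The observable is the
circulating current `J = J_CNG + J_ex` with `J_CNG = J_CNG^sat · x/(1+x)`,
`x = (cG/K_cg)^{m_cg}`, integrated over the shell; responses are reported
as the suppression `r(t) = J_dark − J(t)` (pA, positive).

**Front end.** One photoisomerization produces R\*, which is quenched
through 6 phosphorylation states (equal rates) and arrestin capping —
either sampled as a continuous-time Markov chain or replaced by its
deterministic surrogate `exp(−t/τ_R)` with `τ_R` equal to the chain's
expected integrated activity (so both modes deliver the same expected
drive). Active R\* produces activated transducin/PDE (E\*) at `ν_RG` per ms
per unit activity; E\* spreads on the disk surface by lateral diffusion
(`D_E`), decays at `k_E`, and cannot cross incisures — the surface mesh
duplicates nodes along incisure lines so they act as internal no-flux cuts.

## Discretization

P1 triangles on a polar structured cross-section, extruded into 6-node
prisms (triangle × linear-in-z tensor basis); shell and incisure rectangles
are the corresponding prism faces, assembled as 1-D chains (rim polygon,
radial lines) tensored with the axial basis. Time integration is the
Wilson-theta method: collocation at `t + θ·Δt` with `θ ≥ 1` (default 1.37,
the classic unconditional-stability choice; `θ = 1` is backward Euler),
Picard iteration on the nonlinear forcing (relative tolerance 1e-8, max 50
iterations), step rejection with Δt halving if a field would go negative.
Two iteration-robustness devices keep the fixed point unchanged while
making the Picard map contractive at practical Δt: the exchanger
conductance linearized at the dark state sits inside the Ca factorization,
and a slowly-refreshed snapshot of the (diagonal) hydrolysis sink sits
inside the cGMP factorization, with only the drift since the snapshot
iterated.

An independent axisymmetric finite-volume/backward-Euler solver
(`rodspr.fdsolver`) discretizes the same equations on an `(r, z)` grid for
incisure-free, on-axis configurations and serves as a cross-check; the two
codes share no discretization machinery.

## Parameters

Units are µm, ms, µM, pA throughout. No single published parameter table
covers this model; the bundled species presets are this package's own
operating points, chosen within the ranges reported for amphibian rods and
calibrated against macroscopic observables:

| symbol | salamander | toad | meaning |
|---|---|---|---|
| D_cG / D_Ca | 0.08 / 0.25 | same | cytosolic diffusivities (µm²/ms); D_Ca is the free-ion value, B_Ca=20 buffers it |
| β_d | 4.5e-4 | 7.5e-4 | dark hydrolysis (1/ms) |
| α_min, α_max | 1.20e-3, 7.20e-3 | 2.14e-3, 8.55e-3 | cyclase range (µM/ms) |
| K_cyc, m_cyc | 0.08 µM, 2 | 0.06 µM, 2 | cyclase Ca half-inhibition |
| J_CNG^sat, K_cg, m_cg | 694 pA, 16 µM, 2 | 281 pA, 16 µM, 2 | CNG channel |
| f_Ca | 0.12 | 0.12 | Ca fraction of CNG current |
| J_ex^sat, K_ex | 5.66 pA, 1.5 µM | 2.48 pA, 1.5 µM | exchanger |
| ν_RG, k_E, D_E | 0.30/ms, 1/400, 1.2e-3 | 0.30/ms, 1/500, 1.2e-3 | activation chain |
| k_hyd | 1.4e-3 | 4.0e-3 | hydrolysis capacity per E* (µm³/ms) |
| R* chain | 6 × (1/120), cap 1/30 | 6 × (1/140), cap 1/35 | phosphorylation / capping rates (1/ms) |

Calibration targets (all recorded values from amphibian rods): salamander
dark current 25 pA, dark cGMP 3 µM, dark Ca²⁺ 0.5 µM, SPR ≈ 0.7 pA with
t_p ≈ 1.2 s, T_i ≈ 2.4 s, τ ≈ 1.4 s; toad dark current 10.1 pA, SPR (base)
0.74 pA with T_i ≈ 2.5 s. The dark operating point deliberately sits far
above `K_cyc` (small dark cyclase reserve) with a fast front end and a slow
dark cGMP turnover; this reproduces the fast-rising, slow-recovering
dim-flash shape and lets cyclase stimulation act mainly on recovery.

**Bicarbonate** is modeled purely as parameter multipliers (no transport or
pH mechanism). The shipped `bicarb_salamander_calibrated` scenario carries
cyclase multipliers (α_min × 0.995, α_max × 2.06) solved by
`calibrate_cyclase` against the recorded effects (+13.0% dark current,
−16.5% recovery τ); the α_max factor lands at ≈ 2, a doubling of the low-Ca
rate. The literature's printed variants (α_min × 1.07 or × 1.13 with α_max
× 2.0) are also bundled; in this parameterization they overshoot the
dark-current change (≈ +27%), which is why the calibrated scenario is the
default for quantitative comparisons.

**Base vs tip** (toad) is modeled as two homogeneous rods: rod-t differs
from rod-b by ν_RG × 0.52 and f_Ca × 1.56 (raising dark Ca²⁺ ≈ +50-60%);
bicarbonate variants apply α_max × 2 with ν_RG × 0.7 (rod-b) and α_max ×
1.3 with f_Ca × 0.75 (rod-t). An axial-gradient mode is not implemented.

## Synthetic recordings

`rodspr.synthetic` emulates suction-electrode dim-flash experiments: per
trial a Poisson number of photoisomerizations (`m` per trial), each scaling
a unit-peak SPR template by `a + N(0, σ₁)` with σ₁ = 0.2·a by default (the
reproducibility of real SPRs); plus low-pass-filtered Gaussian recording
noise (4-pole Bessel-type filter, 20 Hz cutoff, 400 Hz sampling) and
optional linear baseline drift. `baseline_sd` parameterizes the noise in
the *amplitude domain*: the injected noise is scaled so that the
template-projection amplitude of a pure-noise trial has this SD (the gain
is estimated per ensemble from 600 noise realizations, including the
pre-flash baseline subtraction step). Slit optics restrict
photoisomerization positions: parallel slits confine them to a rim band
("edge") or the central chord ("middle"); perpendicular slits fix an axial
band ("base"/"tip"). What the generator does *not* emulate: continuous
cascade-origin dark noise, template shape variability across trials,
nonstationary drift — so passing recovery tests here demonstrate estimator
correctness under the model's own assumptions, not robustness to every
feature of real recordings.

## Amplitude statistics

Trial amplitudes follow the compound-Poisson Gaussian mixture
`p(r) = Σ_k e^{−m} m^k/k! · N(r; k·a, σ₀² + k·σ₁²)`; the series is
truncated at the smallest `k_max` with Poisson tail mass < 1e-6. σ₀ and σ₁
are standard deviations. Fitting is unbinned maximum likelihood by default
(the histogram least-squares procedure, bin width 0.1 pA, is available as
`method="binned"`); per-trial amplitudes are template-scaling estimates
against a degree-7 polynomial smoothing of the rod's mean response.
Goodness of fit uses the exact mixture CDF in a KS statistic whose null
distribution is generated by Monte Carlo at the *fixed* fitted parameters
(100,000 replicates by default; this ignores fitting uncertainty and is in
general anti-conservative — a re-fit-per-replicate mode is available as a
clearly labelled extension). Negative amplitudes are allowed throughout.

## Numerical choices and known limitations

* **Survey problem sizes.** The bundled studies use meshes of 8 radial
  rings × (2 sectors per incisure gap) × 12–24 axial layers with Δt = 5 ms
  — the package's stated survey quality; one deterministic SPR runs in tens
  of seconds on one CPU. Defaults double these counts.
* **Resolution sensitivity.** The concentrated activated-disk sink makes
  the absolute response amplitude sensitive to axial resolution (the
  near-plane depletion layer is ~1 µm); convergence is slow, especially in
  incisure-free geometries where the plane compartment drains only through
  the rim. All scientific comparisons are therefore made at fixed, stated
  resolutions, and the FEM/FD cross-check is run at matched grids and dim
  amplitude (where the solution is regularization-insensitive; agreement
  ≤ 2% of peak). Kinetic ratios between scenarios are far less sensitive
  than absolute amplitudes.
* **Edge vs random positions.** The model robustly predicts the shorter
  onset delay of rim events (≈ 65 ms) but *not* a steeper 20–60% rising
  slope: with channel Hill coefficient > 1 far below half-activation, the
  whole-cell current suppression is concave in the local depletion, so a
  concentrated rim-side depletion closes slightly fewer channel-units than
  the same depletion spread out. The time-to-peak advance of edge events is
  correspondingly modest (≈ 25–35 ms at SPR amplitude, growing as the
  response is made dimmer and with disk radius).
* **Base/tip rise kinetics.** With the front end (R*, E*) identical in both
  surrogate rods, the rise is nearly identical too; the large base/tip
  base-tip time-to-peak differences that motivated these scenarios would need a
  Ca²⁺-dependent front-end mechanism (e.g. recoverin-modulated R*
  lifetime), which this cascade deliberately does not include.
* **Deterministic runs are bitwise reproducible** on a platform; stochastic
  runs are reproducible per seed, with per-trial seeds spawned from the
  master seed via `numpy.random.SeedSequence`.
* The point photoisomerization source is regularized onto the nearest
  surface-mesh node (mass-lumped delta); with duplicated (slit) nodes the
  copy on the event's side of the cut is chosen.
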