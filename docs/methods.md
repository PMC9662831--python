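# Methods

## The stochastic model

`parahop` simulates plasmid positioning by ParABS as a discrete-time
(dt = 0.001 s) 2D off-lattice model on a rectangular nucleoid [0, L]×[0, W].
ParA-ATP dimers have three states — cytosolic, nucleoid-bound and tethered —
and their total number nA is conserved.  Per time step, in this order:

1. **Association.**  Each cytosolic dimer binds with probability `ka·dt` at
   a uniformly random point; the binding point becomes its home position.
   The cytosolic pool carries no spatial state (ParA's slow conformational
   reactivation makes it well mixed).
2. **Basal dissociation.**  Each bound, untethered dimer unbinds with
   probability `kd·dt`.
3. **Tether breakage.**  Each tethered dimer is released to the cytosol
   with probability `kh·dt` (ParB-stimulated hydrolysis).  Tethered dimers
   are not subject to `kd`; the model distinguishes the basal and
   ParB-stimulated pathways.
4. **Bound-dimer motion.**  Per axis, the new position is drawn from the
   exact Ornstein–Uhlenbeck transition density about the home position
   (spring constant 1/σx² or 1/σy², diffusion DA), then a hopping offset
   N(0, 2·Dh·dt) is added to both the position and the home position.
5. **Tether formation.**  A bound dimer within `Rp + RA` of a plasmid
   centre tethers to the nearest such plasmid instantly.
6. **Plasmid motion.**  A plasmid with n ≥ 1 tethers takes an exact OU step
   with spring constant n/σ² per axis, diffusion Dp, and equilibrium point
   x_p + Σ(x_h − x)/n (the tether force is quasi-static within one dt).
   Tethered dimers translate rigidly with their plasmid; their home
   positions do not move, so tether extensions relax as the plasmid
   approaches the home positions.  With no tethers the plasmid takes a free
   Gaussian step of sd √(2·Dp·dt) per axis.
7. **Reflection** of all positions (dimer, home, plasmid) at the rectangle
   boundary.

Torque is ignored; plasmids have no excluded volume and interact only by
competing for ParA.  Event probabilities are rate·dt rather than
1 − exp(−rate·dt); validation enforces dt·max(ka, kd, kh) < 0.1 so the
difference is O(dt²), and the sub-step order is likewise an O(dt²) choice.
Replication duplicates a plasmid in place; the copy inherits the position
but none of the tethers (tether numbers re-equilibrate within seconds).

### Parameters

Defaults (SI-μm units): ka = 0.19 s⁻¹, kd = 0.01 s⁻¹, Dp = 3×10⁻³ μm²/s,
DA = 0.01 μm²/s, σx = 0.1 μm, σy = 0.05 μm, Rp = 0.05 μm, RA = 0.002 μm,
nA = 500, W = 0.95 μm, L = 2.53 μm, dt = 0.001 s.  `kh` and `Dh` are the
swept quantities and have no default; named presets (`fig3C` … `fig3H`,
`fig4`, `fig5`, `fig5rep`, `fig6short`, `fig6long`) provide the published
per-figure combinations.  The dimensionless summary is λ = √(2Dh/kd)/(L/2),
ε = kh/kd, θ = nA·ka/(ka+kd), λn = np·λ; the fitted single-plasmid point
(`fig4`) sits at (λ, ε) = (2.66, 56.42).

### Engines

Two kernels implement identical dynamics:

* **reference** — the literal per-step scheme above; used by `step()` and
  as the statistical oracle in tests.
* **fast** (default for `run()`) — event-driven and statistically
  equivalent: per-step Bernoulli trials are replaced by presampled
  geometric waiting times, and a bound dimer provably unable to reach any
  plasmid within k steps advances those k steps in a single exact
  aggregated Gaussian draw (OU and Brownian increments are Gaussian and
  Markov, so aggregation is exact away from the boundary; near a wall both
  engines approximate reflection by per-draw folding).  "Provably" means a
  5σ envelope on the combined dimer-plus-plasmid displacement variance
  plus a directed-plasmid-motion allowance of 0.2 μm/s and a 0.01 μm
  margin; sleep windows are capped at 512 steps.  The envelope makes a
  missed plasmid contact a ≲10⁻⁶-probability event per window (a handful
  of grazing encounters per 10⁷-step run at worst), which is far below the
  statistical noise of any quantity measured here.  The fast engine is
  ~20× faster at nA = 500 because most dimers are far from the plasmid at
  any instant.

Equivalence of the engines is asserted statistically in the test suite
(bound fraction, tether counts, positional spread and event totals on a
shared configuration).

## Trajectory analysis

**Over-damped spring.**  Sampled positions x(t) with spacing δt give
stepwise velocities v = Δx/δt paired with position relative to the
trajectory mean.  For an OU process, E[v|x₀] = x₀(e^(−δt/τ) − 1)/δt and
Var[v] = (Dτ/δt²)(1 − e^(−2δt/τ)), so the fitted slope m and residual
variance invert to τ = −δt/ln(δt·m + 1) and
D = Var[v]·ln(δt·m + 1)/(δt·m² + 2m); k/kBT = 1/(Dτ) and the
characteristic force is F = kBT·√(k/kBT).  The linear fit is ordinary
least squares on the raw pairs inside the smallest symmetric interval
about zero containing ≥ 68.27% of points (binned profile statistics are
display-only; default bin width 0.05 μm).  Model autocorrelations,
the exact transition density and time-averaged MSD are provided alongside
(position AC e^(−t/τ); velocity AC negative at lag δt — the elastic
signature).  The empirical autocorrelation is the mean-subtracted,
lag-0-normalised (biased) estimator, which tapers by (n−k)/n at lag k.

**Phase-space descriptors.**  With trajectory mean x̄ (absolute nucleoid
coordinate), sd s and position series x:
φ = 1 − 2·|frac(n·x̄/L) − 0.5| (1 at the n-plasmid home positions, 0 at
poles and midpoints); ψ = s·n·√12/L (sd relative to a uniform sweep of the
plasmid's L/n territory; clamped at 1 for scoring); χ = the highest
positive local maximum after the first negative local minimum of the
position autocorrelation over lags 1..len/2 (0 if either is absent; local
extrema by sign changes of first differences).  Scores: regular (1−ψ)φ,
static (1−ψ)(1−φ), oscillation χ; display colour is the score-weighted
blend of amber/blue/pink, black when all ≈ 0.  The categorical call is a
decision cascade mirroring the phase-diagram legend: confined (ψ ≤ 0.6) →
regular if φ ≥ 0.5 else static; otherwise oscillation if χ ≥ 0.15 else
diffusive.  The cascade is used because on 35-min tracks the score noise
floors of weak oscillation and sub-sampled diffusion overlap, making a
score-argmax unreliable; the thresholds are package constants, exposed in
`parahop.regimes`.  Phase grids realise λ through Dh and ε through kh with
everything else fixed; optional smoothing (3×3 morphological opening then
a Gaussian of 1 cell) is display-only and never applied before numeric
checks.

**Segment classification.**  A window (default 12 points) slides along the
track; the lag-1 autocorrelation of the within-window velocities
(mean-subtracted, variance-normalised) labels the window's centre point
oscillatory if positive, regular otherwise; runs of ≥ 6 identical labels
form segments and shorter runs become undetermined.  At the fitted
timescales (τ ≈ 2 min, δt = 1 min) the expected lag-1 velocity
autocorrelation of spring-like motion is only ≈ −0.2 while an 11-velocity
window estimates it with sd ≈ 0.3, so genuinely spring-like tracks carry
~15–20% oscillatory-labelled timepoints.  This false-positive floor is
intrinsic to the small window (larger windows would miss short segments);
population fractions computed from these labels inherit a corresponding
positive bias, and per-track majority votes separate spring-like from
oscillatory tracks far more reliably (≥ 97% on synthetic ground truth)
than individual labels do.

## Synthetic ground truth

Three seeded generators cover the analysis paths: an **OU** track using the
exact discrete transition (x₀ from the stationary Gaussian, variance Dτ) so
estimator tests carry no discretisation confound; a **pure-diffusion** walk
(Gaussian steps, specular reflection at ±L/2); and a **triangle wave**
(amplitude, period, mean) with additive Gaussian noise, mimicking the
oscillatory regime's sweeps.  Defaults mirror the experimental scales:
δt = 60 s, D = 2.27×10⁻⁴ μm²/s, τ = 120 s, amplitudes below the cell
half-length.  What the generators deliberately lack: localisation error on
top of OU tracks, cell growth, variable track lengths, and the
heavy-tailed excursions of real trajectories — so passing recovery tests
validates the estimators' correctness, not their robustness to those
artefacts.

## Measurement protocol and problem sizes

Quantitative checks at the fitted point use ensembles of 35-min productions
(10 min burn-in, 1 min sampling) — the cadence of the underlying tracking
experiments.  Two protocol facts matter when comparing numbers:

* the pooled sd about per-trajectory means on 36-sample tracks
  under-measures the stationary spread by ~5% (correlated samples), and the
  velocity-profile τ through the same protocol is biased low by ~12% even
  for an exact OU with τ = 2 min (measured with `gen_ou`);
* τ estimates from 20-run ensembles scatter with sd ≈ 0.4 min, so the
  acceptance script and the test suite use 40-run ensembles.

At the fitted point the simulator yields pooled sd ≈ 0.155–0.160 μm
(stationary sd ≈ 0.17 μm) and ensemble τ ≈ 1.8–2.1 min, with
D ≈ 2×10⁻⁴ μm²/s.  The λn-threshold probe and regime examples run at full
nA = 500 (reduced dimer counts leave the regimes intact down to nA ≈ 50
for one plasmid, but the two-plasmid probe needs the full complement for a
stable ψ); scaling down is done through run counts and durations instead.
The burn-in default is 600 s ≈ 6/kd.

## Known limitations

2D geometry with a fixed nucleoid per run (no growth); no explicit ParB
molecules, CTP mechanics or ParA-ADP intermediate; no force-dependent bond
breakage or tether-length limit; reflecting boundaries are a modelling
choice where the physical boundary condition is unspecified.  Whether
tethered dimers retain independent elastic fluctuation is not observable
in the data the model targets; they are frozen relative to their plasmid
here.  The sliding-window classifier's false-positive floor (above) is a
property of the published window size, not of this implementation.
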