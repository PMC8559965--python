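# Methods

## Model structure and assumptions

The package couples a feed-forward intracellular cascade to a tumor
population under two drugs.  IL-6 (*L*) activates NF-κB (*F*), which
induces the anti-apoptotic Bcl-2 (*B*); Bcl-2 represses the pro-apoptotic
BAX (*X*) through a Hill-type fractional inhibition term, and trastuzumab
(TZB, *T*) represses the autocatalytic Bcl-2 supply the same way (quadratic
inhibition, `k₅k₄²/(k₄²+δT²)`).  Apoptotic killing of tumor cells is
gated by a hard indicator: it is active only while Bcl-2 is below and BAX
above a common threshold (th_B = th_X = 8), i.e. while the state sits in
the apoptotic (Ta) corner of the (X, B) plane.  The inequalities are
strict, and the plane deliberately has a third "neither" region (large or
small in both coordinates) where killing is also off; boundaries belong to
no region.  Killing strength scales as `μ_C α/B`, so residual Bcl-2
attenuates it; since `dB/dt ≥ λ_B > 0` and B(0) = 5, B stays positive along
trajectories, and the `α/B` term additionally carries a defensive 1e-12
floor that is never reached in practice.

Cancer stem cells (*S*) are produced at rate `βT` only inside a fixed
activation window (days 20–25 of therapy), modelling delayed CSC
enrichment under sustained TZB; S never decays.  CSCs secrete IL-6 through
`k₃S/(k₁+k₂A)`, the only point where atorvastatin (ATV, *A*) enters the
model.  Tumor cells follow logistic growth with CSC seeding `λ₁S`.

Drugs are either *clamped* (held at a constant level, the four study arms)
or *infused*: rectangular windows of rate I and duration h feeding a
single-exponential clearance.  Eq-level assumptions kept deliberately
simple: no pharmacokinetic compartments beyond that clearance, no spatial
structure, no stochastic dynamics.

## The nondimensional working parameter set

All published simulation magnitudes (doses T ∈ [0,6], A ∈ [0,40],
thresholds at 8, IL-6 of order 10–60) are expressed in a nondimensional
system whose scale constants are not published; the dimensional literature
values are therefore carried only as metadata
(`table_dimensional_parameters`, bridged by the generic `convert_units`
scale algebra), and the working set was reconstructed by calibration
against the printed anchor values, **before** any test of this package was
run:

* IL-6 equilibria `L*(S=1, A=0) = 60` and `L*(S=1, A=5) = 18`, and the
  30-day four-arm reductions 46 % (ATV vs control) and 69 % (combination vs
  TZB-alone), pin `λ_L, k₃, k₂, β` exactly (four equations, four
  unknowns, using `L* = (λ_L + k₃S/(k₁+k₂A))/μ_L` and the linearity of the
  IL-6 equation).  With μ_L = 0.0815 h⁻¹ this gives λ_L = 0.8504,
  k₃ = 4.0396, k₂ = 1.1103, β = 5.609e-3.
* The apoptotic crossing doses of the equilibrium dose–response — T = 0.25
  at (S = 0.25, A = 5) and T = 0.4 at (S = 1, A = 5) — pin `λ_B` and `k₅`
  once `λ₂, λ₃, δ` are chosen.  λ₂ = 0.05 and λ₃ = 0.025 set the NF-κB
  scale (F* ≈ 10 at L = 60, ≈ 3 at L = 18); δ = 10 makes the two crossing
  equations consistent with the high-dose behaviour (at T = 4 the CSC-driven
  IL-6 rise pushes Bcl-2 back above threshold, producing the bell-shaped
  anti-tumor efficacy).  This yields λ_B = 0.16028, k₅ = 0.10245.
* The BAX branch (λ_X = 0.006, k₇ = 0.3136, γ = 0.015, μ_X = 0.02) is set
  so that `X*(B = 8) = 8.3`: the BAX condition flips just before the Bcl-2
  condition, the crossing dose is governed by B* = 8, and BAX spans a
  plot-friendly 0.3–16 range.
* Intracellular decay rates keep their per-hour literature values
  (μ_F = 0.3, μ_B = 0.0347, μ_X = 0.02, μ_L = 0.0815, μ_T = 0.005,
  μ_A = 0.0495); time is hours in both unit systems, and all day-valued
  settings (CSC window, slot days, periods) convert at the boundary.
* Tumor kinetics (r = 0.007 h⁻¹, λ₁ = 1e-4, μ_C = 0.05, α = 2, K = 1)
  are set so the untreated tumor fills its capacity gradually across the
  40-day horizon and Ta-status killing depletes it over days rather than
  hours, matching the published trajectory shapes.  This is the one place
  the per-hour literature rates do not transfer: with r = 0.07 h⁻¹ every
  arm saturates to K within days, after which CSC seeding would leave the
  TZB-alone arm *above* control at the horizon, inverting the published
  strategy ordering.

Initial condition for every study run: (L,F,B,X,S,C) = (0,0,5,0,0.25,0.01),
with clamped drugs at their arm levels and infused drugs at zero.

## Numerical integration

The right-hand side is discontinuous at infusion-window edges, the CSC
window endpoints, and apoptosis-threshold crossings.  `simulate` splits the
horizon at the first two (exact, known a priori) and locates the third by
root-finding on `B − th_B` and `X − th_X` (scipy event detection,
terminal events with a 1e-6 h restart nudge off the switching surface), so
the kill term switches at crossing times rather than at solver step
boundaries.  Defaults: LSODA, rtol 1e-8, atol 1e-10, 1-hour output grid
via dense interpolation.  A `switching="naive"` mode (indicator evaluated
per right-hand-side call, no threshold events) is provided as a
cross-check; the suite verifies both modes agree.  Integration is fully
deterministic; all randomness in the package lives in the sampling and
synthetic-data modules and is driven by explicit seeds.

Apoptosis persistence is the Lebesgue measure of {t : I_apop = 1} computed
from the event-resolved segment trace, hence exact up to crossing-location
tolerance.

## Efficacy scores

`E_T = f_T/C(t)` and `E_c = f_c/L(t)` with `E_total = ω₁E_T + ω₂E_c`
(defaults ω₁ = ω₂ = 0.5).  The scale factors are not intrinsic: by
convention `f_T` is taken as the untreated C at the evaluation time (so the
control arm scores E_T = 1) and `f_c` as the combination-arm IL-6 at zero
TZB; both are explicit arguments, never implicit normalizations.
Evaluation times: 30 days for dose–response comparisons, 40 days for
schedule experiments.

## Sensitivity analysis

Latin hypercube sampling (scipy's stratified `LatinHypercube`) over the
eight parameters without direct experimental support (λ₂, δ, γ, r, λ₁,
μ_C, k₂, k₃).  Ranges are baseline × [0.5, 1.5]; the published analysis
does not state them, and the reported result — the sign pattern — is
robust to the width.  Each sample is simulated under the combination arm
(T = 1, A = 5 clamped; the protocol is likewise unstated, and the
combination arm exercises every sampled parameter) and read out at 24, 480
and 960 h.  PRCC: rank-transform all columns (average ranks on ties),
regress the parameter and output ranks on the ranks of the remaining
parameters, and correlate the residuals.  Default ensemble size 10,000;
the test suite uses 1,000, at which the full sign pattern is already
stable.

## Synthetic data and parameter recovery

`generate_observations` simulates the four arms and perturbs the sampled
readouts (IL-6, Bcl-2, tumor density by default; 8 time points over 30
days, 3 replicates) with multiplicative lognormal noise
`exp(N(0, σ))`, `σ = sqrt(log(1+cv²))`, so the replicate CV equals the
requested level and observations stay positive — matching ratio-scaled
assay readouts rather than additive instrument noise.  What the generator
does *not* emulate: biological between-subject variability, measurement
drift, limits of detection, or model misspecification; recovery tests
therefore demonstrate estimator correctness under the model, not robustness
on real data.

`fit_parameters` minimizes the summed squared log-residuals by bounded
trust-region least squares in **log-parameter space** (scale-free across
parameters spanning three orders of magnitude), from Latin-hypercube
multi-starts, deterministic given seeds.  The canonical recovery experiment
frees (λ₂, k₂, δ) because each dominates a distinct arm contrast.
Identifiability caveat: the clamped doses nearly saturate the k₂ and δ
inhibition terms, so those two carry ~5–10 % posterior spread at 5 % noise
(1σ ≈ 8 % for δ); individual noise realizations can exceed 10 % relative
error for δ.  Identifiability is not analyzed formally.

## Schedule experiments

The alternating-therapy scheme assigns six injection slots (days 0, 7, …,
35; spacing configurable) to three TZB and three ATV infusions; all
C(6,3) = 20 codes are enumerated and ranked by final-time values (not time
averages) at 40 days.  Infusion durations h_A = h_T = 1 day are a design
choice (the windows are only defined abstractly in the source material);
overlapping windows are rejected at construction.  In the periodic-ATV
grid scan, TZB is clamped at its basal level 1.0, τ_A = 0 denotes
continuous infusion, and the qualitative cost/safety/CRCC zones are
quantile cuts over the scanned grid (top-quartile dose → high-cost,
top-quartile final IL-6 → CRCC-risk, remaining bottom-quartile tumor →
safe), since no numeric zone boundaries are published.

Known limitation: with the CSC window fixed at days 20–25, the final IL-6
ranking of alternating schedules is governed by the TZB exposure integrated
over that window, so schedules injecting TZB at day 21 maximize IL-6.  The
package reports whatever ranking the model produces rather than any
externally asserted ordering; see the test suite for which published
endpoints this reproduces.

## Problem sizes

Default test and example workloads are desk-scale by construction: a
40-day run integrates in well under a second, the 20-schedule sweep in a
few seconds, and a 1,000-sample PRCC ensemble in under a minute; the
acceptance script's quantities are all deterministic and complete in
seconds.
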