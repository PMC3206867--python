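# Methods

## Model and assumptions

The package treats plasma insulin as a single well-mixed pool with a
source proportional to beta cell mass and a first-order clearance sink.
Only the fasting steady state of that balance is ever used: every derived
quantity (minimum required mass `BCM_min = α·W`, excess mass fraction
`EBCM = 1 − α·W/BCM`, fasting insulin `C_I = q_max·ρ·BCM/(k_clr·W)`)
follows from setting the transient to zero. The transient right-hand side
is still exposed (`PhysiologyModel.insulin_balance_rhs`) for completeness,
but it is never integrated — no downstream quantity needs it.

Assumptions worth stating explicitly:

- **Lumped identifiability.** Of the mechanistic constants, only the
  combination `α = k_clr·C_I,fast/(ρ·q_max)` is identifiable from EBCM
  data; `q_max`, `k_clr`, `ρ`, `γ` default to 1 and exist so that
  concentrations can be put into physical units when they are known.
- **C-peptide proportionality.** Plasma C-peptide is `γ × C_I` with `γ`
  independent of disease state, so study-level C-peptide means can stand
  in for endogenous insulin production.
- **EBCM as an islet fraction.** Predicted EBCM is *not* clamped — a
  negative value means demand exceeds total mass and is meaningful.
  Observed EBCM (fraction of insulin-deficient islets) is a proportion
  and is validated/clamped to [0, 1] at ingestion.
- **Steady state only.** Glucose dynamics, secretion pulsatility and
  functional compensation are out of scope; the model is a mass balance.

## Age curves

`W(a)` and `BCM(a)` are natural cubic splines (zero second derivative at
both ends) through sparse knot tables; natural boundaries are the
conventional choice for sparse biological trend data, and interpolation —
not smoothing — is used throughout. Outside the knot range curves clamp to
the boundary value, avoiding cubic blow-up beyond the last growth-chart
age (~20–25 y). The total-mass curve is the product of the density and
volume splines, materialized by resampling the pointwise product on a
200-point uniform grid and refitting, so downstream code handles a single
curve type; with 200 points the re-splined product stays within 0.5% of
the exact product (asserted in tests). Weight-for-age is the pointwise
average of male and female tables, resampled to the union grid when the
grids differ.

Canonical units: age in decimal years, weight in kg, time since diagnosis
in months (inputs in weeks convert at 4.345 weeks/month). BCM-units are
deliberately abstract — only the ratio `α·W/BCM` matters, and all outputs
are invariant under a joint rescaling of `α` and the BCM curve (tested).

### Packaged fixture tables

The real density/volume tables behind the original analysis were never
published in machine-readable form, so the packaged knot tables
(`ebcm/data/*.csv`) are synthetic stand-ins constructed to match the two
quantitative anchors the analysis rests on: with `α = 499` BCM-units/kg,
EBCM ≈ 0.85 in infancy and exactly `1 − 499/829 = 0.398` at age 20 (the
ratio `BCM/W` falls quadratically from 3330 to 829 units/kg between ages
0.5 and 20). Weight tables are chart-style 50th-percentile values;
pancreas volume rises to ~70 cm³ by adulthood; density is derived as
`ratio × W / volume`. Conclusions about the *real* cohorts cannot be read
off these tables — they exist so the pipeline's arithmetic is exercised at
physiologic magnitudes.

## Demand-parameter fit

With `x_i = W(a_i)/BCM(a_i)` and `y_i = 1 − EBCM_obs,i`, the model is
linear through the origin in α, so the default `wls` fit is closed-form
(`α̂ = Σx_iy_i / Σx_i²`) with a t-based 95% interval from the profile
curvature (n − 1 df). Records enter the fit only if they are recent-onset
(≤ 0.75 months = three weeks at the 28-day convention, configurable) and
under age 20, matching the cohort the parameter is defined on. Records are
unweighted by islet counts (the historical convention is unstated;
unweighted is the default). Observed fractions of exactly 0 or 1 are
retained — the likelihood is Gaussian, not binomial, so no continuity
correction applies. An `mcmc` alternative (flat positive prior, profiled
variance, 3 chains of the same adaptive Metropolis engine) reports the
posterior median and central 95% interval; the two agree within the CI
width on well-conditioned data (tested).

Identifiability guard: at least 3 records spanning at least 2 distinct
ages are required; a single-age cohort is rejected even though a
through-the-origin fit is formally computable, because the age-dependence
is the quantity of interest.

## Residual smoothing and pairing

Residuals `ΔEBCM = EBCM_pred(age) − EBCM_obs` are ordered by time since
diagnosis (ties broken by patient id for determinism) and smoothed with a
nine-**point** (record-index, not fixed-width) centered moving average and
moving sample SD (ddof = 1). Only full windows are formed — `n − 9 + 1`
windows for `n` records, each stamped with the time of its middle record —
because edge-shrunk windows would bias the ends of the trajectory.
C-peptide timepoints are matched by linear interpolation between window
centers (nearest-neighbour available as an option); timepoints outside the
center span are excluded with a logged warning rather than extrapolated.
The smoothed-x uncertainty is carried into the paired observations but not
modelled (no errors-in-variables), matching the original procedure.

## Weighted Bayesian regression

- **Likelihood.** Gaussian, per-point variance `σ²/w_i` with normalized
  sample-size weights `w_i = n_i/Σn`; `σ²` is profiled at its conditional
  maximum on every evaluation (empirical-Bayes plug-in), floored at 1e-12
  so exactly collinear data stays finite. Reported y-standard errors are
  carried through outputs; `use_se=True` switches the variances to
  `SE_i²` instead. Raw-vs-normalized weights are equivalent up to the
  profiled scale, so normalization is a convention, not a choice that
  affects inference.
- **Prior.** Flat improper on (slope, intercept). The Gaussian
  distribution associated with the sampler is the random-walk *proposal*,
  not a prior.
- **Proposal adaptation.** Component scales start at the WLS standard
  errors; a global scale factor moves by `exp(gain·(acc − 0.4))` per
  500-step batch with decaying gain and freezes after two consecutive
  batches within ±0.03 of the 0.4 target (or a 30 000-step budget).
  Across seeded test problems the frozen long-run acceptance stays inside
  [0.35, 0.45].
- **Initialization and convergence.** Three chains start at the WLS
  solution offset by (−1, 0, +1) × 4 SE. PSRF
  `sqrt(((n−1)/n·W + B/n)/W)` is computed per parameter on the second
  half of doubling windows (1000, 2000, …); burn-in ends at the first
  window with both PSRFs < 1.1 (the conventional cutoff; per-parameter
  with a both-below rule). 100 000 fresh post-convergence steps per chain
  are then pooled. If the threshold is never met within a 200 000-step
  budget a `ConvergenceError` carries the diagnostics.
- **Outputs.** `P(slope>0)` = pooled fraction of positive slope samples,
  significant above 0.95; slope–intercept posterior correlation (negative
  for x̄ > 0, as in the uncentered design); acceptance fractions and PSRF
  per chain. Under this likelihood and prior the slope marginal is exactly
  Student-t (n − 2 df, WLS center and scale); the test suite holds the
  sampler to that closed form within Monte-Carlo error and checks
  null-slope calibration (≤ 10% of 50 replicates exceed 0.95).
- **Determinism.** One master seed; chain seeds are fixed offsets from
  it; identical seeds give bit-identical results (tested).

## Synthetic data generator

The generator emulates the *declared structure* of the historical data,
not its unpublished joint distribution:

- 102 autopsy records, ages uniform on 0.5–25 y (the true age
  distribution is unpublished; uniform is a declared stand-in), death
  times 0–117 months, with exactly 60 records quota-forced into the
  (age < 20, ≤ 3 weeks) cell and the rest drawn beyond the window so the
  filter count is exact.
- Observed EBCM = clamp₀₁(EBCM_pred(age) − r(t) + ε), ε ~ N(0, 0.08).
- Recovery kernel `r(t) = A·s·e^{1−s} − d·max(0, t − t_peak)` with
  `s = max(0, t−t₀)/(t_peak−t₀)`: zero through the recent-onset window
  (t₀ = 0.75 months) — so the α fit is unbiased by construction, which is
  exactly the property the recent-onset restriction is meant to buy —
  rising to a unique maximum A at t_peak = 2.3 months (~10 weeks), then
  declining linearly. Defaults A = 0.1 ("slight rise") and d = 0.003/month
  (≈ −0.35 over the 117-month span) were fixed once as physiologically
  plausible magnitudes for a subtle post-onset recovery.
- Three C-peptide studies with N = 769 (24-month follow-up, random
  sampling, 732 AA+/37 AA− metadata), 24 and 41 (12-month, fasting).
  Study means are `γ·set_point·max(0, 1 − baseline_deficit + r(t))` plus
  one N(0, sd/√n) draw; reported SE = sd/√n. Defaults γ = 8×10⁻⁴ nmol/L
  per set-point unit and baseline_deficit = 0.5 put means near 0.2–0.25
  nmol/L with SEs of 0.02–0.10 nmol/L, the scale such studies report.
  Autoantibody strata are labels only — no stratum-specific biology is
  emulated.

What passing tests therefore show: the estimators recover known truths
under the declared noise at the declared sample sizes, and the sampler's
probabilities are calibrated. What they cannot show: anything about the
real cohorts' values — in particular the printed α interval (458–605) and
the real-cohort trajectory figures depend on the original digitized
tables and are replaced here by property checks (algebraic identities,
closed-form oracles, calibration), not by numeric reproduction.

## Problem sizes and numerical choices

Defaults run the full protocol (3 × 100 000 post-convergence steps) in
seconds thanks to an O(1)-per-step moment-based likelihood. Simulation
studies in the test suite use deliberately reduced designs chosen as
adequate for their assertions: coverage over 30 replicates per α ∈ {300,
499, 700}, bias monotonicity over 40 replicates per noise level, and
null calibration over 50 replicates with 10 000-step chains. Tolerances:
knot interpolation 1e-9 relative; product-curve 0.5%; sampler-vs-t-oracle
0.02 on probabilities; posterior means within 3 Monte-Carlo SEs
(chain-mean spread) of WLS.

Degenerate inputs are rejected loudly rather than repaired: fewer than 3
knots, duplicate ages, non-overlapping curve domains, single-age fit
cohorts, sub-window residual series, zero within-chain variance in the
PSRF, non-finite likelihood at a chain start.

## Known limitations

- The fixture curves are stand-ins; α-scale conclusions transfer to real
  data only after substituting real knot tables.
- Moving-average windows over record index make the effective time
  resolution depend on the death-time distribution (dense near onset,
  sparse late), as in the original procedure.
- Measurement error in smoothed ΔEBCM (x_sd) is reported but not
  modelled; a formal errors-in-variables treatment would widen the slope
  posterior.
- Random (non-fasting) C-peptide means from the largest study enter
  unadjusted alongside fasting means.
- The empirical-Bayes plug-in variance slightly understates posterior
  spread relative to a full variance prior (the t-oracle equivalence in
  the tests quantifies the sampler, not this modelling choice).
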