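# ebcm — age-corrected excess beta cell mass and plasma C-peptide

`ebcm` implements a physiology-based inference pipeline for type 1
diabetes: how much beta cell mass can a person of a given age lose before
hyperglycemia appears, and does the departure from that age-expected loss
after diagnosis track plasma C-peptide?

It is aimed at quantitative diabetes researchers and biostatisticians who
want the full chain — growth-curve construction, demand-parameter fitting,
residual smoothing and weighted Bayesian regression — as reusable,
seedable, testable components.

## The model

Plasma insulin is a balance between secretion (proportional to beta cell
mass, maximum per-mass rate `q_max`) and clearance (rate constant `k_clr`,
distribution volume `W/ρ` for body weight `W` and body density `ρ`):

    dN/dt = q_max·BCM − k_clr·C_I·W/ρ,    C_I = N·ρ/W

At the fasting steady state the beta cell mass just sufficient for
euglycemia is proportional to body weight,

    BCM_min(a) = α·W(a),      α = k_clr·C_I,fast / (ρ·q_max)

and the **normalized excess beta cell mass**

    EBCM(a) = 1 − α·W(a) / BCM(a)

is the fraction of an age-matched person's beta cells that can be lost
before onset — histologically, the tolerable fraction of insulin-deficient
islets. `W(a)` is a natural cubic spline through averaged male/female
growth-chart knots; `BCM(a)` is the product of splines through beta cell
density and pancreas volume knots. Because weight keeps rising through age
20 while beta cell mass plateaus, EBCM falls from ≈0.85 in infancy to
≈0.40 at age 20: onset requires far less destruction in adolescents than
the classic fixed "80–95% destroyed" threshold implies.

`α` is fitted by least squares to recent-onset autopsy records (death
within three weeks of diagnosis, age < 20). For the whole cohort the
residual `ΔEBCM = EBCM_pred(age) − EBCM_obs` is smoothed with a nine-point
moving average over time since diagnosis and paired with study-level
C-peptide means at the same times. A sample-size-weighted Bayesian linear
regression of C-peptide on smoothed ΔEBCM — Gaussian likelihood with
variance `σ²/w_i` (`w_i ∝ study N`, `σ²` profiled empirical-Bayes style),
flat prior, three adaptive random-walk Metropolis chains tuned to 0.4
acceptance, Gelman–Rubin convergence, ≥100 000 post-convergence steps per
chain — yields the headline statistic `P(slope > 0)`.

The historical autopsy and C-peptide datasets are not redistributable, so
a first-class synthetic module generates cohorts with the declared
structure (102 records, 60 recent-onset under age 20, studies of
N = 769/24/41) and a rise-then-decline post-onset recovery trajectory.

## Worked example

```python
from ebcm import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(outdir="demo-out", seed=42))
print(report["alpha_hat"], report["alpha_ci95"])
print(report["p_slope_positive"], report["significant"])
```

With seed 42 this simulates the default cohort, fits the demand parameter,
smooths and pairs the residuals (17 paired timepoints), and runs the full
MCMC:

```
508.56572365188254 [480.19329708964983, 536.9381502141152]
0.9946833333333334 True
```

Read: the fitted demand parameter is 508.6 BCM-units/kg (95% CI 480–537;
the generator's true value is 499, i.e. recovery within 2%), and the
posterior probability that C-peptide rises with the age-corrected mass
residual is 0.995 — a significant positive correlation at the 0.95 bar,
consistent with C-peptide acting as a surrogate for beta cell mass. All
artifacts (`autopsy.csv`, `residuals.csv`, `pairs.csv`, `posterior.json`,
`report.json`) land in `demo-out/`, each stamped with the seed and package
version.

The same chain is available from the shell:

```sh
ebcm simulate --seed 42 --out-autopsy autopsy.csv --out-cpeptide cpep.csv
ebcm fit-alpha --autopsy autopsy.csv
ebcm residuals --autopsy autopsy.csv --out residuals.csv
ebcm pair --residuals residuals.csv --cpeptide cpep.csv --out pairs.csv
ebcm regress --pairs pairs.csv --seed 42 --out posterior.json --plots
# or everything at once:
ebcm run --seed 42 --out demo-out
```

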