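# Methods

## Data and units

The unit of analysis is a treatment arm's longitudinal series of BTB
fractions (women with breakthrough bleeding per cycle, internally always a
fraction in [0, 1]; percent appears only at I/O boundaries). Time is stored
as months since the **first** observation (x = 0), which corresponds to
completion of one full 21/7 cycle; "treatment month m" therefore maps to
x = m − 1, and times-to-baseline are reported as months since initiation,
x* + 1. One month is treated as one 28-day cycle. This convention is an
inference from how the first observation is anchored, not something the
source trials state uniformly; it reproduces the reference simulation
medians and is used consistently everywhere (simulation, diagnostics,
reporting).

Observations from cycles with fewer than 100 subjects and observed BTB
below 1% cannot distinguish drug effect from the natural unscheduled-
bleeding background (1.68%, measured pre-treatment in large cohorts) and
are replaced by half that baseline (0.84%), flagged. The subject count used
for the rule is the per-observation count when available, else the arm
size; which count the original workflow used is not documented, so the
fallback is a package choice.

## Structural and statistical model

BTB(x) = A·e^(−αx) + B·e^(−βx), all four macro-constants positive.
Study-level random effects act multiplicatively, θ_i = θ_pop·e^η, η ~
N(0, Ω); arms within a study share η but differ in covariates. Covariates
are power functions on ratios: EE dose (reference 30 μg) on B, molar
progestin dose (reference 0.48 μmol ≈ 150 μg levonorgestrel) on α. Molar
doses use standard molecular weights (LNG 312.45, DSG 310.48, GSD 310.43,
DRSP 366.49 g/mol); that the progestin-amount normaliser 0.48 is in μmol is
an inference (it equals 150 μg LNG), and the MW table is configurable.
Residual error is additive with variance σ²/N_ik (N_ik = arm size), i.e.
arm-level fractions behave like means of N subject-level outcomes.

Ω is diagonal by default. Covariances among the inter-study variances were
estimated in the original analysis but never reported, so the shipped,
reproducible configuration is the diagonal one; `simulate_product` accepts
a full 4×4 matrix for sensitivity analyses.

## Estimation

The marginal likelihood integrates η out per study. We use the Laplace
approximation: for each study a damped Newton iteration (analytic gradient
and Hessian, batched across studies; saddle-free |eigenvalue| steps with a
5-log-unit step cap and backtracking line search) finds the mode of the
joint −2 log-likelihood from η = 0; the mode value plus log det(H/2)
− q·log 2π gives the study's contribution. Starting every inner solve from
zero makes the objective a deterministic function of the outer parameters —
a history-dependent warm start produced inconsistent re-evaluations and
derailed the outer optimiser. Inner tolerance is 1e−7 on the gradient
norm; indefinite Hessians at a numerical mode (flat random-effect
directions in small studies) are ridged to positive definite before the
determinant.

The outer problem optimises log fixed effects, covariate exponents,
log ISV variances and log σ² by L-BFGS-B with finite-difference gradients
under box bounds that encode scale knowledge (intercepts are fractions
< 1; rates < 20/month; ISV variances < 5.5; σ² < 1 — without these bounds
the optimiser can reach a degenerate basin where enormous ISVs emulate
per-study free parameters). Multistart: the first start comes from the
method of residuals (each arm with ≥ 4 points is curve-stripped — terminal
third log-linear for B, β, then peeled residuals for A, α, with one
refinement pass; medians across arms, floored at half-baseline and with
the slow rate capped at min(0.2, α/4) to avoid the label-swapped
fast/slow basin); the second start is a generic two-phase shape scaled to
the data ceiling; further restarts perturb these (seeded). Best OFV wins.
This multistart was needed in practice: single-start fits occasionally
converged to a phase-swapped local optimum with a markedly worse OFV.

FOCEI (the estimation method of the original analysis) is approximated
here by Laplace; exact NONMEM OFV parity is a non-goal. The approximation
is quantified, not assumed: an adaptive Gauss–Hermite routine (33 nodes
per active dimension, feasible for ≤ 3 active effects) provides the oracle
— tests require agreement within 1 OFV unit on small instances — and on a
linear-in-η Gaussian model, where Laplace is exact, the generic per-study
path matches the closed-form marginal to 1e−6.

Uncertainty comes from a nonparametric bootstrap that resamples **studies**
with replacement (all arms of a study move together), refitting each
replicate from the base optimum; non-converging replicates are excluded
and counted.

## Covariate workflow

Screening: Pearson correlation on study-level covariates — for any pair
with |r| > 0.6 (strictly) the member with more missingness is dropped
(ties: later in input order); one-way ANOVA tests continuous covariates
across categorical ones at p < 0.05. Stepwise covariate modeling uses the
likelihood-ratio test with forward p < 0.01 (ΔOFV ≥ 6.635 at 1 df) and
backward p < 0.001 (ΔOFV ≥ 10.828); every tested step is logged. Candidate
fits start from the current optimum with a zero exponent appended. When a
candidate's apparent ΔOFV clears the forward threshold, the nested model is
re-fitted from the candidate's own basin before the drop is believed: a
large "effect" can otherwise be an artifact of a poorly converged base
fit. Without this guard the null false-selection rate was visibly inflated;
with it, 100 null datasets yield ≥ 95% empty final models at the stated
thresholds.

The shipped final-model configuration hard-codes molar progestin dose on α
alongside EE dose on B. On data generated without a progestin effect the
SCM engine itself would not (and should not) select that term; it is
retained in the default configuration as a deliberate scientific choice
about the progestin/EE interplay, mirroring the original analysis. BMI is
a selectable candidate but excluded from the shipped configuration (the
observed BMI range is too narrow to support it).

Missing covariates: imputation by individual parameter (IIP) regresses
ln(cov) = k₀ + k₁·θ_i on complete cases, θ_i the empirical-Bayes individual
parameter on the **log** scale (log typical averaged over the study's arms
plus η̂; the log scale is chosen for consistency with the regression's
linearity). The parameter is the one with the most significant
complete-case association. Median imputation is the comparator; multiple
imputation by chained equations is out of scope (the comparison harness
accepts any externally completed dataset instead).

## Synthetic data

The generator is the fitted model read forwards, with defaults that mirror
the published trial overview: 25 studies carrying 33 arms across ten
progestin/EE combinations weighted by their trial counts (DSG 150/20×3,
150/30×4; DRSP 3000/20×1, 3000/30×5; GSD 60/15×3, 75/20×1, 75/30×4,
75/35×1; LNG 100/20×5, 150/30×6); monthly cycle-end schedules with the
per-product observation counts (3–26, median 6); arm sizes log-normal
around each product's published median subject count (94–5602, pooled
median ≈ 308; log-sd 0.35 for trial-to-trial spread); demographics around
the pooled means (age 26.4 y, weight 59.2 kg, height 162.8 cm, BMI
23.0 kg/m²) with height and BMI missing 40% of the time (they are the most
often unreported fields). Generating parameters default to the reference
estimates. Ground truth (η draws, per-arm parameters, truncation count) is
written to a JSON sidecar, never mixed into analysis inputs.

Simulated fractions are truncated at zero — a fraction of women cannot be
negative. At the reference parameters and realistic arm sizes about 4–6%
of observations are truncated, concentrated in late, low-level
observations where the Gaussian arm-level error is an imperfect stand-in
for a bounded count; the rate is counted and reported because the
truncation slightly inflates late-time levels and with them the B/β
estimates. What the generator deliberately does not emulate: subject-level
bleeding diaries, dropout, reporting-standard heterogeneity between
trials, and non-21/7 regimens — so passing recovery tests demonstrate
internal consistency of the method, not robustness to those real-data
features.

## Diagnostics

The VPC re-simulates the original design (same arms, covariates, arm
sizes, times; truncation at zero exactly as the generator) and compares
observed 10th/50th/90th percentiles per time bin with the 2.5–97.5%
envelope of those percentiles across replicates (default 1000). Bins are
the unique scheduled times; no smoothing. A stratified (per-product) VPC
is available since the pooling choice is a presentation decision.
Residuals: PRED (η = 0), IPRED (η = η̂), IWRES = (y − IPRED)/√(σ²/N), and
CWRES from a first-order expansion at the posterior mode, standardised by
(G Ω Gᵀ + Σ)^{1/2} per study — an approximation to NONMEM's CWRES; a
singular linearised covariance falls back to IWRES with a flag.

## Product simulations

For each approved product (DSG 150/20, 150/30; DRSP 3000/20, 3000/30;
GSD 60/15, 75/20, 75/30; LNG 100/20, 150/30) 1000 parameter sets are drawn
by applying log-normal random effects to the product's typical parameters
— population simulation, no residual error. BTB is summarised at months 1,
3, 4 (x = m − 1); time-to-baseline solves BTB(x) = 0.0168 per draw by
bisection on the analytic bracket [0, ln((A+B)/baseline)/min(α, β) + 1]
(the curve is strictly decreasing, so the root is unique) to 1e−6 months,
reported as x* + 1. The baseline is the 1.68% pre-treatment rate, not the
0.84% imputation value. Draws crossing only beyond a 600-month horizon are
censored there and counted (extreme η draws would otherwise produce
unbounded roots; at the reference parameters censoring is absent in
practice).

## Problem sizes and numerical choices in the test suite

The suite exercises the full pipeline at desk scale: parameter recovery
fits 200 synthetic studies once and twenty 25-study replicates; the null
stepwise-search simulation runs 100 repetitions at 25 studies with a
reduced optimizer budget (single start, capped function evaluations,
base fits initialised at the generating values — initialisation affects
cost, not the location of the optimum); the VPC calibration uses 1000
replicates. The known-tight check is 200-study parameter recovery at 10%
relative error for every fixed effect: scaling the reference fit's
reported relative standard errors (22–35% at 25 studies) by √8 puts the
sampling noise of several parameters at 8–12%, so this bound sits near
one standard error and individual datasets can genuinely miss it on one
parameter — a limitation of the design's information content, not of the
estimator.

## Known limitations

- Laplace, not FOCEI: OFV values are close to but not identical with
  NONMEM's; all thresholds (SCM, bootstrap) are used on self-consistent
  Laplace OFVs.
- The Gaussian arm-level error admits negative fractions; truncation at
  zero is a pragmatic repair whose small upward bias is documented above.
- Study-level aggregation: the model says nothing about within-arm
  heterogeneity; N_ik-weighting assumes exchangeable subjects.
- The ISV covariance structure of the original final model is unknown;
  all shipped configurations are diagonal.
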