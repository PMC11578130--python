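# cocbtb — dose–response modeling of breakthrough bleeding under combined oral contraceptives

Breakthrough bleeding (BTB) — unscheduled vaginal bleeding during active
pill use — is one of the main reasons women stop taking combined oral
contraceptives (COCs). BTB spikes after treatment initiation and subsides
over the following months, faster at higher ethinyl-estradiol (EE) doses.
`cocbtb` implements a model-based meta-analysis (MBMA) of arm-level BTB
time courses pooled across COC trials of four progestins (desogestrel DSG,
drospirenone DRSP, gestodene GSD, levonorgestrel LNG), and the Monte-Carlo
simulations that turn the fitted model into product-level statements: how
much BTB to expect in months 1–4, and how long until bleeding returns to
its pre-treatment baseline.

The package is aimed at pharmacometricians and reproductive-health
researchers who need a transparent, testable re-implementation of this
class of analysis: arm-level nonlinear mixed-effects estimation, covariate
search, predictive checks and product simulation — without NONMEM.

## The model

The fraction of women with BTB in study *i*, arm *k*, at time *x* months
after the first post-initiation observation declines bi-exponentially:

    BTB(x) = A·e^(−αx) + B·e^(−βx)

*A*, *α* describe the rapid initial decline; *B*, *β* the slow terminal
phase. Covariates enter as power models on a ratio to a reference value:

    log α_i = log α_pop + θ_prog · log(ProgestinAMT / 0.48 μmol) + η_α,i
    log B_i = log B_pop + θ_EE · log(EEdose / 30 μg) + η_B,i

with study random effects η ~ N(0, Ω) on all four parameters
(θ_i = θ_pop·e^η: log-normal inter-study variability, reported as
%CV = √(e^ω² − 1)). Observed arm fractions carry additive residual error
with variance σ²/N_ik, so large arms constrain the fit more tightly.
Estimation maximises the Laplace-approximate marginal likelihood (a batched
Newton solver finds each study's empirical-Bayes mode; an adaptive
Gauss–Hermite routine cross-checks the approximation). Low-information
observations — cycles with under 100 subjects reporting under 1% BTB — are
replaced by half the 1.68% pre-treatment unscheduled-bleeding baseline.

Because the underlying 25-study dataset is not public, the package ships a
first-class synthetic-data generator (`cocbtb.synthetic`) that emulates the
trial composition (25 studies, 33 arms, ten progestin/EE dose combinations,
per-product arm sizes and schedules, demographic missingness), so every
stage of the analysis is testable end to end.

## Worked example

```python
from cocbtb.products import simulate_registry
from cocbtb.reference import (BASELINE, final_model_fixed_effects,
                              final_model_isv_variances)

sims = simulate_registry(final_model_fixed_effects(),
                         final_model_isv_variances(),
                         n_draws=1000, seed=1, baseline=BASELINE)
for s in sims:
    print(f"{s.product.label:13s} month-1 median "
          f"{100 * s.stats[1.0]['median']:5.1f}%   "
          f"back to baseline in {s.median_time_to_baseline:5.1f} months")
```

prints

```
DSG 150/20    month-1 median   8.0%   back to baseline in  15.0 months
DSG 150/30    month-1 median   5.6%   back to baseline in   3.7 months
DRSP 3000/20  month-1 median   7.8%   back to baseline in  14.8 months
DRSP 3000/30  month-1 median   5.2%   back to baseline in   1.7 months
GSD 60/15     month-1 median  12.5%   back to baseline in  29.2 months
GSD 75/20     month-1 median   7.9%   back to baseline in  15.5 months
GSD 75/30     month-1 median   5.4%   back to baseline in   4.5 months
LNG 100/20    month-1 median   8.1%   back to baseline in  16.1 months
LNG 150/30    month-1 median   5.5%   back to baseline in   3.8 months
```

Each line is the median over 1000 population draws (log-normal random
effects around the product's typical parameters). The pattern carries the
clinical message: at 30 μg EE, bleeding settles within ~2–5 months for
every progestin, at 20 μg it takes over a year, and the 15 μg product is
slowest — the EE dose, not the progestin, dominates both the early BTB
burden and the recovery time. By month 4 the products at a matched EE dose
differ by under one percentage point.

The `analysis/` scripts run the full pipeline on synthetic data:
`01_generate_dataset.py` (data), `02_fit_model.py` (Laplace fit),
`03_covariate_analysis.py` (screening, stepwise search, imputation
comparison), `04_diagnostics.py` (bootstrap, VPC, residuals),
`05_simulate_products.py` (the tables above). Programmatic use goes
through `cocbtb.pipeline.run_pipeline`.

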