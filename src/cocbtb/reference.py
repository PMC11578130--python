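"""Reference constants and final-model estimates.

Molecular weights are standard chemistry constants (PubChem monoisotopic-free
average MWs of the free steroids).  The final-model estimates are the published
population estimates from the 25-trial meta-analysis of breakthrough bleeding
(BTB) under combined oral contraceptives; they parameterise the shipped
simulation defaults and serve as generating values for synthetic datasets.
"""

from __future__ import annotations

import numpy as np

from .datamodel import BaselineSpec
from .structural import FixedEffects, ReferenceConstants

#: Average molecular weights (g/mol) of the four progestins.
MOLECULAR_WEIGHTS: dict[str, float] = {
    "LNG": 312.45,   # levonorgestrel
    "DSG": 310.48,   # desogestrel
    "GSD": 310.43,   # gestodene
    "DRSP": 366.49,  # drospirenone
}

#: Covariate normalisers: 0.48 umol molar progestin dose (= 150 ug LNG) and
#: 30 ug ethinyl estradiol.
REFERENCE_CONSTANTS = ReferenceConstants(
    molar_ref_umol=0.48,
    ee_ref_ug=30.0,
    molecular_weights=dict(MOLECULAR_WEIGHTS),
)

#: Pre-treatment unscheduled-bleeding rate (1.68%) and the half-baseline value
#: used to impute low-information observations.
BASELINE = BaselineSpec(baseline_fraction=0.0168, imputation_fraction=0.0084)


def final_model_fixed_effects() -> FixedEffects:
    """Population fixed effects of the final bi-exponential BTB model."""
    return FixedEffects(
        A_pop=0.0383,
        alpha_pop=0.922,
        B_pop=0.0134,
        beta_pop=0.0524,
        theta_ee_on_B=-2.45,
        theta_prog_on_alpha=0.576,
    )


def final_model_isv_variances() -> np.ndarray:
    """Diagonal inter-study variances (log scale) for (A, alpha, B, beta).

    The meta-analysis also estimated covariances among the ISVs but their
    values were never reported, so the reproducible reference configuration
    is diagonal.
    """
    return np.array([0.824, 0.959, 0.223, 0.138])


#: Residual unexplained variance: unweighted additive variance sigma^2; the
#: variance at an observation is sigma^2 / N (N = arm size).
FINAL_MODEL_SIGMA2 = 0.0410

#: 95% bootstrap confidence intervals (1000 resamples) of the published fixed
#: effects, used as reference intervals in recovery checks.
FINAL_MODEL_BOOTSTRAP_CI: dict[str, tuple[float, float]] = {
    "A_pop": (0.026, 0.050),
    "alpha_pop": (0.032, 1.813),
    "B_pop": (0.006, 0.021),
    "beta_pop": (0.028, 0.077),
    "theta_ee_on_B": (-3.873, -1.028),
    "theta_prog_on_alpha": (-0.231, 1.383),
}


def molar_dose_umol(progestin: str, dose_ug: float) -> float:
    """Convert a progestin mass dose (ug) to a molar dose (umol)."""
    try:
        mw = MOLECULAR_WEIGHTS[progestin]
    except KeyError:
        raise ValueError(f"unknown progestin {progestin!r}") from None
    if dose_ug <= 0:
        raise ValueError("progestin dose must be positive")
    return dose_ug / mw
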