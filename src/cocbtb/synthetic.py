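"""Synthetic MBMA datasets with the statistical structure the analysis
assumes.

The generating process is exactly the fitted model read forwards: per study a
log-normal random effect on each macro-parameter, per arm a typical
bi-exponential profile driven by the product's EE dose and molar progestin
dose, and additive Gaussian residual noise whose variance shrinks with arm
size (sigma^2 / N).  Defaults mirror the composition of the 25-trial /
33-arm meta-analysis dataset: the same ten progestin/EE dose combinations
with their observed trial counts, a log-normal arm-size distribution with
median 308 subjects, monthly observation schedules with a median of 6
observations per arm, and study-level demographics with realistic
missingness (height and BMI are the most frequently unreported).

Negative simulated fractions are truncated at zero (a fraction of women
cannot be negative); the truncation count is reported because heavy
truncation would bias late low-EE observations upward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (Dataset, Observation, StudyArm, StudyDemographics)
from .structural import FixedEffects

__all__ = ["ArmTemplate", "GeneratorConfig", "generate_dataset",
           "inject_covariate_missingness", "write_ground_truth"]


@dataclass(frozen=True)
class ArmTemplate:
    """One progestin/EE dose combination with its weight (number of trials),
    per-arm observation count and median arm size in the emulated dataset."""

    progestin: str
    progestin_dose_ug: float
    ee_dose_ug: float
    n_trials: int
    n_obs: int
    median_n_subjects: int


#: Dose combinations of the meta-analysis dataset: (progestin, dose, EE,
#: number of trials, median observations per arm, median subjects per arm).
#: 33 arms in total; the pooled median arm size is ~308 subjects.
DEFAULT_ARM_TABLE: tuple[ArmTemplate, ...] = (
    ArmTemplate("DSG", 150, 20, 3, 12, 338),
    ArmTemplate("DSG", 150, 30, 4, 4, 327),
    ArmTemplate("DRSP", 3000, 20, 1, 26, 461),
    ArmTemplate("DRSP", 3000, 30, 5, 3, 203),
    ArmTemplate("GSD", 60, 15, 3, 6, 94),
    ArmTemplate("GSD", 75, 20, 1, 12, 740),
    ArmTemplate("GSD", 75, 30, 4, 6, 309),
    ArmTemplate("GSD", 75, 35, 1, 6, 5602),
    ArmTemplate("LNG", 100, 20, 5, 6, 380),
    ArmTemplate("LNG", 150, 30, 6, 4, 176),
)


def _default_fixed() -> FixedEffects:
    from .reference import final_model_fixed_effects
    return final_model_fixed_effects()


def _default_omega() -> np.ndarray:
    from .reference import final_model_isv_variances
    return final_model_isv_variances()


@dataclass
class GeneratorConfig:
    """Study conditions for dataset generation.

    Arm sizes are log-normal around each product's median subject count
    (``n_subjects_log_sd`` is the trial-to-trial spread on the log scale;
    the pooled median is ~308 subjects).  Demographics means/sds follow
    the pooled trial demographics (age ~26 y, weight ~59 kg, height ~163 cm,
    BMI ~23 kg/m^2); missingness probabilities reflect how often each field
    was unreported."""

    n_studies: int = 25
    arm_table: tuple[ArmTemplate, ...] = DEFAULT_ARM_TABLE
    n_subjects_log_sd: float = 0.35
    fixed: FixedEffects = field(default_factory=_default_fixed)
    omega_diag: np.ndarray = field(default_factory=_default_omega)
    sigma2: float = 0.0410
    demographics_mean: dict[str, float] = field(default_factory=lambda: {
        "mean_age": 26.4, "mean_weight": 59.2, "mean_height": 162.8,
        "mean_bmi": 23.0})
    demographics_sd: dict[str, float] = field(default_factory=lambda: {
        "mean_age": 2.5, "mean_weight": 4.0, "mean_height": 4.0,
        "mean_bmi": 1.5})
    missingness: dict[str, float] = field(default_factory=lambda: {
        "mean_age": 0.0, "mean_weight": 0.05, "mean_height": 0.4,
        "mean_bmi": 0.4})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if any(not 0 <= p <= 1 for p in self.missingness.values()):
            raise ValueError("missingness probabilities must be in [0, 1]")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if np.any(np.asarray(self.omega_diag) < 0):
            raise ValueError("omega variances must be non-negative")


def _arm_assignments(config: GeneratorConfig, rng: np.random.Generator):
    """Expand the arm table by trial counts, scale to n_studies, and allocate
    arms to studies (multi-arm studies absorb the surplus)."""
    arms: list[ArmTemplate] = []
    for t in config.arm_table:
        arms.extend([t] * t.n_trials)
    total_default = len(arms)
    if config.n_studies != 25:
        # rescale composition proportionally for other dataset sizes
        n_arms = max(config.n_studies,
                     round(total_default * config.n_studies / 25))
        idx = rng.integers(0, total_default, n_arms)
        arms = [arms[i] for i in idx]
    rng.shuffle(arms)
    n_extra = len(arms) - config.n_studies
    study_of_arm = list(range(config.n_studies))
    study_of_arm += list(rng.choice(config.n_studies, size=n_extra,
                                    replace=n_extra > config.n_studies))
    return arms, study_of_arm


def generate_dataset(config: GeneratorConfig
                     ) -> tuple[Dataset, dict]:
    """Simulate a dataset plus its ground truth.

    Returns (dataset, truth) where ``truth`` records the per-study eta draws,
    per-arm macro-parameters, truncation count and the generating values.
    Byte-identical output under a fixed seed.
    """
    from .structural import (ArmCovariates, apply_random_effects,
                             predict_btb, typical_macro_params)
    from .reference import MOLECULAR_WEIGHTS

    rng = np.random.default_rng(config.seed)
    arms_t, study_of_arm = _arm_assignments(config, rng)
    S = config.n_studies
    omega_sd = np.sqrt(np.asarray(config.omega_diag, dtype=float))
    eta = rng.standard_normal((S, 4)) * omega_sd

    arms: list[StudyArm] = []
    truth_arms = []
    n_truncated = 0
    n_total = 0
    arm_counter: dict[str, int] = {}
    for tmpl, s in zip(arms_t, study_of_arm):
        sid = f"S{s + 1:02d}"
        arm_counter[sid] = arm_counter.get(sid, 0) + 1
        aid = f"{sid}a{arm_counter[sid]}"
        n_subj = int(np.clip(np.round(np.exp(
            np.log(tmpl.median_n_subjects)
            + config.n_subjects_log_sd * rng.standard_normal())), 20, 20000))
        molar = tmpl.progestin_dose_ug / MOLECULAR_WEIGHTS[tmpl.progestin]
        typ = typical_macro_params(
            config.fixed, ArmCovariates(ee_dose_ug=tmpl.ee_dose_ug,
                                        progestin_molar_dose_umol=molar))
        p = apply_random_effects(typ, eta[s])
        x = np.arange(tmpl.n_obs, dtype=float)  # monthly cycle-end schedule
        f = predict_btb(p, x)
        eps = rng.standard_normal(x.size) * np.sqrt(config.sigma2 / n_subj)
        y = f + eps
        n_total += y.size
        n_truncated += int((y < 0).sum())
        y = np.clip(y, 0.0, 1.0)
        obs = [Observation(time_since_first_obs=float(xi),
                           btb_fraction=float(yi), n_subjects_at_obs=n_subj)
               for xi, yi in zip(x, y)]
        arms.append(StudyArm(study_id=sid, arm_id=aid,
                             progestin=tmpl.progestin,
                             progestin_dose_ug=tmpl.progestin_dose_ug,
                             ee_dose_ug=tmpl.ee_dose_ug,
                             n_subjects=n_subj, observations=obs))
        truth_arms.append({
            "study_id": sid, "arm_id": aid,
            "A": p.A, "alpha": p.alpha, "B": p.B, "beta": p.beta,
            "A_typ": typ.A, "alpha_typ": typ.alpha, "B_typ": typ.B,
            "beta_typ": typ.beta})

    demographics = []
    for s in range(S):
        sid = f"S{s + 1:02d}"
        vals = {}
        for col in ("mean_age", "mean_weight", "mean_height", "mean_bmi"):
            vals[col] = float(config.demographics_mean[col]
                              + config.demographics_sd[col]
                              * rng.standard_normal())
        demographics.append(StudyDemographics(study_id=sid, **vals))
    demographics = inject_covariate_missingness(
        demographics, config.missingness,
        int(rng.integers(0, 2 ** 31)))

    arms.sort(key=lambda a: (a.study_id, a.arm_id))
    dataset = Dataset(arms=arms, demographics=demographics)
    truth = {
        "seed": config.seed,
        "eta": {f"S{s + 1:02d}": eta[s].tolist() for s in range(S)},
        "arms": truth_arms,
        "fixed": {
            "A_pop": config.fixed.A_pop, "alpha_pop": config.fixed.alpha_pop,
            "B_pop": config.fixed.B_pop, "beta_pop": config.fixed.beta_pop,
            "theta_ee_on_B": config.fixed.theta_ee_on_B,
            "theta_prog_on_alpha": config.fixed.theta_prog_on_alpha},
        "omega_diag": list(np.asarray(config.omega_diag, dtype=float)),
        "sigma2": config.sigma2,
        "n_truncated": n_truncated,
        "n_observations": n_total,
    }
    return dataset, truth


def inject_covariate_missingness(demographics: list[StudyDemographics],
                                 probabilities: dict[str, float],
                                 seed: int) -> list[StudyDemographics]:
    """Blank demographic cells independently at the given per-column rates.
    Reproducible under a fixed seed."""
    for col, p in probabilities.items():
        if not 0 <= p <= 1:
            raise ValueError(f"probability for {col} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for d in demographics:
        kwargs = {"study_id": d.study_id}
        for col in ("mean_age", "mean_weight", "mean_height", "mean_bmi"):
            v = getattr(d, col)
            p = probabilities.get(col, 0.0)
            kwargs[col] = None if (v is not None and rng.random() < p) else v
        out.append(StudyDemographics(**kwargs))
    return out


def write_ground_truth(truth: dict, path) -> None:
    """Ground truth goes to a JSON sidecar, never into the analysis inputs."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
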