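"""Canonical dataset schema, CSV I/O and the low-information imputation rule.

A dataset is a collection of trial arms.  Each arm carries an ordered series
of observations: the fraction of women with breakthrough bleeding (BTB) at a
given number of months since the first post-initiation observation.  BTB is
stored internally as a fraction in [0, 1]; percentages appear only at I/O
boundaries if a caller converts them.

Observations from cycles with fewer than 100 subjects where the observed
fraction is below 1% are too information-poor to distinguish from the natural
(pre-treatment) unscheduled-bleeding background and are replaced by half the
baseline rate, flagged as imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROGESTINS = ("DSG", "DRSP", "GSD", "LNG")

#: mandatory columns of the observations CSV
DATASET_COLUMNS = [
    "study_id", "arm_id", "progestin", "progestin_dose_ug", "ee_dose_ug",
    "n_subjects", "time_months", "btb_fraction",
]
OPTIONAL_COLUMNS = ["n_subjects_at_obs", "imputed"]

DEMOGRAPHICS_COLUMNS = [
    "study_id", "mean_age", "mean_weight", "mean_height", "mean_bmi",
]


@dataclass
class Observation:
    """One arm-level BTB observation."""

    time_since_first_obs: float   # months, >= 0
    btb_fraction: float           # in [0, 1]
    n_subjects_at_obs: int        # > 0
    imputed_flag: bool = False

    def __post_init__(self) -> None:
        if self.time_since_first_obs < 0:
            raise ValueError("time_since_first_obs must be >= 0")
        if not 0 <= self.btb_fraction <= 1:
            raise ValueError("btb_fraction must be in [0, 1]")
        if self.n_subjects_at_obs <= 0:
            raise ValueError("n_subjects_at_obs must be positive")

    @property
    def months_since_initiation(self) -> float:
        """x + 1: the first observation follows one full treatment cycle."""
        return self.time_since_first_obs + 1.0


@dataclass
class StudyArm:
    """One treatment arm of a trial (constant 21/7 monophasic regimen)."""

    study_id: str
    arm_id: str
    progestin: str
    progestin_dose_ug: float
    ee_dose_ug: float
    n_subjects: int
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.progestin not in PROGESTINS:
            raise ValueError(f"unknown progestin {self.progestin!r}")
        if self.progestin_dose_ug <= 0 or self.ee_dose_ug <= 0:
            raise ValueError("doses must be positive")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        times = [o.time_since_first_obs for o in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"arm {self.study_id}/{self.arm_id}: observation times must "
                "be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time_since_first_obs for o in self.observations])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([o.btb_fraction for o in self.observations])


@dataclass
class StudyDemographics:
    """Study-level mean demographics; any field may be missing (None)."""

    study_id: str
    mean_age: float | None = None
    mean_weight: float | None = None
    mean_height: float | None = None
    mean_bmi: float | None = None

    def __post_init__(self) -> None:
        checks = {
            "mean_age": (10, 60), "mean_weight": (30, 200),
            "mean_height": (120, 220), "mean_bmi": (14, 45),
        }
        for name, (lo, hi) in checks.items():
            v = getattr(self, name)
            if v is not None and not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside physiologic range "
                                 f"[{lo}, {hi}] for study {self.study_id}")


@dataclass(frozen=True)
class BaselineSpec:
    """Pre-treatment unscheduled-bleeding baseline and the half-baseline
    value assigned to low-information observations."""

    baseline_fraction: float = 0.0168
    imputation_fraction: float = 0.0084

    def __post_init__(self) -> None:
        if not 0 < self.imputation_fraction <= self.baseline_fraction < 1:
            raise ValueError(
                "need 0 < imputation_fraction <= baseline_fraction < 1")


@dataclass
class Dataset:
    """All arms plus study-level demographics."""

    arms: list[StudyArm]
    demographics: list[StudyDemographics] = field(default_factory=list)

    @property
    def study_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.arms:
            seen.setdefault(a.study_id, None)
        return list(seen)

    @property
    def n_observations(self) -> int:
        return sum(len(a.observations) for a in self.arms)

    def arms_of_study(self, study_id: str) -> list[StudyArm]:
        return [a for a in self.arms if a.study_id == study_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            for o in a.observations:
                rows.append({
                    "study_id": a.study_id, "arm_id": a.arm_id,
                    "progestin": a.progestin,
                    "progestin_dose_ug": a.progestin_dose_ug,
                    "ee_dose_ug": a.ee_dose_ug, "n_subjects": a.n_subjects,
                    "time_months": o.time_since_first_obs,
                    "btb_fraction": o.btb_fraction,
                    "n_subjects_at_obs": o.n_subjects_at_obs,
                    "imputed": o.imputed_flag,
                })
        return pd.DataFrame(rows, columns=DATASET_COLUMNS + OPTIONAL_COLUMNS)

    def demographics_frame(self) -> pd.DataFrame:
        rows = [{
            "study_id": d.study_id, "mean_age": d.mean_age,
            "mean_weight": d.mean_weight, "mean_height": d.mean_height,
            "mean_bmi": d.mean_bmi,
        } for d in self.demographics]
        return pd.DataFrame(rows, columns=DEMOGRAPHICS_COLUMNS)


class ValidationError(ValueError):
    """Raised on malformed input; message names the offending rows."""


def _validate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {missing}")
    bad = df.index[(df["btb_fraction"] < 0) | (df["btb_fraction"] > 1)]
    if len(bad):
        raise ValidationError(
            f"btb_fraction outside [0, 1] at row(s) {list(bad)}")
    dup = df.duplicated(subset=["study_id", "arm_id", "time_months"])
    if dup.any():
        raise ValidationError(
            f"duplicate (study, arm, time) at row(s) {list(df.index[dup])}")


def frame_to_dataset(df: pd.DataFrame,
                     demographics: pd.DataFrame | None = None) -> Dataset:
    """Build a validated Dataset from long-format frames."""
    _validate_frame(df)
    arms: list[StudyArm] = []
    for (sid, aid), g in df.groupby(["study_id", "arm_id"], sort=False):
        g = g.sort_values("time_months")
        first = g.iloc[0]
        obs = []
        for _, r in g.iterrows():
            n_at = r.get("n_subjects_at_obs")
            if n_at is None or (isinstance(n_at, float) and np.isnan(n_at)):
                n_at = r["n_subjects"]  # fall back to the arm size
            obs.append(Observation(
                time_since_first_obs=float(r["time_months"]),
                btb_fraction=float(r["btb_fraction"]),
                n_subjects_at_obs=int(n_at),
                imputed_flag=bool(r.get("imputed", False)),
            ))
        arms.append(StudyArm(
            study_id=str(sid), arm_id=str(aid),
            progestin=str(first["progestin"]),
            progestin_dose_ug=float(first["progestin_dose_ug"]),
            ee_dose_ug=float(first["ee_dose_ug"]),
            n_subjects=int(first["n_subjects"]), observations=obs))
    demo: list[StudyDemographics] = []
    if demographics is not None:
        for _, r in demographics.iterrows():
            def _v(col):
                v = r.get(col)
                return None if v is None or pd.isna(v) else float(v)
            demo.append(StudyDemographics(
                study_id=str(r["study_id"]), mean_age=_v("mean_age"),
                mean_weight=_v("mean_weight"), mean_height=_v("mean_height"),
                mean_bmi=_v("mean_bmi")))
    return Dataset(arms=arms, demographics=demo)


def read_dataset(path, demographics_path=None) -> Dataset:
    """Read and validate the observations CSV (and optional demographics
    CSV keyed by study_id)."""
    df = pd.read_csv(path)
    demo = pd.read_csv(demographics_path) if demographics_path else None
    return frame_to_dataset(df, demo)


def write_dataset(dataset: Dataset, path, demographics_path=None) -> None:
    """Write the canonical CSV schema (UTF-8, header row)."""
    dataset.to_frame().to_csv(path, index=False)
    if demographics_path is not None:
        dataset.demographics_frame().to_csv(demographics_path, index=False)


def impute_low_information_observations(
        dataset: Dataset, baseline: BaselineSpec,
        n_threshold: int = 100, fraction_threshold: float = 0.01) -> Dataset:
    """Replace low-information observations by half the baseline rate.

    An observation qualifies when its cycle had fewer than ``n_threshold``
    subjects AND the observed fraction is below ``fraction_threshold``.  The
    transformation is pure (returns a new Dataset), idempotent, and never
    drops rows; the number of imputations is logged.
    """
    n_imputed = 0
    new_arms = []
    for arm in dataset.arms:
        new_obs = []
        for o in arm.observations:
            if (o.n_subjects_at_obs < n_threshold
                    and o.btb_fraction < fraction_threshold):
                if not (o.imputed_flag
                        and o.btb_fraction == baseline.imputation_fraction):
                    n_imputed += 1
                o = replace(o, btb_fraction=baseline.imputation_fraction,
                            imputed_flag=True)
            new_obs.append(o)
        new_arms.append(replace(arm, observations=new_obs))
    logger.info("low-information imputation: %d observation(s) set to %.4f",
                n_imputed, baseline.imputation_fraction)
    return Dataset(arms=new_arms, demographics=list(dataset.demographics))
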