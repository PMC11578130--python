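"""Covariate screening, stepwise covariate modeling, and missing-covariate
imputation.

Screening: pairwise Pearson correlation (either member of a pair with
|r| > 0.6 is collinear; the one with more missingness is dropped) and one-way
ANOVA of a continuous covariate across a categorical one.

Stepwise covariate modeling (SCM): forward inclusion at p < 0.01 and
backward elimination at p < 0.001 on the likelihood-ratio test, i.e. an OFV
drop of at least chi2(0.99, df) to enter and chi2(0.999, df) to stay.

Missing covariates are imputed by individual parameter (IIP): a log-linear
regression ln(cov) = k0 + k1 * theta_i on complete cases, theta_i the
empirical-Bayes individual parameter (log scale) from the base fit; the
fitted line predicts the gaps.  A single median imputation is provided as
the simple comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Dataset
from .estimation import (CovariateTerm, FitConfig, FitResult, fit_model)

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_screen", "anova_screen", "CovariateCandidate", "ScmStep",
    "ScmResult", "stepwise_covariate_search", "IIPRegression",
    "iip_fit_and_impute", "select_iip_parameter", "median_impute",
    "forward_threshold", "backward_threshold",
]


def forward_threshold(df: int = 1, p: float = 0.01) -> float:
    """OFV drop required for forward inclusion (chi-square quantile)."""
    return float(stats.chi2.ppf(1.0 - p, df))


def backward_threshold(df: int = 1, p: float = 0.001) -> float:
    """OFV rise required to keep a covariate at backward elimination."""
    return float(stats.chi2.ppf(1.0 - p, df))


# ---------------------------------------------------------------------------
# screening

def pearson_screen(table: pd.DataFrame, threshold: float = 0.6
                   ) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of every covariate pair with |r| > threshold.

    ``table`` has one row per study and one column per covariate (NaN =
    missing).  Correlations use pairwise-complete observations; for a
    flagged pair the member with more missing values is dropped (tie: the
    one later in column order).  Constant covariates are excluded with a
    warning.  Returns (retained column names, correlation matrix).
    """
    cols = list(table.columns)
    corr = table.corr(min_periods=3)
    retained = []
    for c in cols:
        col = table[c].dropna()
        if col.size >= 2 and np.isclose(col.std(ddof=0), 0.0):
            logger.warning("covariate %s is constant; excluded", c)
            continue
        retained.append(c)
    dropped: set[str] = set()
    for i, a in enumerate(retained):
        for b in retained[i + 1:]:
            if a in dropped or b in dropped:
                continue
            r = corr.loc[a, b]
            if pd.notna(r) and abs(r) > threshold:  # strict inequality
                na, nb = table[a].isna().sum(), table[b].isna().sum()
                victim = b if nb >= na else a
                dropped.add(victim)
                logger.info("pearson screen: |r(%s, %s)| = %.3f > %.2f; "
                            "dropped %s", a, b, abs(r), threshold, victim)
    return [c for c in retained if c not in dropped], corr


def anova_screen(continuous, categorical) -> float | None:
    """One-way ANOVA p-value of a continuous covariate across the levels of
    a categorical one; None when degenerate (fewer than two groups with at
    least two values each)."""
    df = pd.DataFrame({"y": continuous, "g": categorical}).dropna()
    groups = [g["y"].to_numpy() for _, g in df.groupby("g")]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        return None
    return float(stats.f_oneway(*groups).pvalue)


# ---------------------------------------------------------------------------
# stepwise covariate modeling

@dataclass(frozen=True)
class CovariateCandidate:
    """A candidate power-model covariate effect with its LRT degrees of
    freedom (k-1 for a k-level categorical coded as k-1 terms)."""

    term: CovariateTerm
    df: int = 1

    @property
    def name(self) -> str:
        return self.term.name


@dataclass
class ScmStep:
    step: int
    direction: str            # "forward" | "backward"
    candidate: str
    delta_ofv: float
    threshold: float
    decision: str             # "added" | "removed" | "kept" | "rejected" | "failed"


@dataclass
class ScmResult:
    selected: list[CovariateCandidate]
    final_fit: FitResult
    steps: list[ScmStep]

    def step_log(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


def default_fit_engine(dataset: Dataset, terms: tuple[CovariateTerm, ...],
                       config: FitConfig, init=None) -> FitResult:
    """Fit the model with the given covariate terms (the SCM work-horse)."""
    cfg = replace(config, covariate_terms=terms)
    return fit_model(dataset, init=init, config=cfg)


def _extend_init(base: FitResult, n_new_terms: int) -> np.ndarray:
    """Initial vector for a model with extra covariate terms appended after
    the base model's terms: insert zeros for the new thetas."""
    m = base.model
    x = base.x_opt
    head = x[: m.n_macro + len(m.terms)]
    tail = x[m.n_macro + len(m.terms):]
    return np.concatenate([head, np.zeros(n_new_terms), tail])


def _strip_last_theta(fit: FitResult) -> np.ndarray:
    """The candidate optimum with its last covariate exponent removed —
    an initial vector for re-fitting the nested model in the same basin."""
    m = fit.model
    x = fit.x_opt
    cut = m.n_macro + len(m.terms) - 1
    return np.concatenate([x[:cut], x[cut + 1:]])


def stepwise_covariate_search(dataset: Dataset,
                              candidates: list[CovariateCandidate],
                              config: FitConfig | None = None,
                              forward_p: float = 0.01,
                              backward_p: float = 0.001,
                              candidate_maxfun: int = 250,
                              fit_engine=default_fit_engine) -> ScmResult:
    """Forward-inclusion / backward-elimination covariate search.

    The base model is ``config`` without covariate terms.  Candidate fits
    start from the current model's optimum (with a zero for the new
    exponent), a single optimizer start, which makes the likelihood-ratio
    statistic cheap and conservative.  Every tested step is recorded; ties
    in the OFV drop are broken by candidate input order.  Fit failures skip
    the candidate and are logged.
    """
    config = replace(config or FitConfig(), covariate_terms=())
    base = fit_engine(dataset, (), config, None)
    selected: list[CovariateCandidate] = []
    remaining = list(candidates)
    steps: list[ScmStep] = []
    k = 0
    light = replace(config, restarts=1, maxfun=candidate_maxfun)

    # forward inclusion
    n_base_refresh = 0
    while remaining:
        k += 1
        best_cand, best_fit, best_drop = None, None, -np.inf
        for cand in remaining:
            thr = forward_threshold(cand.df, forward_p)
            try:
                fit = fit_engine(
                    dataset, tuple(c.term for c in selected + [cand]),
                    light, _extend_init(base, 1))
            except (ValueError, np.linalg.LinAlgError):
                steps.append(ScmStep(k, "forward", cand.name, np.nan, thr,
                                     "failed"))
                logger.warning("SCM: fit failed for %s; skipped", cand.name)
                continue
            drop = base.ofv - fit.ofv
            steps.append(ScmStep(k, "forward", cand.name, drop, thr,
                                 "tested"))
            if drop >= thr and drop > best_drop:
                best_cand, best_fit, best_drop = cand, fit, drop
        if best_cand is None:
            break
        # LRT guard: a large drop may come from the candidate fit escaping
        # a poor base optimum rather than from the covariate itself.  Refit
        # the nested model from the candidate's basin; if the base improves,
        # redo this forward step with the honest reference OFV.
        if n_base_refresh < 3:
            try:
                base2 = fit_engine(dataset, tuple(c.term for c in selected),
                                   light, _strip_last_theta(best_fit))
            except (ValueError, np.linalg.LinAlgError):
                base2 = None
            if base2 is not None and base2.ofv < base.ofv - 1e-3:
                base = base2
                n_base_refresh += 1
                k -= 1
                steps.append(ScmStep(k + 1, "forward", "(base refit)",
                                     base.ofv, np.nan, "base_updated"))
                continue
        selected.append(best_cand)
        remaining.remove(best_cand)
        base = best_fit
        steps.append(ScmStep(k, "forward", best_cand.name, best_drop,
                             forward_threshold(best_cand.df, forward_p),
                             "added"))

    # backward elimination
    changed = True
    while changed and selected:
        changed = False
        k += 1
        for cand in list(selected):
            thr = backward_threshold(cand.df, backward_p)
            reduced = [c for c in selected if c is not cand]
            try:
                fit = fit_engine(dataset,
                                 tuple(c.term for c in reduced), light, None)
            except (ValueError, np.linalg.LinAlgError):
                steps.append(ScmStep(k, "backward", cand.name, np.nan, thr,
                                     "failed"))
                continue
            rise = fit.ofv - base.ofv
            if rise < thr:
                selected.remove(cand)
                base = fit
                steps.append(ScmStep(k, "backward", cand.name, rise, thr,
                                     "removed"))
                changed = True
            else:
                steps.append(ScmStep(k, "backward", cand.name, rise, thr,
                                     "kept"))
    # final refit at full settings
    if selected:
        final = fit_engine(dataset, tuple(c.term for c in selected),
                           config, None)
        if final.ofv > base.ofv:
            final = base
    else:
        final = base
    return ScmResult(selected=selected, final_fit=final, steps=steps)


# ---------------------------------------------------------------------------
# missing-covariate imputation

@dataclass
class IIPRegression:
    """Fitted log-linear covariate-on-parameter regression."""

    k0: float
    k1: float
    residual_sd: float
    covariate: str
    parameter: str
    n_complete: int


def select_iip_parameter(cov_values: np.ndarray,
                         log_params: dict[str, np.ndarray]) -> str:
    """Pick the individual parameter with the most significant complete-case
    association with ln(cov) (smallest regression p-value)."""
    obs = np.isfinite(cov_values)
    if obs.sum() < 3:
        raise ValueError("need at least 3 complete cases")
    y = np.log(cov_values[obs])
    best, best_p = None, np.inf
    for name, th in log_params.items():
        x = np.asarray(th, dtype=float)[obs]
        if np.isclose(x.std(ddof=0), 0.0):
            continue
        res = stats.linregress(x, y)
        if res.pvalue < best_p:
            best, best_p = name, res.pvalue
    if best is None:
        raise ValueError("all candidate parameters are constant")
    return best


def iip_fit_and_impute(cov_values, log_theta, covariate: str = "",
                       parameter: str = "") -> tuple[np.ndarray,
                                                     IIPRegression]:
    """Impute gaps in a positive covariate from individual parameters.

    ``cov_values``: per-study covariate values with NaN gaps;
    ``log_theta``: per-study empirical-Bayes individual parameter on the log
    scale (log typical + eta-hat).  k0, k1 are least-squares estimates on
    complete cases; gaps become exp(k0 + k1 * theta).  Observed values are
    never altered.
    """
    v = np.asarray(cov_values, dtype=float)
    th = np.asarray(log_theta, dtype=float)
    obs = np.isfinite(v)
    if not obs.any():
        raise ValueError("covariate is entirely missing")
    if obs.sum() < 3:
        raise ValueError("need at least 3 complete cases for IIP")
    if np.isclose(th[obs].std(ddof=0), 0.0):
        raise ValueError("individual parameter has zero variance")
    res = stats.linregress(th[obs], np.log(v[obs]))
    k0, k1 = float(res.intercept), float(res.slope)
    pred = np.exp(k0 + k1 * th)
    resid = np.log(v[obs]) - (k0 + k1 * th[obs])
    sd = float(resid.std(ddof=2)) if obs.sum() > 2 else 0.0
    out = v.copy()
    out[~obs] = pred[~obs]
    return out, IIPRegression(k0=k0, k1=k1, residual_sd=sd,
                              covariate=covariate, parameter=parameter,
                              n_complete=int(obs.sum()))


def median_impute(cov_values) -> np.ndarray:
    """Replace gaps by the complete-case median."""
    v = np.asarray(cov_values, dtype=float)
    obs = np.isfinite(v)
    if not obs.any():
        raise ValueError("covariate is entirely missing")
    out = v.copy()
    out[~obs] = np.median(v[obs])
    return out


def study_log_parameters(fit: FitResult) -> dict[str, np.ndarray]:
    """Per-study empirical-Bayes log parameters: mean arm-level log typical
    value plus the study's eta-hat, one vector per macro-parameter."""
    m = fit.model
    pop, thetas, _, _ = m.unpack(fit.x_opt)
    log_typ = m.log_typical(pop, thetas)       # (n_arms, n_macro)
    out: dict[str, np.ndarray] = {}
    for mi, name in enumerate(m.macro_names):
        per_study = np.full(m.n_studies, np.nan)
        for s in range(m.n_studies):
            per_study[s] = log_typ[m.arm_study == s, mi].mean()
        out[name] = per_study + fit.eta_hat[:, mi]
    return out
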