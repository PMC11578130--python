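"""Bi-exponential structural model for breakthrough bleeding (BTB).

The fraction of women with BTB in a trial arm declines bi-exponentially with
time x (months since the first post-initiation observation):

    BTB(x) = A * exp(-alpha * x) + B * exp(-beta * x)

A and alpha describe the rapid initial decline, B and beta the slow terminal
phase.  Covariates act as power functions on a ratio to a reference value
(log-linear on the log scale): ethinyl-estradiol (EE) dose on B and molar
progestin dose on alpha.  Inter-study variability is log-normal, applied as
theta_i = theta_typ * exp(eta_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixedEffects",
    "ArmCovariates",
    "MacroParams",
    "ReferenceConstants",
    "typical_macro_params",
    "apply_random_effects",
    "predict_btb",
    "curve_strip_initial_estimates",
    "time_to_baseline",
]


@dataclass(frozen=True)
class FixedEffects:
    """Population fixed effects of the bi-exponential BTB model.

    A_pop, B_pop are fractions in (0, 1); alpha_pop, beta_pop are first-order
    decline rates in 1/month; the two thetas are dimensionless power-model
    exponents (EE dose on B, molar progestin dose on alpha).
    """

    A_pop: float
    alpha_pop: float
    B_pop: float
    beta_pop: float
    theta_ee_on_B: float = 0.0
    theta_prog_on_alpha: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.A_pop < 1 and 0 < self.B_pop < 1):
            raise ValueError("A_pop and B_pop must be fractions in (0, 1)")
        if self.alpha_pop <= 0 or self.beta_pop <= 0:
            raise ValueError("alpha_pop and beta_pop must be positive")


@dataclass(frozen=True)
class ArmCovariates:
    """Arm-level covariates entering the power sub-models."""

    ee_dose_ug: float
    progestin_molar_dose_umol: float

    def __post_init__(self) -> None:
        if self.ee_dose_ug <= 0 or self.progestin_molar_dose_umol <= 0:
            raise ValueError("doses must be positive")


@dataclass(frozen=True)
class MacroParams:
    """Arm-level macro-constants (A, alpha, B, beta), all positive."""

    A: float
    alpha: float
    B: float
    beta: float
    stripped_fallback: bool = False

    def __post_init__(self) -> None:
        if min(self.A, self.alpha, self.B, self.beta) <= 0:
            raise ValueError("macro parameters must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.alpha, self.B, self.beta])


@dataclass(frozen=True)
class ReferenceConstants:
    """Covariate normalisers and the progestin molecular-weight table."""

    molar_ref_umol: float = 0.48
    ee_ref_ug: float = 30.0
    molecular_weights: dict[str, float] = field(default_factory=dict)

    def molar_dose(self, progestin: str, dose_ug: float) -> float:
        return dose_ug / self.molecular_weights[progestin]


def typical_macro_params(fixed: FixedEffects, cov: ArmCovariates,
                         molar_ref: float = 0.48,
                         ee_ref: float = 30.0) -> MacroParams:
    """Typical (no random effect) macro-parameters for one arm.

    alpha = alpha_pop * (molar_dose / molar_ref) ** theta_prog_on_alpha
    B     = B_pop     * (ee_dose    / ee_ref)    ** theta_ee_on_B
    A and beta carry no covariates.  Both multipliers are exactly 1 at the
    reference doses.
    """
    a = fixed.alpha_pop * (cov.progestin_molar_dose_umol / molar_ref) ** fixed.theta_prog_on_alpha
    b = fixed.B_pop * (cov.ee_dose_ug / ee_ref) ** fixed.theta_ee_on_B
    return MacroParams(A=fixed.A_pop, alpha=a, B=b, beta=fixed.beta_pop)


def apply_random_effects(typ: MacroParams, eta: np.ndarray) -> MacroParams:
    """Apply study random effects: each parameter times exp(eta).

    eta is a 4-vector ordered (A, alpha, B, beta).
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (4,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 4-vector")
    e = np.exp(eta)
    return MacroParams(A=typ.A * e[0], alpha=typ.alpha * e[1],
                       B=typ.B * e[2], beta=typ.beta * e[3])


def predict_btb(p: MacroParams, x):
    """Model-predicted BTB fraction at time(s) x >= 0 (months since first
    observation)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    out = p.A * np.exp(-p.alpha * x) + p.B * np.exp(-p.beta * x)
    return float(out) if out.ndim == 0 else out


def _loglinear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit y = c * exp(-r x) by least squares on log y; returns (c, r)."""
    slope, intercept = np.polyfit(x, np.log(y), 1)
    return float(np.exp(intercept)), float(-slope)


def curve_strip_initial_estimates(times, fractions) -> MacroParams:
    """Initial macro-constant estimates by the method of residuals.

    The terminal phase (the last max(2, ceil(n/3)) points, the standard
    terminal-third convention) is fitted log-linearly to give (B, beta); the
    fitted terminal curve is subtracted from the earlier points and the
    positive residuals fitted log-linearly to give (A, alpha).  If stripping
    leaves fewer than two positive residuals the data are effectively
    mono-exponential: the fallback returns A = B/10, alpha = 10*beta with
    ``stripped_fallback=True``.
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 (time, fraction) points")
    if np.any(y <= 0):
        raise ValueError("fractions must be strictly positive for stripping")
    order = np.argsort(x)
    x, y = x[order], y[order]

    n_late = max(2, int(np.ceil(x.size / 3)))
    xl, yl = x[-n_late:], y[-n_late:]
    xe, ye = x[:-n_late], y[:-n_late]

    def _strip_once(yl_eff):
        B, beta = _loglinear_fit(xl, yl_eff)
        beta = max(beta, 1e-6)
        resid = ye - B * np.exp(-beta * xe)
        # a residual buried below 1% of the observation carries no usable
        # information about the fast phase
        keep = resid > 0.01 * ye
        if keep.sum() < 2:
            return B, beta, None, None
        A, alpha = _loglinear_fit(xe[keep], resid[keep])
        return B, beta, A, max(alpha, beta * 1.0001)

    B, beta, A, alpha = _strip_once(yl)
    if A is None:
        return MacroParams(A=B / 10.0, alpha=10.0 * beta, B=B, beta=beta,
                           stripped_fallback=True)
    # one refinement pass: peel the estimated fast phase off the terminal
    # points before re-fitting the slow phase
    yl_corr = yl - A * np.exp(-alpha * xl)
    if np.all(yl_corr > 0):
        B2, beta2, A2, alpha2 = _strip_once(yl_corr)
        if A2 is not None:
            B, beta, A, alpha = B2, beta2, A2, alpha2
    return MacroParams(A=A, alpha=alpha, B=B, beta=beta)


def time_to_baseline(p: MacroParams, baseline: float,
                     xtol: float = 1e-6) -> float:
    """Months since treatment initiation until BTB first reaches ``baseline``.

    The first observation (x = 0) corresponds to completion of one cycle, so
    the reported time is x* + 1.  If the curve is already at or below baseline
    at x = 0 the answer is 1.0.  The root is unique because the curve is a
    strictly decreasing sum of exponentials; it is bracketed analytically by
    [0, ln((A+B)/baseline)/min(alpha, beta) + 1] and found by bisection.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if p.A + p.B <= baseline:
        return 1.0
    hi = np.log((p.A + p.B) / baseline) / min(p.alpha, p.beta) + 1.0
    lo = 0.0
    # plain bisection: the bracket is guaranteed, f is monotone
    f_hi = predict_btb(p, hi) - baseline
    if f_hi > 0:  # numerically flat tail; extend once
        hi *= 2.0
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if predict_btb(p, mid) - baseline > 0:
            lo = mid
        else:
            hi = mid
    return 1.0 + 0.5 * (lo + hi)
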