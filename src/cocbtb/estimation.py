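"""Marginal-likelihood estimation of the mixed-effects BTB model.

The marginal likelihood integrates study-level log-normal random effects out
of the joint likelihood.  The integral is approximated by the Laplace method:
for each study the joint -2 log-likelihood is minimised over eta (a damped
Newton iteration with analytic gradient and Hessian, batched across studies),
and the curvature at the mode supplies the Gaussian correction.  An adaptive
Gauss-Hermite quadrature routine with the same interface serves as an
independent higher-order check for models with few active random effects.

Residual error is additive with variance sigma^2 / N_ik, N_ik the number of
subjects in the arm: larger arms pin the observed fraction down more tightly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .datamodel import Dataset, StudyArm, StudyDemographics
from .structural import FixedEffects

__all__ = [
    "OmegaMatrix", "ResidualSpec", "FitResult", "BootstrapResult",
    "CovariateTerm", "ee_dose_term", "molar_dose_term", "demographic_term",
    "BiExpModel", "study_joint_neg2ll", "marginal_neg2ll_laplace",
    "marginal_neg2ll_agq", "laplace_neg2ll_generic", "agq_neg2ll_generic",
    "FitConfig", "fit_model", "bootstrap_fit",
]

PARAM_NAMES = ("A", "alpha", "B", "beta")
LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# statistical-model components

@dataclass
class OmegaMatrix:
    """Covariance of the study random effects, stored as a lower Cholesky
    factor.  Diagonal entries are log-scale variances; the coefficient of
    variation of the implied log-normal is sqrt(exp(omega^2) - 1)."""

    chol: np.ndarray
    names: tuple[str, ...] = PARAM_NAMES

    @classmethod
    def from_diagonal(cls, variances, names: tuple[str, ...] = PARAM_NAMES
                      ) -> "OmegaMatrix":
        v = np.asarray(variances, dtype=float)
        if np.any(v < 0):
            raise ValueError("variances must be non-negative")
        return cls(chol=np.diag(np.sqrt(v)), names=tuple(names))

    @classmethod
    def from_matrix(cls, matrix, names: tuple[str, ...] = PARAM_NAMES
                    ) -> "OmegaMatrix":
        m = np.asarray(matrix, dtype=float)
        try:
            c = np.linalg.cholesky(m)
        except np.linalg.LinAlgError:
            raise ValueError("omega must be positive definite") from None
        return cls(chol=c, names=tuple(names))

    @property
    def matrix(self) -> np.ndarray:
        return self.chol @ self.chol.T

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.matrix)

    def cv_percent(self) -> np.ndarray:
        """%CV of the log-normal random effect, sqrt(exp(omega^2) - 1)."""
        return 100.0 * np.sqrt(np.expm1(self.variances))


@dataclass(frozen=True)
class ResidualSpec:
    """Additive residual error: variance sigma2 / N at an observation from an
    arm of N subjects."""

    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def variance_at(self, n_subjects) -> np.ndarray:
        return self.sigma2 / np.asarray(n_subjects, dtype=float)

    def cv_percent(self) -> float:
        return 100.0 * float(np.sqrt(np.expm1(self.sigma2)))


@dataclass(frozen=True)
class CovariateTerm:
    """A power-model covariate on one macro-parameter.

    On the log scale the contribution is theta * log(value / reference);
    ``extractor`` pulls the covariate value for an arm (and its study's
    demographics, which may be None)."""

    name: str
    parameter: str
    reference: float
    extractor: Callable[[StudyArm, StudyDemographics | None], float]

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.reference <= 0:
            raise ValueError("reference must be positive")


def ee_dose_term(reference: float = 30.0) -> CovariateTerm:
    """Ethinyl-estradiol dose (ug) on B, normalised to 30 ug."""
    return CovariateTerm("ee_on_B", "B", reference,
                         lambda arm, demo: arm.ee_dose_ug)


def molar_dose_term(molecular_weights: dict[str, float] | None = None,
                    reference: float = 0.48) -> CovariateTerm:
    """Molar progestin dose (umol) on alpha, normalised to 0.48 umol."""
    if molecular_weights is None:
        from .reference import MOLECULAR_WEIGHTS as molecular_weights
    mw = dict(molecular_weights)
    return CovariateTerm(
        "prog_on_alpha", "alpha", reference,
        lambda arm, demo: arm.progestin_dose_ug / mw[arm.progestin])


def demographic_term(column: str, parameter: str,
                     reference: float) -> CovariateTerm:
    """A study-level demographic (mean_age, mean_weight, ...) on a
    macro-parameter.  Missing values must be imputed before fitting."""

    def _extract(arm: StudyArm, demo: StudyDemographics | None) -> float:
        if demo is None:
            raise ValueError(f"no demographics for study {arm.study_id}")
        v = getattr(demo, column)
        if v is None:
            raise ValueError(
                f"{column} missing for study {arm.study_id}; impute first")
        return float(v)

    return CovariateTerm(f"{column}_on_{parameter}", parameter,
                         reference, _extract)


# ---------------------------------------------------------------------------
# the vectorized model

class BiExpModel:
    """Flattened dataset plus covariate design, with batched inner machinery.

    The packed outer parameter vector is
    [log pop macro values | covariate thetas | log omega variances | log sigma2].
    """

    def __init__(self, dataset: Dataset,
                 covariate_terms: Sequence[CovariateTerm] = (),
                 eta_mask: Sequence[bool] = (True, True, True, True),
                 n_phases: int = 2):
        if n_phases not in (1, 2):
            raise ValueError("n_phases must be 1 or 2")
        self.n_phases = n_phases
        self.macro_names = PARAM_NAMES[: 2 * n_phases]
        self.n_macro = len(self.macro_names)
        eta_mask = tuple(bool(b) for b in eta_mask)[: self.n_macro]
        self.eta_mask = eta_mask
        self.eta_macros = [i for i, b in enumerate(eta_mask) if b]
        self.q = len(self.eta_macros)
        self.terms = tuple(covariate_terms)
        for t in self.terms:
            if t.parameter not in self.macro_names:
                raise ValueError(
                    f"term {t.name} targets {t.parameter}, absent from a "
                    f"{n_phases}-phase model")

        self.study_ids = dataset.study_ids
        sidx = {s: i for i, s in enumerate(self.study_ids)}
        demo = {d.study_id: d for d in dataset.demographics}
        self.n_studies = len(self.study_ids)

        arms = dataset.arms
        self.n_arms = len(arms)
        self.arm_study = np.array([sidx[a.study_id] for a in arms])
        # log(cov/ref) per term per arm
        self.design = np.zeros((len(self.terms), self.n_arms))
        for ti, t in enumerate(self.terms):
            vals = np.array([t.extractor(a, demo.get(a.study_id))
                             for a in arms], dtype=float)
            if np.any(vals <= 0):
                raise ValueError(f"term {t.name}: covariate values must be "
                                 "positive for the power model")
            self.design[ti] = np.log(vals / t.reference)

        y, x, n_w, arm_idx = [], [], [], []
        for ai, a in enumerate(arms):
            for o in a.observations:
                y.append(o.btb_fraction)
                x.append(o.time_since_first_obs)
                n_w.append(a.n_subjects)  # Eq-weight: arm size
                arm_idx.append(ai)
        self.y = np.array(y)
        self.x = np.array(x)
        self.n_w = np.array(n_w, dtype=float)
        self.arm_idx = np.array(arm_idx)
        self.obs_study = self.arm_study[self.arm_idx]
        self.n_obs = self.y.size
        self.obs_per_study = np.bincount(self.obs_study,
                                         minlength=self.n_studies)
        if np.any(self.obs_per_study == 0):
            raise ValueError("every study needs at least one observation")
        self._warm_eta = np.zeros((self.n_studies, self.q))

    # -- packing ------------------------------------------------------------

    @property
    def n_params(self) -> int:
        return self.n_macro + len(self.terms) + self.q + 1

    def pack(self, pop: Sequence[float], thetas: Sequence[float],
             omega_var: Sequence[float], sigma2: float) -> np.ndarray:
        return np.concatenate([
            np.log(np.asarray(pop, dtype=float)),
            np.asarray(thetas, dtype=float),
            np.log(np.asarray(omega_var, dtype=float)),
            [np.log(sigma2)]])

    def unpack(self, xvec: np.ndarray):
        m, t, q = self.n_macro, len(self.terms), self.q
        pop = np.exp(xvec[:m])
        thetas = xvec[m:m + t]
        omega_var = np.exp(xvec[m + t:m + t + q])
        sigma2 = float(np.exp(xvec[-1]))
        return pop, thetas, omega_var, sigma2

    def bounds(self) -> list[tuple[float, float]]:
        """Box bounds on the packed log-scale vector: intercepts A, B are
        fractions (< 1), rates alpha, beta below 20/month, ISV variances
        below ~5.5 (CV ~1500%), sigma2 below 1."""
        m, t, q = self.n_macro, len(self.terms), self.q
        pop_b = [(-14.0, 0.0), (-14.0, 3.0), (-14.0, 0.0), (-14.0, 3.0)]
        return (pop_b[:m] + [(-12.0, 12.0)] * t
                + [(-12.0, 1.7)] * q + [(-16.0, 0.0)])

    # -- typical parameters per arm ------------------------------------------

    def log_typical(self, pop: np.ndarray, thetas: np.ndarray) -> np.ndarray:
        """(n_arms, n_macro) log typical macro values."""
        lt = np.tile(np.log(pop), (self.n_arms, 1))
        for ti, t in enumerate(self.terms):
            m = self.macro_names.index(t.parameter)
            lt[:, m] += thetas[ti] * self.design[ti]
        return lt

    # -- inner problem --------------------------------------------------------

    def _obs_log_macros(self, log_typ: np.ndarray, eta: np.ndarray
                        ) -> np.ndarray:
        """(n_obs, n_macro) log macro values including random effects."""
        lm = log_typ[self.arm_idx]
        if self.q:
            lm = lm.copy()
            eta_obs = eta[self.obs_study]
            for j, m in enumerate(self.eta_macros):
                lm[:, m] += eta_obs[:, j]
        return lm

    def _predict(self, log_macros: np.ndarray):
        """Predictions plus the per-phase exponentials; mono-exponential when
        n_phases == 1."""
        A = np.exp(log_macros[:, 0])
        al = np.exp(log_macros[:, 1])
        E1 = A * np.exp(-al * self.x)
        if self.n_phases == 1:
            return E1, (E1, al * self.x, None, None)
        B = np.exp(log_macros[:, 2])
        be = np.exp(log_macros[:, 3])
        E2 = B * np.exp(-be * self.x)
        return E1 + E2, (E1, al * self.x, E2, be * self.x)

    def _dF(self, parts) -> np.ndarray:
        """(n_obs, q) derivative of the prediction in each active eta."""
        E1, u, E2, v = parts
        cols = {0: E1, 1: -u * E1}
        if self.n_phases == 2:
            cols[2] = E2
            cols[3] = -v * E2
        return np.stack([cols[m] for m in self.eta_macros], axis=1)

    def _joint_parts(self, log_typ, eta, omega_var, sigma2):
        """Per-study joint -2LL split into data and prior terms."""
        f, parts = self._predict(self._obs_log_macros(log_typ, eta))
        r = self.y - f
        wi = self.n_w / sigma2
        data = np.bincount(self.obs_study, weights=wi * r * r,
                           minlength=self.n_studies)
        data += np.bincount(self.obs_study,
                            weights=LOG2PI + np.log(sigma2 / self.n_w),
                            minlength=self.n_studies)
        if self.q:
            prior = (eta * eta / omega_var).sum(axis=1) \
                + float(np.log(2 * np.pi * omega_var).sum())
        else:
            prior = np.zeros(self.n_studies)
        return data + prior, f, parts, r, wi

    def joint_neg2ll_per_study(self, xvec: np.ndarray, eta: np.ndarray
                               ) -> np.ndarray:
        pop, thetas, omega_var, sigma2 = self.unpack(xvec)
        j, *_ = self._joint_parts(self.log_typical(pop, thetas), eta,
                                  omega_var, sigma2)
        return j

    def _grad_hess(self, eta, omega_var, r, wi, parts):
        """Batched gradient (S, q) and Hessian (S, q, q) of the joint -2LL."""
        S, q = self.n_studies, self.q
        dF = self._dF(parts)
        g = np.empty((S, q))
        for j in range(q):
            g[:, j] = -2.0 * np.bincount(
                self.obs_study, weights=wi * r * dF[:, j], minlength=S)
        g += 2.0 * eta / omega_var

        H = np.empty((S, q, q))
        E1, u, E2, v = parts
        d2 = {(0, 0): E1, (0, 1): -u * E1, (1, 1): E1 * (u * u - u)}
        if self.n_phases == 2:
            d2.update({(2, 2): E2, (2, 3): -v * E2,
                       (3, 3): E2 * (v * v - v)})
        for j in range(q):
            for k in range(j, q):
                mj, mk = self.eta_macros[j], self.eta_macros[k]
                w = 2.0 * wi * dF[:, j] * dF[:, k]
                key = (min(mj, mk), max(mj, mk))
                if key in d2:
                    w = w - 2.0 * wi * r * d2[key]
                H[:, j, k] = H[:, k, j] = np.bincount(
                    self.obs_study, weights=w, minlength=S)
        H[:, range(q), range(q)] += 2.0 / omega_var
        return g, H

    def inner_modes(self, xvec: np.ndarray, eta0: np.ndarray | None = None,
                    tol: float = 1e-7, max_iter: int = 120):
        """Posterior modes of eta per study: batched damped Newton from the
        warm start (or zero), with per-study backtracking line search and
        negative-curvature escape from saddle points.

        Returns (eta_hat, joint -2LL per study at the modes, Hessians there,
        converged flag per study)."""
        pop, thetas, omega_var, sigma2 = self.unpack(xvec)
        log_typ = self.log_typical(pop, thetas)
        S, q = self.n_studies, self.q
        if q == 0:
            j, *_ = self._joint_parts(log_typ, np.zeros((S, 0)),
                                      omega_var, sigma2)
            return (np.zeros((S, 0)), j, np.zeros((S, 0, 0)),
                    np.ones(S, dtype=bool))
        # always start from eta = 0 (or the caller's eta0): the objective
        # must be a deterministic function of xvec — a history-dependent
        # warm start makes re-evaluations inconsistent and derails the
        # outer quasi-Newton iteration
        if eta0 is not None:
            eta = np.clip(np.asarray(eta0, dtype=float).copy(), -20, 20)
        else:
            eta = np.zeros((S, q))

        # constants hoisted out of the Newton loop
        wi_all = self.n_w / sigma2
        const = np.bincount(self.obs_study,
                            weights=LOG2PI + np.log(sigma2 / self.n_w),
                            minlength=S) \
            + float(np.log(2 * np.pi * omega_var).sum())
        # one-hot map from active-eta space into macro space
        M = np.zeros((q, self.n_macro))
        for j_, m_ in enumerate(self.eta_macros):
            M[j_, m_] = 1.0
        lt_obs = log_typ[self.arm_idx]

        def joint(eta_):
            lm = lt_obs + eta_[self.obs_study] @ M
            f_, parts_ = self._predict(lm)
            r_ = self.y - f_
            j_ = np.bincount(self.obs_study, weights=wi_all * r_ * r_,
                             minlength=S)
            j_ += const + (eta_ * eta_ / omega_var).sum(axis=1)
            return j_, f_, parts_, r_

        j_cur, f, parts, r = joint(eta)
        wi = wi_all
        converged = np.zeros(S, dtype=bool)
        n_fail = np.zeros(S, dtype=int)  # line-search failures per study
        for _ in range(max_iter):
            g, H = self._grad_hess(eta, omega_var, r, wi, parts)
            if not (np.all(np.isfinite(g)) and np.all(np.isfinite(H))):
                raise np.linalg.LinAlgError(
                    "non-finite inner derivatives (degenerate parameters)")
            gnorm = np.abs(g).max(axis=1)
            ev, V = np.linalg.eigh(H)
            ev_min = ev[:, 0]
            converged = ((gnorm < tol) & (ev_min > -1e-8)) | (n_fail >= 3)
            if converged.all():
                break
            # saddle-free Newton: invert |eigenvalues| (floored) so that
            # indefinite curvature still yields a bounded descent direction
            inv_ev = 1.0 / np.maximum(np.abs(ev), 1e-6)
            step = np.einsum("sij,sj,skj,sk->si", V, inv_ev, V, g)
            # cap the move at 5 log-units per component
            scale = np.maximum(1.0, np.abs(step).max(axis=1) / 5.0)
            step /= scale[:, None]
            # at a saddle (tiny gradient, negative curvature) walk along the
            # most negative eigenvector instead
            saddle = (gnorm < tol) & (ev_min <= -1e-8)
            if saddle.any():
                step[saddle] = V[saddle, :, 0] * 0.5
            t = np.where(converged, 0.0, 1.0)
            accepted = converged.copy()
            eta_best, j_best = eta.copy(), j_cur.copy()
            for _ls in range(8):
                trial = eta - t[:, None] * step
                np.clip(trial, -20, 20, out=trial)
                j_try, *_ = joint(trial)
                better = ~accepted & (j_try <= j_cur - 1e-14)
                eta_best[better] = trial[better]
                j_best[better] = j_try[better]
                accepted |= better
                if saddle.any():  # a saddle step may improve in either sense
                    trial2 = eta + t[:, None] * step
                    np.clip(trial2, -20, 20, out=trial2)
                    j_try2, *_ = joint(trial2)
                    better2 = saddle & (j_try2 < j_best - 1e-14)
                    eta_best[better2] = trial2[better2]
                    j_best[better2] = j_try2[better2]
                    accepted |= better2
                if accepted.all():
                    break
                t = np.where(accepted, t, t * 0.5)
            n_fail[~accepted] += 1
            total_gain = float((j_cur - j_best).sum())
            eta = eta_best
            j_cur, f, parts, r = joint(eta)
            if total_gain < 1e-12:
                break  # stalled: no study can improve further
        g, H = self._grad_hess(eta, omega_var, r, wi, parts)
        converged = (np.abs(g).max(axis=1) < max(tol, 1e-6))
        self._warm_eta = eta.copy()
        return eta, j_cur, H, converged

    def laplace_ofv(self, xvec: np.ndarray) -> float:
        """-2 log marginal likelihood by the Laplace approximation:
        sum_s [joint(-2LL at mode) - q*log(2*pi) + log det(H_s / 2)].

        Inner Hessians that are numerically indefinite at the mode are
        ridged to the nearest comfortably positive-definite matrix before
        the determinant (flat random-effect directions in small studies)."""
        if not np.all(np.isfinite(xvec)):
            return 1e12
        try:
            eta, j, H, ok = self.inner_modes(xvec)
        except np.linalg.LinAlgError:
            return 1e12
        if self.q == 0:
            return float(j.sum())
        ev_min = np.linalg.eigvalsh(H)[:, 0]
        bad = ev_min < 1e-10
        if bad.any():
            H = H.copy()
            H[bad] += (np.abs(ev_min[bad]) + 1e-8)[:, None, None] \
                * np.eye(self.q)
        sign, logdet = np.linalg.slogdet(H / 2.0)
        if np.any(sign <= 0) or not np.all(np.isfinite(logdet)) \
                or not np.all(np.isfinite(j)):
            return 1e12
        return float((j - self.q * LOG2PI + logdet).sum())

    def agq_ofv(self, xvec: np.ndarray, n_nodes: int = 33) -> float:
        """Adaptive Gauss-Hermite -2 log marginal likelihood.

        Quadrature nodes are centred at the per-study mode and scaled by the
        local curvature.  Cost grows as n_nodes**q; intended for q <= 2 as an
        independent check on the Laplace value."""
        if self.q == 0:
            return self.laplace_ofv(xvec)
        if self.q > 3:
            raise ValueError("AGQ supported for at most 3 active effects")
        pop, thetas, omega_var, sigma2 = self.unpack(xvec)
        log_typ = self.log_typical(pop, thetas)
        eta_hat, j_hat, H, _ = self.inner_modes(xvec)
        z1, w1 = np.polynomial.hermite.hermgauss(n_nodes)
        grids = np.array(list(itertools.product(z1, repeat=self.q)))
        logw = np.log(np.array(
            [np.prod(c) for c in itertools.product(w1, repeat=self.q)]))
        z2 = (grids ** 2).sum(axis=1)
        total = 0.0
        for s in range(self.n_studies):
            Hnll = H[s] / 2.0
            L = np.linalg.cholesky(np.linalg.inv(Hnll))
            pts = eta_hat[s] + np.sqrt(2.0) * grids @ L.T
            # joint -2LL at all nodes of this study at once
            jv = np.empty(len(pts))
            for k, e in enumerate(pts):
                jv[k] = self._joint_single(log_typ, s, e, omega_var, sigma2)
            log_i = (0.5 * self.q * np.log(2.0)
                     + np.log(np.diag(L)).sum()
                     + logsumexp(logw + z2 - 0.5 * jv))
            total += -2.0 * log_i
        return float(total)

    def _joint_single(self, log_typ, study: int, eta_s: np.ndarray,
                      omega_var, sigma2) -> float:
        """Joint -2LL of one study at one eta value (scalar path)."""
        mask = self.obs_study == study
        lm = log_typ[self.arm_idx[mask]].copy()
        for j, m in enumerate(self.eta_macros):
            lm[:, m] += eta_s[j]
        A = np.exp(lm[:, 0])
        f = A * np.exp(-np.exp(lm[:, 1]) * self.x[mask])
        if self.n_phases == 2:
            f = f + np.exp(lm[:, 2]) * np.exp(-np.exp(lm[:, 3]) * self.x[mask])
        r = self.y[mask] - f
        nw = self.n_w[mask]
        val = float((r * r * nw / sigma2).sum()
                    + (LOG2PI + np.log(sigma2 / nw)).sum())
        val += float((eta_s ** 2 / omega_var).sum()
                     + np.log(2 * np.pi * omega_var).sum())
        return val


# ---------------------------------------------------------------------------
# spec-level operations on (FixedEffects, OmegaMatrix, ResidualSpec)

def _canonical_model(dataset: Dataset, eta_mask=(True,) * 4) -> BiExpModel:
    return BiExpModel(dataset,
                      covariate_terms=(molar_dose_term(), ee_dose_term()),
                      eta_mask=eta_mask)


def _canonical_x(model: BiExpModel, fixed: FixedEffects, omega: OmegaMatrix,
                 residual: ResidualSpec) -> np.ndarray:
    pop = [fixed.A_pop, fixed.alpha_pop, fixed.B_pop, fixed.beta_pop]
    thetas = [fixed.theta_prog_on_alpha, fixed.theta_ee_on_B]
    var = omega.variances[list(model.eta_macros)]
    return model.pack(pop, thetas, var, residual.sigma2)


def study_joint_neg2ll(study_arms: Sequence[StudyArm], fixed: FixedEffects,
                       eta: np.ndarray, omega: OmegaMatrix,
                       residual: ResidualSpec) -> float:
    """Joint -2 log-likelihood of one study's arms at a given eta:
    Gaussian observation terms (variance sigma2/N) plus the Gaussian eta
    prior under Omega."""
    from .reference import MOLECULAR_WEIGHTS
    from .structural import (ArmCovariates, apply_random_effects,
                             predict_btb, typical_macro_params)
    eta = np.asarray(eta, dtype=float)
    om = omega.matrix
    sign, logdet = np.linalg.slogdet(om)
    if sign <= 0:
        raise ValueError("omega is singular")
    total = float(eta @ np.linalg.solve(om, eta)
                  + logdet + eta.size * LOG2PI)
    for arm in study_arms:
        cov = ArmCovariates(
            ee_dose_ug=arm.ee_dose_ug,
            progestin_molar_dose_umol=(
                arm.progestin_dose_ug / MOLECULAR_WEIGHTS[arm.progestin]))
        p = apply_random_effects(typical_macro_params(fixed, cov), eta)
        f = predict_btb(p, arm.times)
        var = residual.sigma2 / arm.n_subjects
        total += float((((arm.fractions - f) ** 2) / var).sum()
                       + arm.times.size * (LOG2PI + np.log(var)))
    return total


def marginal_neg2ll_laplace(dataset: Dataset, fixed: FixedEffects,
                            omega: OmegaMatrix, residual: ResidualSpec
                            ) -> float:
    """Laplace -2 log marginal likelihood of the canonical final model."""
    model = _canonical_model(dataset)
    return model.laplace_ofv(_canonical_x(model, fixed, omega, residual))


def marginal_neg2ll_agq(dataset: Dataset, fixed: FixedEffects,
                        omega: OmegaMatrix, residual: ResidualSpec,
                        eta_mask=(True,) * 4, n_nodes: int = 33) -> float:
    """Adaptive Gauss-Hermite -2 log marginal likelihood (oracle route)."""
    model = _canonical_model(dataset, eta_mask=eta_mask)
    return model.agq_ofv(_canonical_x(model, fixed, omega, residual),
                         n_nodes=n_nodes)


# ---------------------------------------------------------------------------
# generic per-study Laplace / AGQ over arbitrary joint -2LL callables

def _numeric_mode_and_hessian(fn: Callable[[np.ndarray], float], q: int):
    res = optimize.minimize(fn, np.zeros(q), method="BFGS")
    res = optimize.minimize(fn, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    mode = res.x
    # central second differences: 1e-3 balances truncation against
    # cancellation (and is exact up to rounding for quadratic objectives)
    h = 1e-3
    H = np.zeros((q, q))
    f0 = fn(mode)
    for i in range(q):
        for j in range(i, q):
            ei = np.eye(q)[i] * h
            ej = np.eye(q)[j] * h
            if i == j:
                H[i, i] = (fn(mode + ei) - 2 * f0 + fn(mode - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    fn(mode + ei + ej) - fn(mode + ei - ej)
                    - fn(mode - ei + ej) + fn(mode - ei - ej)) / (4 * h ** 2)
    return mode, f0, H


def laplace_neg2ll_generic(per_study_neg2ll: Sequence[Callable],
                           q: int) -> float:
    """Laplace -2 log marginal likelihood for arbitrary per-study joint
    -2LL callables of a q-vector eta (numeric modes and Hessians).  Exact
    whenever each callable is quadratic in eta."""
    total = 0.0
    for fn in per_study_neg2ll:
        mode, f0, H = _numeric_mode_and_hessian(fn, q)
        sign, logdet = np.linalg.slogdet(H / 2.0)
        if sign <= 0:
            raise ValueError("non-positive-definite Hessian at the mode")
        total += f0 - q * LOG2PI + logdet
    return float(total)


def agq_neg2ll_generic(per_study_neg2ll: Sequence[Callable], q: int,
                       n_nodes: int = 33) -> float:
    """Adaptive Gauss-Hermite counterpart of :func:`laplace_neg2ll_generic`."""
    z1, w1 = np.polynomial.hermite.hermgauss(n_nodes)
    grids = np.array(list(itertools.product(z1, repeat=q)))
    logw = np.log(np.array(
        [np.prod(c) for c in itertools.product(w1, repeat=q)]))
    z2 = (grids ** 2).sum(axis=1)
    total = 0.0
    for fn in per_study_neg2ll:
        mode, _, H = _numeric_mode_and_hessian(fn, q)
        L = np.linalg.cholesky(np.linalg.inv(H / 2.0))
        pts = mode + np.sqrt(2.0) * grids @ L.T
        jv = np.array([fn(p) for p in pts])
        log_i = (0.5 * q * np.log(2.0) + np.log(np.diag(L)).sum()
                 + logsumexp(logw + z2 - 0.5 * jv))
        total += -2.0 * log_i
    return float(total)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitConfig:
    """Estimation options.

    restarts > 1 re-launches the quasi-Newton outer optimisation from
    perturbed initial vectors (seeded) and keeps the best OFV."""

    covariate_terms: tuple[CovariateTerm, ...] = ()
    eta_mask: tuple[bool, ...] = (True, True, True, True)
    n_phases: int = 2
    restarts: int = 3
    perturb_scale: float = 0.3
    maxfun: int = 2000
    gtol: float = 1e-4
    seed: int = 0


@dataclass
class FitResult:
    """Estimates plus convergence metadata and empirical-Bayes eta modes."""

    params: dict[str, float]
    omega: OmegaMatrix
    residual: ResidualSpec
    ofv: float
    eta_hat: np.ndarray            # (n_studies, 4), zero where eta inactive
    study_ids: list[str]
    converged: bool
    n_function_evals: int
    seed: int
    config: FitConfig
    model: BiExpModel
    x_opt: np.ndarray

    @property
    def fixed_effects(self) -> FixedEffects:
        """Canonical FixedEffects view (covariate thetas default to 0 when
        the corresponding term is absent)."""
        p = self.params
        return FixedEffects(
            A_pop=p["A_pop"], alpha_pop=p["alpha_pop"],
            B_pop=p.get("B_pop", 1e-12) or 1e-12,
            beta_pop=p.get("beta_pop", 1e-12) or 1e-12,
            theta_ee_on_B=p.get("theta_ee_on_B", 0.0),
            theta_prog_on_alpha=p.get("theta_prog_on_alpha", 0.0),
        )

    def estimates_frame(self):
        import pandas as pd
        rows = [{"parameter": k, "estimate": v} for k, v in
                self.params.items()]
        for name, var, cv in zip(
                [self.model.macro_names[m] for m in self.model.eta_macros],
                self.omega.variances, self.omega.cv_percent()):
            rows.append({"parameter": f"isv_{name}", "estimate": var,
                         "cv_percent": cv})
        rows.append({"parameter": "sigma2", "estimate": self.residual.sigma2,
                     "cv_percent": self.residual.cv_percent()})
        rows.append({"parameter": "ofv", "estimate": self.ofv})
        return pd.DataFrame(rows)


_THETA_KEY = {"ee_on_B": "theta_ee_on_B", "prog_on_alpha":
              "theta_prog_on_alpha"}


def _params_dict(model: BiExpModel, xvec: np.ndarray) -> dict[str, float]:
    pop, thetas, omega_var, sigma2 = model.unpack(xvec)
    out = {f"{n}_pop": float(v) for n, v in zip(model.macro_names, pop)}
    for t, v in zip(model.terms, thetas):
        out[_THETA_KEY.get(t.name, f"theta_{t.name}")] = float(v)
    return out


def default_initial_values(dataset: Dataset, model: BiExpModel) -> np.ndarray:
    """Initial packed vector by the method of residuals.

    Each arm with at least four observations is curve-stripped separately
    and the medians of the recovered macro-constants are used, clipped into
    plausible ranges so that no phase starts numerically extinguished."""
    from .structural import curve_strip_initial_estimates
    strips = []
    for arm in dataset.arms:
        if len(arm.observations) < 4:
            continue
        try:
            # fractions below half the background bleeding rate carry no
            # shape information; flooring them keeps log-fits sane
            mp = curve_strip_initial_estimates(
                arm.times, np.clip(arm.fractions, 0.004, None))
        except (ValueError, np.linalg.LinAlgError):
            continue
        strips.append([mp.A, mp.alpha, mp.B, mp.beta])
    if strips:
        med = np.median(np.array(strips), axis=0)
    else:  # sparse arms only: start from the data range
        ymax = float(model.y.max()) or 0.05
        med = np.array([0.7 * ymax, 1.0, 0.3 * ymax, 0.05])
    A = float(np.clip(med[0], 1e-3, 0.5))
    alpha = float(np.clip(med[1], 0.3, 5.0))
    B = float(np.clip(med[2], 1e-3, 0.5))
    # the terminal phase declines on a months scale: cap the initial slow
    # rate well below the fast one to avoid the label-swapped basin
    beta = float(np.clip(med[3], 0.005, min(0.2, alpha / 4.0)))
    pop = [A, alpha, B, beta][: model.n_macro]
    return model.pack(pop, np.zeros(len(model.terms)),
                      np.full(model.q, 0.2), 0.02)


def shape_anchor_initial_values(model: BiExpModel) -> np.ndarray:
    """A second deterministic start: generic two-phase decline shaped by the
    data ceiling (fast phase about one month, slow phase about 20 months)."""
    first = float(np.mean(model.y[model.x == model.x.min()])) or 0.05
    last = float(np.mean(model.y[model.x == model.x.max()]))
    A = max(0.75 * first, 1e-3)
    B = float(np.clip(max(last, 0.15 * first), 1e-3, 0.5))
    pop = [A, 1.0, B, 0.05][: model.n_macro]
    return model.pack(pop, np.zeros(len(model.terms)),
                      np.full(model.q, 0.2), 0.02)


def fit_model(dataset: Dataset, init: np.ndarray | None = None,
              config: FitConfig | None = None) -> FitResult:
    """Maximise the Laplace marginal likelihood.

    Fixed effects are estimated on the log scale (they are positive and
    log-normally distributed across studies), covariate exponents on the
    natural scale, variances on the log scale.
    """
    config = config or FitConfig()
    model = BiExpModel(dataset, covariate_terms=config.covariate_terms,
                       eta_mask=config.eta_mask, n_phases=config.n_phases)
    if init is None:
        x0 = default_initial_values(dataset, model)
        anchors = [x0, shape_anchor_initial_values(model)]
    else:
        x0 = np.asarray(init, dtype=float)
        anchors = [x0]
    rng = np.random.default_rng(config.seed)
    n_evals = 0
    best = None
    for r in range(max(1, config.restarts)):
        if r < len(anchors):
            xs = anchors[r]
        else:
            xs = anchors[r % len(anchors)] + rng.normal(
                0.0, config.perturb_scale, x0.size)
        model._warm_eta = np.zeros((model.n_studies, model.q))
        res = optimize.minimize(
            model.laplace_ofv, xs, method="L-BFGS-B",
            bounds=model.bounds(),
            options={"maxfun": config.maxfun, "eps": 1e-6,
                     "gtol": config.gtol, "ftol": 1e-9})
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    x_opt = best.x
    model._warm_eta = np.zeros((model.n_studies, model.q))
    eta_q, j, H, ok = model.inner_modes(x_opt)
    eta_full = np.zeros((model.n_studies, 4))
    for jcol, m in enumerate(model.eta_macros):
        eta_full[:, m] = eta_q[:, jcol]
    pop, thetas, omega_var, sigma2 = model.unpack(x_opt)
    names = tuple(model.macro_names[m] for m in model.eta_macros)
    return FitResult(
        params=_params_dict(model, x_opt),
        omega=OmegaMatrix.from_diagonal(omega_var, names=names),
        residual=ResidualSpec(sigma2=sigma2),
        ofv=float(best.fun), eta_hat=eta_full,
        study_ids=list(model.study_ids),
        converged=bool(best.success and np.isfinite(best.fun)),
        n_function_evals=n_evals, seed=config.seed, config=config,
        model=model, x_opt=x_opt)


# ---------------------------------------------------------------------------
# nonparametric bootstrap

@dataclass
class BootstrapResult:
    """Replicate estimates with percentile confidence intervals."""

    replicates: "object"           # DataFrame, one row per replicate
    median: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    n_failed_replicates: int
    n_boot: int
    seed: int


def resample_studies(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Resample studies with replacement; all arms of a study move together.
    Resampled studies get fresh unique ids so repeated draws stay distinct."""
    ids = dataset.study_ids
    demo = {d.study_id: d for d in dataset.demographics}
    picks = rng.integers(0, len(ids), len(ids))
    arms, demos = [], []
    for k, pi in enumerate(picks):
        sid = ids[pi]
        new_sid = f"bs{k}_{sid}"
        for a in dataset.arms_of_study(sid):
            arms.append(replace(a, study_id=new_sid,
                                observations=list(a.observations)))
        if sid in demo:
            demos.append(replace(demo[sid], study_id=new_sid))
    return Dataset(arms=arms, demographics=demos)


def bootstrap_fit(dataset: Dataset, n_boot: int, seed: int,
                  base_fit: FitResult, config: FitConfig | None = None
                  ) -> BootstrapResult:
    """Nonparametric study-level bootstrap of the fit.

    Each replicate resamples whole studies with replacement, refits from the
    base estimates (single start), and contributes one row of estimates;
    non-converged replicates are excluded and counted."""
    import pandas as pd
    config = config or base_fit.config
    config = replace(config, restarts=1)
    rows = []
    n_failed = 0
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_boot):
        rng = np.random.default_rng(child)
        bs = resample_studies(dataset, rng)
        try:
            fit = fit_model(bs, init=base_fit.x_opt, config=config)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not np.isfinite(fit.ofv) or fit.ofv >= 1e12:
            n_failed += 1
            continue
        row = dict(fit.params)
        for name, var in zip(fit.omega.names, fit.omega.variances):
            row[f"isv_{name}"] = var
        row["sigma2"] = fit.residual.sigma2
        rows.append(row)
    reps = pd.DataFrame(rows)
    med = reps.median().to_dict() if len(reps) else {}
    lo = reps.quantile(0.025).to_dict() if len(reps) else {}
    hi = reps.quantile(0.975).to_dict() if len(reps) else {}
    return BootstrapResult(replicates=reps, median=med, ci_lower=lo,
                           ci_upper=hi, n_failed_replicates=n_failed,
                           n_boot=n_boot, seed=seed)
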