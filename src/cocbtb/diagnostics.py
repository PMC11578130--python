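"""Visual predictive check and residual diagnostics for a fitted model.

The VPC re-simulates the original design (same arms, covariates, arm sizes
and observation times) from the fitted model many times and compares the
observed 10th/50th/90th percentiles per time bin with the 95% confidence
band of the same percentiles across replicates.  Time bins are the unique
scheduled observation times — trial schedules are discrete, so no smoothing
is applied.

Residuals follow the population-model conventions: PRED is the prediction
at eta = 0, IPRED at the empirical-Bayes mode eta-hat, IWRES the residual
standardised by the residual sd sqrt(sigma^2/N), and CWRES the first-order
(FOCE-style) conditional weighted residual, standardised by the full
linearised covariance (G Omega G' + Sigma)^(1/2) per study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Dataset
from .estimation import FitResult

__all__ = ["VPCResult", "run_vpc", "run_vpc_stratified",
           "compute_residuals", "cwres_linearized", "plot_vpc"]

PERCENTILES = (10.0, 50.0, 90.0)


@dataclass
class VPCResult:
    """Observed and simulated percentile summaries per time bin."""

    bins: np.ndarray                       # unique observation times
    n_obs_per_bin: np.ndarray
    observed: pd.DataFrame                 # columns p10, p50, p90
    band_lower: pd.DataFrame               # 2.5% of each percentile
    band_median: pd.DataFrame              # 50% of each percentile
    band_upper: pd.DataFrame               # 97.5% of each percentile
    n_replicates: int
    seed: int

    def coverage(self) -> pd.DataFrame:
        """Per bin and percentile: does the observed percentile fall inside
        the 95% band?"""
        cols = [f"p{int(p)}" for p in PERCENTILES]
        inside = {}
        for c in cols:
            inside[c] = ((self.observed[c] >= self.band_lower[c])
                         & (self.observed[c] <= self.band_upper[c]))
        return pd.DataFrame(inside, index=self.observed.index)

    def to_frame(self) -> pd.DataFrame:
        out = {"time": self.bins, "n_obs": self.n_obs_per_bin}
        for c in self.observed.columns:
            out[f"obs_{c}"] = self.observed[c].to_numpy()
            out[f"sim_{c}_lo"] = self.band_lower[c].to_numpy()
            out[f"sim_{c}_med"] = self.band_median[c].to_numpy()
            out[f"sim_{c}_hi"] = self.band_upper[c].to_numpy()
        return pd.DataFrame(out)


def _simulate_replicates(fit: FitResult, n_replicates: int,
                         rng: np.random.Generator) -> np.ndarray:
    """(n_replicates, n_obs) matrix of simulated observations under the
    fitted model on the original design, truncated at 0 exactly as the data
    generator truncates."""
    m = fit.model
    pop, thetas, omega_var, sigma2 = m.unpack(fit.x_opt)
    log_typ = m.log_typical(pop, thetas)
    sd_eta = np.sqrt(omega_var)
    res_sd = np.sqrt(sigma2 / m.n_w)
    sims = np.empty((n_replicates, m.n_obs))
    for r in range(n_replicates):
        eta = rng.standard_normal((m.n_studies, m.q)) * sd_eta
        lm = log_typ[m.arm_idx].copy()
        for j, mi in enumerate(m.eta_macros):
            lm[:, mi] += eta[m.obs_study, j]
        f, _ = m._predict(lm)
        y = f + rng.standard_normal(m.n_obs) * res_sd
        sims[r] = np.clip(y, 0.0, 1.0)
    return sims


def run_vpc(fit: FitResult, dataset: Dataset | None = None,
            n_replicates: int = 1000, seed: int = 0) -> VPCResult:
    """Visual predictive check of a converged fit.

    ``dataset`` defaults to the dataset the model was built on (the design
    is taken from the fitted model either way).  Empty bins cannot arise by
    construction — bins are the observed times themselves.
    """
    m = fit.model
    rng = np.random.default_rng(seed)
    sims = _simulate_replicates(fit, n_replicates, rng)
    bins = np.unique(m.x)
    cols = [f"p{int(p)}" for p in PERCENTILES]
    obs_rows, lo_rows, med_rows, hi_rows, nobs = [], [], [], [], []
    for b in bins:
        mask = m.x == b
        nobs.append(int(mask.sum()))
        obs_rows.append([np.percentile(m.y[mask], p) for p in PERCENTILES])
        # percentile of each replicate, then CI across replicates
        rep_pct = np.percentile(sims[:, mask], PERCENTILES, axis=1)  # (3, R)
        lo_rows.append(np.percentile(rep_pct, 2.5, axis=1))
        med_rows.append(np.percentile(rep_pct, 50.0, axis=1))
        hi_rows.append(np.percentile(rep_pct, 97.5, axis=1))
    idx = pd.Index(bins, name="time")
    return VPCResult(
        bins=bins, n_obs_per_bin=np.array(nobs),
        observed=pd.DataFrame(obs_rows, columns=cols, index=idx),
        band_lower=pd.DataFrame(lo_rows, columns=cols, index=idx),
        band_median=pd.DataFrame(med_rows, columns=cols, index=idx),
        band_upper=pd.DataFrame(hi_rows, columns=cols, index=idx),
        n_replicates=n_replicates, seed=seed)


def run_vpc_stratified(fit: FitResult, dataset: Dataset,
                       n_replicates: int = 1000, seed: int = 0
                       ) -> dict[str, VPCResult]:
    """Per-product VPCs (one per progestin/EE dose combination).

    The pooled VPC mixes arms with very different dose levels into one
    percentile band; stratifying re-runs the check on each product's arms
    at the same fitted parameters.  Strata are keyed
    "<progestin> <dose>/<EE>"."""
    from .estimation import BiExpModel, FitResult as FR

    combos: dict[str, list] = {}
    for arm in dataset.arms:
        key = (f"{arm.progestin} {arm.progestin_dose_ug:g}"
               f"/{arm.ee_dose_ug:g}")
        combos.setdefault(key, []).append(arm)
    out: dict[str, VPCResult] = {}
    for i, (key, arms) in enumerate(sorted(combos.items())):
        sub = Dataset(arms=arms, demographics=dataset.demographics)
        model = BiExpModel(sub, covariate_terms=fit.model.terms,
                           eta_mask=fit.model.eta_mask,
                           n_phases=fit.model.n_phases)
        eta_q, j, H, ok = model.inner_modes(fit.x_opt)
        eta_full = np.zeros((model.n_studies, 4))
        eta_full[:, list(model.eta_macros)] = eta_q
        pinned = FR(params=dict(fit.params), omega=fit.omega,
                    residual=fit.residual, ofv=float(j.sum()),
                    eta_hat=eta_full, study_ids=list(model.study_ids),
                    converged=fit.converged, n_function_evals=0,
                    seed=fit.seed, config=fit.config, model=model,
                    x_opt=fit.x_opt)
        out[key] = run_vpc(pinned, sub, n_replicates=n_replicates,
                           seed=seed + i)
    return out


def cwres_linearized(y: np.ndarray, f_hat: np.ndarray, G: np.ndarray,
                     eta_hat: np.ndarray, omega: np.ndarray,
                     var_diag: np.ndarray) -> np.ndarray:
    """First-order conditional weighted residuals for one study.

    The model is linearised at the posterior mode: y ~ N(f(eta_hat) -
    G eta_hat, G Omega G' + Sigma) under the population distribution of
    eta, so the standardised residual is
    (G Omega G' + Sigma)^(-1/2) (y - f_hat + G eta_hat).
    """
    resid = y - f_hat + G @ eta_hat
    cov = G @ omega @ G.T + np.diag(var_diag)
    w, v = np.linalg.eigh(cov)
    if w.min() <= 0:
        raise np.linalg.LinAlgError("singular linearised covariance")
    inv_sqrt = v @ np.diag(1.0 / np.sqrt(w)) @ v.T
    return inv_sqrt @ resid


def compute_residuals(fit: FitResult, dataset: Dataset | None = None
                      ) -> pd.DataFrame:
    """Residual table: one row per observation with PRED, IPRED, IWRES and
    CWRES (falling back to IWRES with a flag when the linearised covariance
    is singular)."""
    m = fit.model
    pop, thetas, omega_var, sigma2 = m.unpack(fit.x_opt)
    log_typ = m.log_typical(pop, thetas)

    # PRED at eta = 0
    pred, _ = m._predict(log_typ[m.arm_idx])

    # IPRED and derivatives at eta-hat
    eta_q = fit.eta_hat[:, list(m.eta_macros)]
    lm = log_typ[m.arm_idx].copy()
    for j, mi in enumerate(m.eta_macros):
        lm[:, mi] += eta_q[m.obs_study, j]
    ipred, parts = m._predict(lm)
    dF = m._dF(parts)                      # (n_obs, q)

    var_diag = sigma2 / m.n_w
    iwres = (m.y - ipred) / np.sqrt(var_diag)
    omega = np.diag(omega_var)

    cwres = np.full(m.n_obs, np.nan)
    flagged = np.zeros(m.n_obs, dtype=bool)
    for s in range(m.n_studies):
        mask = m.obs_study == s
        try:
            cwres[mask] = cwres_linearized(
                m.y[mask], ipred[mask], dF[mask], eta_q[s], omega,
                var_diag[mask])
        except np.linalg.LinAlgError:
            cwres[mask] = iwres[mask]
            flagged[mask] = True

    arms = dataset.arms if dataset is not None else None
    arm_names = None
    if arms is not None:
        arm_names = np.array([f"{a.study_id}/{a.arm_id}" for a in arms])
    return pd.DataFrame({
        "study": np.array(fit.study_ids)[m.obs_study],
        "arm": arm_names[m.arm_idx] if arm_names is not None
        else m.arm_idx.astype(str),
        "time": m.x,
        "observed": m.y,
        "PRED": pred,
        "IPRED": ipred,
        "IWRES": iwres,
        "CWRES": cwres,
        "cwres_fallback": flagged,
    })


def plot_vpc(vpc: VPCResult, path=None, ax=None, as_percent: bool = True):
    """Observed dots and percentile lines over shaded simulated 95% bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    s = 100.0 if as_percent else 1.0
    t = vpc.bins
    for c, style in zip(("p10", "p50", "p90"), ("--", "-", "--")):
        ax.fill_between(t, s * vpc.band_lower[c], s * vpc.band_upper[c],
                        alpha=0.25,
                        color="tab:purple" if c == "p50" else "tab:blue",
                        linewidth=0)
        ax.plot(t, s * vpc.observed[c], style, color="black", linewidth=1.2)
    ax.set_xlabel("months since first observation")
    ax.set_ylabel("women with BTB (%)" if as_percent else "BTB fraction")
    ax.set_title(f"visual predictive check ({vpc.n_replicates} replicates)")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
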