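"""Joint likelihood, Laplace marginal likelihood, fitting and bootstrap."""

import numpy as np
import pytest
from scipy import stats

from cocbtb.datamodel import Dataset, Observation, StudyArm
from cocbtb.estimation import (BiExpModel, FitConfig, OmegaMatrix,
                               ResidualSpec, agq_neg2ll_generic,
                               bootstrap_fit, ee_dose_term, fit_model,
                               laplace_neg2ll_generic,
                               marginal_neg2ll_laplace, molar_dose_term,
                               resample_studies, study_joint_neg2ll)
from cocbtb.reference import final_model_isv_variances
from cocbtb.synthetic import GeneratorConfig, generate_dataset

FINAL_TERMS = (molar_dose_term(), ee_dose_term())


def _one_study(n_subjects=200, times=(0.0, 1.0, 3.0), fractions=(0.06, 0.04, 0.02)):
    obs = [Observation(time_since_first_obs=t, btb_fraction=f,
                       n_subjects_at_obs=n_subjects)
           for t, f in zip(times, fractions)]
    return StudyArm(study_id="S1", arm_id="a1", progestin="LNG",
                    progestin_dose_ug=150, ee_dose_ug=30,
                    n_subjects=n_subjects, observations=obs)


def _density_product_neg2ll(arm, fixed, eta, omega, sigma2):
    """Independent oracle: assemble the joint density from scipy normals."""
    from cocbtb.reference import MOLECULAR_WEIGHTS
    from cocbtb.structural import (ArmCovariates, apply_random_effects,
                                   predict_btb, typical_macro_params)
    cov = ArmCovariates(arm.ee_dose_ug,
                        arm.progestin_dose_ug / MOLECULAR_WEIGHTS[arm.progestin])
    p = apply_random_effects(typical_macro_params(fixed, cov), eta)
    ll = stats.multivariate_normal.logpdf(eta, mean=np.zeros(4),
                                          cov=omega.matrix)
    for o in arm.observations:
        mu = predict_btb(p, o.time_since_first_obs)
        ll += stats.norm.logpdf(o.btb_fraction, loc=mu,
                                scale=np.sqrt(sigma2 / arm.n_subjects))
    return -2.0 * ll


def test_study_joint_neg2ll_matches_density_product_oracle(reference_fixed):
    rng = np.random.default_rng(5)
    arm = _one_study(fractions=tuple(rng.uniform(0.01, 0.1, 3)))
    eta = rng.normal(0, 0.4, 4)
    omega = OmegaMatrix.from_diagonal([0.8, 0.9, 0.2, 0.15])
    got = study_joint_neg2ll([arm], reference_fixed, eta, omega,
                             ResidualSpec(0.041))
    want = _density_product_neg2ll(arm, reference_fixed, eta, omega, 0.041)
    assert got == pytest.approx(want, rel=1e-10)


def test_weighting_halves_variance_when_arm_doubles(reference_fixed):
    """sigma^2/N law: doubling the arm size changes each observation term by
    r^2*N/sigma^2 doubling minus log 2."""
    omega = OmegaMatrix.from_diagonal([0.5] * 4)
    eta = np.zeros(4)
    a1 = _one_study(n_subjects=100)
    a2 = _one_study(n_subjects=200)
    j1 = study_joint_neg2ll([a1], reference_fixed, eta, omega,
                            ResidualSpec(0.041))
    j2 = study_joint_neg2ll([a2], reference_fixed, eta, omega,
                            ResidualSpec(0.041))
    # recompute expected difference directly
    from cocbtb.structural import predict_btb, typical_macro_params, \
        ArmCovariates
    p = typical_macro_params(reference_fixed, ArmCovariates(30.0, 150 / 312.45))
    expected = 0.0
    for o in a1.observations:
        r2 = (o.btb_fraction - predict_btb(p, o.time_since_first_obs)) ** 2
        expected += r2 * 100 / 0.041 - np.log(2.0)  # var halves, quad doubles
    assert j2 - j1 == pytest.approx(expected, rel=1e-9)


def test_omega_cv_reporting_convention():
    """Log-normal %CV = sqrt(exp(omega^2) - 1): variance 0.824 -> 113% CV."""
    om = OmegaMatrix.from_diagonal([0.824, 0.959, 0.223, 0.138])
    cv = om.cv_percent()
    assert cv[0] == pytest.approx(113.0, abs=0.5)
    assert cv[1] == pytest.approx(127.0, abs=0.5)
    assert cv[2] == pytest.approx(49.9, abs=0.5)
    assert cv[3] == pytest.approx(38.5, abs=0.5)


def test_laplace_collapsed_random_effects(small_dataset, reference_fixed):
    """With vanishing ISV the marginal equals the eta = 0 likelihood."""
    ds, _ = small_dataset
    omega = OmegaMatrix.from_diagonal([1e-12] * 4)
    got = marginal_neg2ll_laplace(ds, reference_fixed, omega,
                                  ResidualSpec(0.041))
    m = BiExpModel(ds, covariate_terms=FINAL_TERMS, eta_mask=(False,) * 4)
    x = m.pack([0.0383, 0.922, 0.0134, 0.0524], [0.576, -2.45], [], 0.041)
    no_re = m.laplace_ofv(x)
    assert got == pytest.approx(no_re, abs=1e-3)


def test_laplace_exact_on_linear_gaussian_model():
    """For y = a + G eta + eps the Laplace method is exact; the closed-form
    marginal is y ~ N(a, G Omega G' + Sigma)."""
    rng = np.random.default_rng(3)
    q, n = 2, 4
    fns, closed = [], 0.0
    for _ in range(5):
        G = rng.normal(size=(n, q))
        a = rng.normal(size=n)
        y = rng.normal(size=n)
        sig2 = 0.3
        omega = np.diag([0.7, 0.4])

        def neg2ll(eta, G=G, a=a, y=y):
            mu = a + G @ eta
            v = -2 * stats.norm.logpdf(y, mu, np.sqrt(sig2)).sum()
            v += -2 * stats.multivariate_normal.logpdf(
                eta, np.zeros(q), omega)
            return float(v)

        fns.append(neg2ll)
        closed += -2 * stats.multivariate_normal.logpdf(
            y, a, G @ omega @ G.T + sig2 * np.eye(n))
    lap = laplace_neg2ll_generic(fns, q)
    assert lap == pytest.approx(closed, abs=1e-6)
    agq = agq_neg2ll_generic(fns, q, n_nodes=21)
    assert agq == pytest.approx(closed, abs=1e-6)


def test_laplace_close_to_quadrature_single_random_effect(reference_fixed):
    """One active random effect: Laplace within 0.5 OFV units of 33-node
    adaptive Gauss-Hermite on a 5-study synthetic set."""
    cfg = GeneratorConfig(n_studies=5, seed=21,
                          omega_diag=np.array([0.3, 0.0, 0.0, 0.0]))
    ds, _ = generate_dataset(cfg)
    mask = (True, False, False, False)
    m = BiExpModel(ds, covariate_terms=FINAL_TERMS, eta_mask=mask)
    x = m.pack([0.0383, 0.922, 0.0134, 0.0524], [0.576, -2.45], [0.3], 0.041)
    lap = m.laplace_ofv(x)
    agq = m.agq_ofv(x, n_nodes=33)
    assert abs(lap - agq) <= 0.5


def test_fit_recovers_noise_free_fixed_effects():
    """No ISV, tiny residual noise: the fixed effects come back within 1%."""
    cfg = GeneratorConfig(n_studies=12, seed=5,
                          omega_diag=np.zeros(4), sigma2=1e-8)
    ds, truth = generate_dataset(cfg)
    fit = fit_model(ds, config=FitConfig(
        covariate_terms=FINAL_TERMS, eta_mask=(False,) * 4,
        restarts=1, maxfun=3000, seed=0))
    for k, v in truth["fixed"].items():
        assert fit.params[k] == pytest.approx(v, rel=0.01), k


def test_refit_from_optimum_is_stationary(small_fit, small_dataset):
    ds, _ = small_dataset
    again = fit_model(ds, init=small_fit.x_opt,
                      config=FitConfig(covariate_terms=FINAL_TERMS,
                                       restarts=1, maxfun=2500, seed=0))
    assert abs(again.ofv - small_fit.ofv) < 0.01


def test_ofv_invariant_to_study_relabeling_and_order(small_dataset,
                                                     reference_fixed):
    ds, _ = small_dataset
    omega = OmegaMatrix.from_diagonal(final_model_isv_variances())
    res = ResidualSpec(0.041)
    base = marginal_neg2ll_laplace(ds, reference_fixed, omega, res)
    perm = Dataset(arms=list(reversed(ds.arms)),
                   demographics=ds.demographics)
    assert marginal_neg2ll_laplace(perm, reference_fixed, omega, res) == \
        pytest.approx(base, abs=1e-6)
    relab = Dataset(arms=[
        StudyArm(study_id="X" + a.study_id, arm_id=a.arm_id,
                 progestin=a.progestin,
                 progestin_dose_ug=a.progestin_dose_ug,
                 ee_dose_ug=a.ee_dose_ug, n_subjects=a.n_subjects,
                 observations=list(a.observations)) for a in ds.arms])
    assert marginal_neg2ll_laplace(relab, reference_fixed, omega, res) == \
        pytest.approx(base, abs=1e-6)


def test_bootstrap_single_study_is_identity(reference_fixed):
    """With one study every with-replacement resample is the dataset itself,
    so the replicate estimate equals the base fit."""
    cfg = GeneratorConfig(n_studies=1, seed=9, omega_diag=np.zeros(4),
                          sigma2=1e-6)
    ds, _ = generate_dataset(cfg)
    fc = FitConfig(covariate_terms=(), eta_mask=(False,) * 4, restarts=1,
                   maxfun=800, seed=0)
    base = fit_model(ds, config=fc)
    boot = bootstrap_fit(ds, n_boot=1, seed=4, base_fit=base, config=fc)
    assert boot.n_failed_replicates == 0
    for k, v in base.params.items():
        assert boot.replicates[k].iloc[0] == pytest.approx(v, rel=1e-3)


def test_resample_moves_whole_studies(table1_dataset):
    ds, _ = table1_dataset
    rng = np.random.default_rng(0)
    bs = resample_studies(ds, rng)
    assert len(bs.study_ids) == len(ds.study_ids)
    # arms of a resampled study keep their original sibling arms together
    orig_arm_sets = {sid: sorted(a.arm_id for a in ds.arms_of_study(sid))
                     for sid in ds.study_ids}
    for sid in bs.study_ids:
        src = sid.split("_", 1)[1]
        assert sorted(a.arm_id for a in bs.arms_of_study(sid)) == \
            orig_arm_sets[src]


def test_bootstrap_median_tracks_point_estimates():
    """Bootstrap medians agree with the base estimates on synthetic data
    (the qualitative check used for the real fit)."""
    cfg = GeneratorConfig(n_studies=12, seed=31)
    ds, _ = generate_dataset(cfg)
    fc = FitConfig(covariate_terms=(), restarts=1, maxfun=500, seed=0)
    base = fit_model(ds, config=fc)
    boot = bootstrap_fit(ds, n_boot=20, seed=12, base_fit=base, config=fc)
    ok = 0
    for k in ("A_pop", "alpha_pop", "B_pop", "beta_pop"):
        med = boot.median[k]
        if np.isfinite(med) and abs(np.log(med / base.params[k])) < np.log(2):
            ok += 1
    assert ok >= 3
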