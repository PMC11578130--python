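"""Bi-exponential model, covariate sub-models, curve stripping and the
time-to-baseline solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocbtb.structural import (ArmCovariates, FixedEffects, MacroParams,
                               apply_random_effects,
                               curve_strip_initial_estimates, predict_btb,
                               time_to_baseline, typical_macro_params)


def test_typical_params_at_reference_doses(reference_fixed):
    """Covariate multipliers are exactly 1 at EE 30 ug and 0.48 umol."""
    cov = ArmCovariates(ee_dose_ug=30.0, progestin_molar_dose_umol=0.48)
    p = typical_macro_params(reference_fixed, cov)
    assert (p.A, p.alpha, p.B, p.beta) == pytest.approx(
        (0.0383, 0.922, 0.0134, 0.0524))


def test_ee_effect_matches_log_domain_oracle(reference_fixed):
    """B at EE 15 ug equals the log-linear sub-model evaluated directly."""
    cov = ArmCovariates(ee_dose_ug=15.0, progestin_molar_dose_umol=0.48)
    p = typical_macro_params(reference_fixed, cov)
    expected_B = np.exp(np.log(0.0134) + (-2.45) * np.log(15.0 / 30.0))
    assert p.B == pytest.approx(expected_B, rel=1e-12)
    assert p.B == pytest.approx(0.0134 * 0.5 ** (-2.45), rel=1e-12)
    assert (p.A, p.alpha, p.beta) == pytest.approx((0.0383, 0.922, 0.0524))


@given(ee=st.floats(5.0, 60.0), molar=st.floats(0.05, 10.0))
@settings(max_examples=50, deadline=None)
def test_null_covariate_effects_leave_population_values(ee, molar):
    fx = FixedEffects(A_pop=0.04, alpha_pop=1.0, B_pop=0.012,
                      beta_pop=0.05, theta_ee_on_B=0.0,
                      theta_prog_on_alpha=0.0)
    p = typical_macro_params(fx, ArmCovariates(ee, molar))
    assert (p.A, p.alpha, p.B, p.beta) == (0.04, 1.0, 0.012, 0.05)


@given(ee1=st.floats(10.0, 50.0), ee2=st.floats(10.0, 50.0))
@settings(max_examples=50, deadline=None)
def test_covariate_effect_signs(reference_fixed, ee1, ee2):
    """Negative EE exponent: B strictly decreases with EE dose; positive
    progestin exponent: alpha strictly increases with molar dose."""
    if abs(ee1 - ee2) < 1e-9:
        return
    lo, hi = min(ee1, ee2), max(ee1, ee2)
    p_lo = typical_macro_params(reference_fixed, ArmCovariates(lo, 0.48))
    p_hi = typical_macro_params(reference_fixed, ArmCovariates(hi, 0.48))
    assert p_lo.B > p_hi.B
    q_lo = typical_macro_params(reference_fixed, ArmCovariates(30.0, 0.1))
    q_hi = typical_macro_params(reference_fixed, ArmCovariates(30.0, 1.0))
    assert q_lo.alpha < q_hi.alpha


def test_random_effects_identity_and_log_shift():
    typ = MacroParams(A=0.04, alpha=1.0, B=0.012, beta=0.05)
    same = apply_random_effects(typ, np.zeros(4))
    assert same.as_array() == pytest.approx(typ.as_array())
    shifted = apply_random_effects(typ, np.array([np.log(2), 0, 0, 0]))
    assert shifted.A == pytest.approx(0.08)
    assert (shifted.alpha, shifted.B, shifted.beta) == pytest.approx(
        (1.0, 0.012, 0.05))


def test_random_effects_lognormal_median(reference_fixed, reference_isv):
    """Over many draws the median of each parameter is its typical value."""
    typ = MacroParams(A=0.0383, alpha=0.922, B=0.0134, beta=0.0524)
    rng = np.random.default_rng(7)
    eta = rng.standard_normal((100_000, 4)) * np.sqrt(reference_isv)
    draws = typ.as_array() * np.exp(eta)
    med = np.median(draws, axis=0)
    assert med == pytest.approx(typ.as_array(), rel=0.03)


def test_predict_intercept_and_monotonicity():
    p = MacroParams(A=0.0383, alpha=0.922, B=0.0134, beta=0.0524)
    assert predict_btb(p, 0.0) == pytest.approx(0.0517)
    x = np.linspace(0, 24, 200)
    y = predict_btb(p, x)
    assert np.all(np.diff(y) < 0)
    with pytest.raises(ValueError):
        predict_btb(p, -0.5)


def test_predict_mono_exponential_half_life():
    """With a vanishing second phase the decay is single-exponential."""
    p = MacroParams(A=0.05, alpha=0.7, B=1e-300, beta=0.05)
    half_life = np.log(2) / 0.7
    assert predict_btb(p, half_life) == pytest.approx(0.025, rel=1e-6)


def test_predict_symmetric_under_phase_swap():
    """(A, alpha) <-> (B, beta) relabeling leaves predictions unchanged."""
    p = MacroParams(A=0.0383, alpha=0.922, B=0.0134, beta=0.0524)
    q = MacroParams(A=0.0134, alpha=0.0524, B=0.0383, beta=0.922)
    x = np.linspace(0, 12, 25)
    assert predict_btb(p, x) == pytest.approx(predict_btb(q, x))


def test_curve_strip_recovers_noise_free_constants():
    true = MacroParams(A=0.04, alpha=1.0, B=0.012, beta=0.05)
    x = np.arange(0.0, 13.0)
    y = predict_btb(true, x)
    est = curve_strip_initial_estimates(x, y)
    assert est.as_array() == pytest.approx(true.as_array(), rel=0.05)
    assert not est.stripped_fallback


def test_curve_strip_mono_exponential_fallback():
    x = np.arange(0.0, 8.0)
    y = 0.03 * np.exp(-0.06 * x)
    est = curve_strip_initial_estimates(x, y)
    assert est.stripped_fallback
    assert est.B == pytest.approx(0.03, rel=0.2)
    assert est.A == pytest.approx(est.B / 10)


def test_curve_strip_requires_four_points():
    with pytest.raises(ValueError):
        curve_strip_initial_estimates([0, 1, 2], [0.3, 0.2, 0.1])


def test_time_to_baseline_already_below():
    p = MacroParams(A=0.006, alpha=1.0, B=0.004, beta=0.05)
    assert time_to_baseline(p, 0.0168) == 1.0


def test_time_to_baseline_matches_grid_scan_oracle(reference_fixed):
    """Bisection agrees with a dense grid scan to 0.01 months on the
    GSD 60/15 typical curve and on 1000 random parameter sets."""
    cov = ArmCovariates(ee_dose_ug=15.0, progestin_molar_dose_umol=60 / 310.43)
    sets = [typical_macro_params(reference_fixed, cov)]
    rng = np.random.default_rng(11)
    for _ in range(1000):
        sets.append(MacroParams(
            A=rng.uniform(0.01, 0.2), alpha=rng.uniform(0.3, 3.0),
            B=rng.uniform(0.005, 0.1), beta=rng.uniform(0.02, 0.3)))
    for p in sets:
        t = time_to_baseline(p, 0.0168)
        if p.A + p.B <= 0.0168:
            assert t == 1.0
            continue
        hi = np.log((p.A + p.B) / 0.0168) / min(p.alpha, p.beta) + 1.0
        grid = np.arange(0.0, hi + 0.001, 0.001)
        vals = predict_btb(p, grid)
        below = np.nonzero(vals <= 0.0168)[0]
        x_star = grid[below[0]] if below.size else grid[-1]
        assert t == pytest.approx(1.0 + x_star, abs=0.01)


def test_time_to_baseline_monotone_in_B():
    p1 = MacroParams(A=0.04, alpha=1.0, B=0.02, beta=0.05)
    p2 = MacroParams(A=0.04, alpha=1.0, B=0.04, beta=0.05)
    assert time_to_baseline(p2, 0.0168) > time_to_baseline(p1, 0.0168)


def test_time_to_baseline_rejects_nonpositive_baseline():
    p = MacroParams(A=0.04, alpha=1.0, B=0.02, beta=0.05)
    with pytest.raises(ValueError):
        time_to_baseline(p, 0.0)
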