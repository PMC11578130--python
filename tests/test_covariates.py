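"""Covariate screening, SCM step logic, and missing-covariate imputation."""

import numpy as np
import pandas as pd
import pytest

from cocbtb.covariates import (CovariateCandidate, anova_screen,
                               backward_threshold, forward_threshold,
                               iip_fit_and_impute, median_impute,
                               pearson_screen, select_iip_parameter,
                               stepwise_covariate_search)
from cocbtb.estimation import FitConfig, demographic_term


def _pair_with_exact_r(n, r, rng):
    """Two vectors whose sample correlation is exactly r (Gram-Schmidt)."""
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    xc = (x - x.mean()) / x.std()
    zc = z - z.mean()
    zc -= (zc @ xc) / (xc @ xc) * xc
    zc /= zc.std()
    y = r * xc + np.sqrt(1 - r ** 2) * zc
    return xc, y


def test_pearson_screen_drops_more_missing_member():
    rng = np.random.default_rng(1)
    w, b = _pair_with_exact_r(30, 0.95, rng)
    tbl = pd.DataFrame({"weight": w, "bmi": b, "age": rng.normal(size=30)})
    tbl.loc[:4, "bmi"] = np.nan  # bmi has more gaps -> bmi is dropped
    kept, corr = pearson_screen(tbl)
    assert "bmi" not in kept and "weight" in kept and "age" in kept
    assert abs(corr.loc["weight", "age"]) < 0.6


def test_pearson_screen_boundary_is_strict():
    """|r| = 0.6 exactly keeps both covariates (strict inequality)."""
    rng = np.random.default_rng(2)
    x, y = _pair_with_exact_r(40, 0.6, rng)
    tbl = pd.DataFrame({"a": x, "b": y})
    assert abs(tbl.corr().loc["a", "b"]) == pytest.approx(0.6, abs=1e-12)
    kept, _ = pearson_screen(tbl)
    assert kept == ["a", "b"]
    x2, y2 = _pair_with_exact_r(40, 0.601, rng)
    kept2, _ = pearson_screen(pd.DataFrame({"a": x2, "b": y2}))
    assert len(kept2) == 1


def test_pearson_screen_constant_covariate_excluded():
    tbl = pd.DataFrame({"c": np.ones(10),
                        "a": np.arange(10, dtype=float)})
    kept, _ = pearson_screen(tbl)
    assert kept == ["a"]


def test_anova_extreme_separation_and_degenerate_groups():
    rng = np.random.default_rng(3)
    y = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
    g = ["lo"] * 30 + ["hi"] * 30
    assert anova_screen(y, g) < 1e-3
    assert anova_screen(y[:30], ["only"] * 30) is None


def test_anova_type_one_error_rate():
    """Null data: rejection rate at alpha = 0.05 stays near 5%."""
    rng = np.random.default_rng(4)
    rejections = 0
    n_rep = 400
    g = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
    for _ in range(n_rep):
        y = rng.normal(size=30)
        if anova_screen(y, g) < 0.05:
            rejections += 1
    rate = rejections / n_rep
    assert 0.02 <= rate <= 0.085  # 95% binomial band around 0.05


def test_lrt_thresholds_match_chi_square_quantiles():
    assert forward_threshold() == pytest.approx(6.635, abs=0.001)
    assert backward_threshold() == pytest.approx(10.828, abs=0.001)
    assert forward_threshold(df=2) == pytest.approx(9.210, abs=0.001)


class _StubFit:
    """Deterministic fit result driven by a lookup of OFVs per term set."""

    def __init__(self, terms, ofv):
        self.ofv = ofv
        self.terms = terms
        self.x_opt = np.zeros(9 + len(terms))
        self.model = type("M", (), {"n_macro": 4, "terms": terms})()
        self.converged = True


def _stub_engine(ofv_table):
    def engine(dataset, terms, config, init=None):
        key = frozenset(t.name for t in terms)
        return _StubFit(terms, ofv_table[key])
    return engine


def _cands():
    return [CovariateCandidate(demographic_term("mean_age", "A", 26.0)),
            CovariateCandidate(demographic_term("mean_weight", "B", 59.0)),
            CovariateCandidate(demographic_term("mean_bmi", "beta", 23.0))]


def test_scm_selects_significant_candidates_and_keeps_them():
    """Forward picks the largest qualifying drop first; backward keeps
    covariates whose removal would cost more than 10.828 units."""
    c_age, c_wt, c_bmi = (c.name for c in _cands())
    ofv = {
        frozenset(): 100.0,
        frozenset({c_age}): 80.0,            # drop 20  -> qualifies
        frozenset({c_wt}): 92.0,             # drop 8   -> qualifies
        frozenset({c_bmi}): 99.0,            # drop 1   -> no
        frozenset({c_age, c_wt}): 68.0,      # second forward: drop 12
        frozenset({c_age, c_bmi}): 79.5,     # drop 0.5 -> no
        frozenset({c_age, c_wt, c_bmi}): 67.8,
    }
    res = stepwise_covariate_search(None, _cands(),
                                    config=FitConfig(restarts=1),
                                    fit_engine=_stub_engine(ofv))
    assert [c.name for c in res.selected] == [c_age, c_wt]
    log = res.step_log()
    assert (log["decision"] == "added").sum() == 2
    # backward keeps both: removal would cost 12 (wt) and 24 (age) units
    assert (log["decision"] == "kept").sum() == 2


def test_scm_backward_removes_weakly_supported_covariate():
    """A covariate that entered at p<0.01 but costs <10.828 to remove is
    eliminated backward (forward/backward asymmetry)."""
    c_age, c_wt, c_bmi = (c.name for c in _cands())
    ofv = {
        frozenset(): 100.0,
        frozenset({c_age}): 80.0,
        frozenset({c_wt}): 93.0,   # drop 7 -> qualifies forward
        frozenset({c_bmi}): 100.0,
        frozenset({c_age, c_wt}): 73.0,   # wt adds another 7
        frozenset({c_age, c_bmi}): 80.0,
        frozenset({c_age, c_wt, c_bmi}): 73.0,
    }
    res = stepwise_covariate_search(None, _cands(),
                                    config=FitConfig(restarts=1),
                                    fit_engine=_stub_engine(ofv))
    # weight removal raises OFV by 7 < 10.828 -> removed; age costs 20 -> kept
    assert [c.name for c in res.selected] == [c_age]
    removed = res.step_log().query("decision == 'removed'")
    assert list(removed["candidate"]) == [c_wt]


def test_scm_invariant_to_candidate_order():
    c_age, c_wt, c_bmi = (c.name for c in _cands())
    ofv = {
        frozenset(): 100.0,
        frozenset({c_age}): 80.0,
        frozenset({c_wt}): 92.0,
        frozenset({c_bmi}): 99.0,
        frozenset({c_age, c_wt}): 68.0,
        frozenset({c_age, c_bmi}): 79.5,
        frozenset({c_age, c_wt, c_bmi}): 67.8,
    }
    sel = []
    for order in ([0, 1, 2], [2, 1, 0], [1, 0, 2]):
        cands = [_cands()[i] for i in order]
        res = stepwise_covariate_search(None, cands,
                                        config=FitConfig(restarts=1),
                                        fit_engine=_stub_engine(ofv))
        sel.append(sorted(c.name for c in res.selected))
    assert sel[0] == sel[1] == sel[2]


def test_iip_exact_recovery_of_noise_free_log_linear_covariate():
    theta = np.array([-0.5, -0.2, 0.0, 0.3, 0.6, 1.0])
    cov = np.exp(1.0 + 2.0 * theta)
    gappy = cov.copy()
    gappy[[1, 4]] = np.nan
    filled, reg = iip_fit_and_impute(gappy, theta, "weight", "A")
    assert filled == pytest.approx(cov, rel=1e-10)
    assert (reg.k0, reg.k1) == pytest.approx((1.0, 2.0), abs=1e-10)
    assert reg.n_complete == 4


def test_iip_identity_when_no_gaps():
    theta = np.linspace(-1, 1, 5)
    cov = np.exp(0.5 + 0.3 * theta)
    filled, reg = iip_fit_and_impute(cov, theta)
    assert filled == pytest.approx(cov)
    assert reg.k1 == pytest.approx(0.3, abs=1e-10)


def test_iip_preserves_association_sign():
    """Imputed values are monotone in theta with the fitted slope's sign."""
    rng = np.random.default_rng(8)
    theta = rng.normal(size=20)
    cov = np.exp(2.0 - 1.5 * theta + rng.normal(0, 0.1, 20))
    gappy = cov.copy()
    gaps = [3, 7, 15]
    gappy[gaps] = np.nan
    filled, reg = iip_fit_and_impute(gappy, theta)
    assert reg.k1 < 0
    order = np.argsort(theta[gaps])
    imputed_sorted = filled[gaps][order]
    assert np.all(np.diff(imputed_sorted) < 0)
    # observed values untouched
    obs = np.isfinite(gappy)
    assert filled[obs] == pytest.approx(cov[obs])


def test_iip_error_conditions():
    with pytest.raises(ValueError):
        iip_fit_and_impute(np.full(4, np.nan), np.arange(4.0))
    with pytest.raises(ValueError):
        iip_fit_and_impute(np.array([1.0, 2.0, np.nan, 3.0]),
                           np.zeros(4))  # zero-variance theta


def test_select_iip_parameter_finds_generating_association():
    rng = np.random.default_rng(9)
    thA = rng.normal(size=15)
    thB = rng.normal(size=15)
    cov = np.exp(1.0 + 2.0 * thA + rng.normal(0, 0.05, 15))
    picked = select_iip_parameter(cov, {"A": thA, "B": thB})
    assert picked == "A"


@pytest.mark.parametrize("values, expected", [
    ([1.0, 2.0, np.nan, 4.0], 2.0),
    ([5.0, np.nan, np.nan, 5.0], 5.0),
])
def test_median_impute(values, expected):
    out = median_impute(values)
    assert np.isfinite(out).all()
    assert out[np.isnan(np.asarray(values))] == pytest.approx(expected)


def test_median_impute_identity_and_all_missing():
    v = np.array([1.0, 2.0, 3.0])
    assert median_impute(v) == pytest.approx(v)
    with pytest.raises(ValueError):
        median_impute(np.full(3, np.nan))
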