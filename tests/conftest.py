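"""Shared fixtures: reference parameters and small synthetic datasets."""

from __future__ import annotations

import pytest

from cocbtb.estimation import FitConfig, ee_dose_term, fit_model, \
    molar_dose_term
from cocbtb.reference import (BASELINE, final_model_fixed_effects,
                              final_model_isv_variances)
from cocbtb.synthetic import GeneratorConfig, generate_dataset

FINAL_TERMS = (molar_dose_term(), ee_dose_term())


@pytest.fixture(scope="session")
def reference_fixed():
    return final_model_fixed_effects()


@pytest.fixture(scope="session")
def reference_isv():
    return final_model_isv_variances()


@pytest.fixture(scope="session")
def baseline():
    return BASELINE


@pytest.fixture(scope="session")
def table1_dataset():
    """A 25-study dataset mirroring the meta-analysis composition."""
    ds, truth = generate_dataset(GeneratorConfig(n_studies=25, seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def small_dataset():
    """An 8-study dataset for cheap estimation tests."""
    ds, truth = generate_dataset(GeneratorConfig(n_studies=8, seed=123))
    return ds, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A light full-model fit reused across diagnostic tests."""
    ds, _ = small_dataset
    cfg = FitConfig(covariate_terms=FINAL_TERMS, restarts=1, maxfun=2500,
                    seed=0)
    return fit_model(ds, config=cfg)
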