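"""Shared fixtures: packaged scenarios, randomized scenario factory, and a
small pre-fitted metamodel reused across metamodel/threshold/CLI tests."""

from __future__ import annotations

import numpy as np
import pytest

from cadcea import AnalysisSettings, CohortParams, Scenario, TestProfile, load_scenario
from cadcea.metamodel import fit_metamodel
from cadcea.psa import run_psa

FLAT_TABLE = {0.0: 0.0, 200.0: 0.0}  # zero background mortality, any age


@pytest.fixture(scope="session")
def ge_us() -> Scenario:
    return load_scenario("ge_us")


@pytest.fixture(scope="session")
def genders_plus() -> Scenario:
    return load_scenario("genders_plus_ge_accuracy")


def make_scenario(**overrides) -> Scenario:
    """A compact, valid scenario with overridable fields."""
    base = dict(
        prevalence=0.3,
        age=60.0,
        male_fraction=0.5,
        test_profiles={
            "cmr": TestProfile(0.89, 0.87, 800.0),
            "spect": TestProfile(0.70, 0.75, 550.0),
            "ccta": TestProfile(0.90, 0.71, 980.0),
        },
        ica_cost=3000.0,
        cabg_cost=39000.0,
        pci_cost=20000.0,
        medical_therapy_annual_cost=1200.0,
        revascularization_fraction=0.6,
        cabg_share=0.3,
        utility_no_mace=0.84,
        utility_mace=0.78,
        mace_first_year_cost=14500.0,
        mace_subsequent_annual_cost=3400.0,
        discount_rate=0.03,
        wtp=100_000.0,
        fn_return_prob=0.58,
        horizon_age=100.0,
    )
    base.update(overrides)
    return Scenario(**base)


def random_scenario(rng: np.random.Generator) -> Scenario:
    """Randomized valid scenario; treatment is risk-reducing by construction."""
    untreated = rng.uniform(0.03, 0.10)
    u_no = rng.uniform(0.7, 0.95)
    cp = CohortParams(
        annual_first_mace_prob_untreated_cad=untreated,
        annual_first_mace_prob_treated_cad=untreated * rng.uniform(0.3, 0.9),
        annual_first_mace_prob_no_cad=rng.uniform(0.002, 0.01),
        recurrent_mace_multiplier=rng.uniform(1.0, 3.0),
        mace_case_fatality=rng.uniform(0.05, 0.3),
    )
    profiles = {
        name: TestProfile(
            sensitivity=rng.uniform(0.5, 0.99),
            specificity=rng.uniform(0.5, 0.99),
            cost=rng.uniform(200, 2000),
        )
        for name in ("cmr", "spect", "ccta")
    }
    age = rng.uniform(50, 70)
    return make_scenario(
        prevalence=rng.uniform(0.05, 0.6),
        age=age,
        horizon_age=100.0,
        test_profiles=profiles,
        ica_cost=rng.uniform(1000, 5000),
        cabg_cost=rng.uniform(20000, 50000),
        pci_cost=rng.uniform(5000, 40000),
        utility_no_mace=u_no,
        utility_mace=u_no * rng.uniform(0.8, 1.0),
        discount_rate=rng.uniform(0.0, 0.05),
        fn_return_prob=rng.uniform(0.0, 1.0),
        cohort_params=cp,
    )


@pytest.fixture(scope="session")
def small_psa(ge_us):
    """A modest PSA run shared by metamodel-level tests (3,000 / 300 records)."""
    settings = AnalysisSettings(n_train=3000, n_test=300, seed=11)
    train, test = run_psa(ge_us, settings)
    return settings, train, test


@pytest.fixture(scope="session")
def ge_metamodel(ge_us, small_psa):
    settings, train, _ = small_psa
    return fit_metamodel(train, settings, scenario=ge_us.name)
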