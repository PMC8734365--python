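"""Decision tree + Markov cohort engine: worked examples and invariants."""

import numpy as np
import pytest

from cadcea import (
    StateDistribution,
    TestProfile,
    classify_cohort,
    evaluate_all,
    evaluate_strategy,
    first_year_pathway,
    run_markov,
    step_markov,
)
from cadcea.markov import STRATEGIES
from cadcea.scenarios import CohortParams

from conftest import FLAT_TABLE, make_scenario, random_scenario


# --- classify_cohort -------------------------------------------------------

@pytest.mark.parametrize(
    "prevalence, se, sp, expected",
    [
        (0.5, 1.0, 1.0, (0.5, 0.0, 0.0, 0.5)),
        (0.324, 0.89, 0.87, (0.28836, 0.03564, 0.08788, 0.58812)),
        (0.0, 0.8, 0.6, (0.0, 0.0, 0.4, 0.6)),
    ],
)
def test_classify_cohort_partitions(prevalence, se, sp, expected):
    part = classify_cohort(prevalence, TestProfile(se, sp, 100.0))
    got = (part.tp, part.fn, part.fp, part.tn)
    assert got == pytest.approx(expected, abs=1e-12)
    assert part.tp + part.fn + part.fp + part.tn == pytest.approx(1.0, abs=1e-12)
    assert part.prevalence == pytest.approx(prevalence, abs=1e-12)


def test_classify_cohort_rejects_bad_probabilities():
    with pytest.raises(ValueError):
        classify_cohort(1.2, TestProfile(0.9, 0.9, 10.0))
    with pytest.raises(ValueError):
        classify_cohort(0.5, TestProfile(-0.1, 0.9, 10.0))


# --- first_year_pathway ----------------------------------------------------

def test_pathway_disease_free_cohort_costs_test_plus_fp_ica():
    s = make_scenario(prevalence=0.0)
    part = classify_cohort(0.0, s.test_profiles["cmr"])
    dist, cost, _ = first_year_pathway(part, s, "cmr")
    expected = s.test_profiles["cmr"].cost + part.fp * s.ica_cost
    assert cost == pytest.approx(expected, rel=1e-12)
    assert dist.occupancy[("treated_cad", "no_mace")] == 0.0
    assert dist.occupancy[("untreated_cad", "no_mace")] == 0.0


def test_pathway_false_negative_crossover_fraction():
    # 58% of false negatives return for ICA and treatment within year 1
    s = make_scenario(prevalence=0.324, fn_return_prob=0.58)
    part = classify_cohort(0.324, TestProfile(0.89, 0.87, 807.0))
    dist, _, _ = first_year_pathway(part, s, "cmr")
    rerouted = 0.58 * 0.03564
    assert rerouted == pytest.approx(0.0206712, abs=1e-12)
    assert dist.occupancy[("treated_cad", "no_mace")] == pytest.approx(
        part.tp + rerouted, abs=1e-12
    )
    assert dist.occupancy[("untreated_cad", "no_mace")] == pytest.approx(
        0.42 * 0.03564, abs=1e-12
    )


def test_pathway_ica_treats_exactly_the_prevalent_fraction():
    s = make_scenario(prevalence=0.27)
    dist, cost, _ = first_year_pathway(None, s, "ica")
    assert dist.occupancy[("treated_cad", "no_mace")] == pytest.approx(0.27)
    assert dist.occupancy[("untreated_cad", "no_mace")] == 0.0
    treat = s.revascularization_fraction * (
        s.cabg_share * s.cabg_cost + (1 - s.cabg_share) * s.pci_cost
    )
    assert cost == pytest.approx(
        s.ica_cost + 0.27 * (treat + s.medical_therapy_annual_cost)
    )


def test_pathway_unknown_strategy_and_missing_partition():
    s = make_scenario()
    with pytest.raises(ValueError, match="pet"):
        first_year_pathway(None, s, "pet")
    with pytest.raises(ValueError, match="DiagnosticPartition"):
        first_year_pathway(None, s, "cmr")


# --- step_markov -----------------------------------------------------------

def _distribution(occ):
    d = {("no_cad", "no_mace"): 0.0, "dead": 0.0}
    d.update(occ)
    total = sum(d.values())
    d[("no_cad", "no_mace")] += 1.0 - total
    return StateDistribution(d)


def test_step_markov_dead_is_absorbing():
    d = StateDistribution({"dead": 1.0})
    cp = CohortParams(background_mortality=FLAT_TABLE)
    out = step_markov(d, cp, age=70.0)
    assert out.occupancy["dead"] == pytest.approx(1.0, abs=1e-15)


def test_step_markov_identity_without_events_or_mortality():
    d = _distribution({("treated_cad", "one_mace"): 0.4})
    cp = CohortParams(
        annual_first_mace_prob_treated_cad=0.0,
        annual_first_mace_prob_untreated_cad=0.0,
        annual_first_mace_prob_no_cad=0.0,
        background_mortality=FLAT_TABLE,
    )
    out = step_markov(d, cp, age=70.0)
    for key, value in d.occupancy.items():
        assert out.occupancy.get(key, 0.0) == pytest.approx(value, abs=1e-15)


def test_step_markov_conserves_occupancy():
    rng = np.random.default_rng(5)
    cp = CohortParams()
    for _ in range(25):
        raw = rng.dirichlet(np.ones(10))
        occ = {
            (s, h): raw[i * 3 + j]
            for i, s in enumerate(("no_cad", "treated_cad", "untreated_cad"))
            for j, h in enumerate(("no_mace", "one_mace", "multi_mace"))
        }
        occ["dead"] = raw[9]
        d = StateDistribution(occ)
        out = step_markov(d, cp, age=float(rng.uniform(45, 99)))
        assert abs(out.total() - 1.0) < 1e-12
        assert all(v >= -1e-15 for v in out.occupancy.values())


def test_step_markov_age_outside_table_errors():
    cp = CohortParams()
    d = StateDistribution({("no_cad", "no_mace"): 1.0, "dead": 0.0})
    with pytest.raises(ValueError, match="mortality"):
        step_markov(d, cp, age=130.0)


# --- run_markov ------------------------------------------------------------

def test_run_markov_all_dead_yields_zero():
    s = make_scenario()
    res = run_markov(StateDistribution({"dead": 1.0}), s)
    assert (res.lifetime_cost, res.lifetime_qaly) == (0.0, 0.0)


def test_run_markov_discounting_convention():
    # one alive state, utility 0.84, no deaths/events, 2 cycles at 3%:
    # QALY = 0.84 * (1 + 1/1.03)
    cp = CohortParams(
        annual_first_mace_prob_treated_cad=0.0,
        annual_first_mace_prob_untreated_cad=0.0,
        annual_first_mace_prob_no_cad=0.0,
        background_mortality=FLAT_TABLE,
    )
    s = make_scenario(age=60.0, horizon_age=62.0, cohort_params=cp,
                      medical_therapy_annual_cost=0.0)
    d = StateDistribution({("no_cad", "no_mace"): 1.0, "dead": 0.0})
    res = run_markov(d, s)
    assert res.lifetime_qaly == pytest.approx(0.84 * (1 + 1 / 1.03), rel=1e-12)
    assert res.lifetime_cost == 0.0


def test_run_markov_zero_discount_counts_cycles():
    cp = CohortParams(
        annual_first_mace_prob_treated_cad=0.0,
        annual_first_mace_prob_untreated_cad=0.0,
        annual_first_mace_prob_no_cad=0.0,
        background_mortality=FLAT_TABLE,
    )
    s = make_scenario(age=60.0, horizon_age=75.0, discount_rate=0.0,
                      utility_no_mace=1.0, utility_mace=1.0, cohort_params=cp)
    d = StateDistribution({("no_cad", "no_mace"): 1.0, "dead": 0.0})
    res = run_markov(d, s)
    assert res.lifetime_qaly == pytest.approx(15.0, rel=1e-12)


def test_run_markov_trace_conserves_occupancy_every_cycle():
    s = make_scenario()
    part = classify_cohort(s.prevalence, s.test_profiles["cmr"])
    d, _, _ = first_year_pathway(part, s, "cmr")
    res = run_markov(d, s, collect_trace=True)
    trace = res.trace
    state_cols = [c for c in trace.columns if "." in c] + ["dead"]
    totals = trace[state_cols].sum(axis=1)
    assert np.all(np.abs(totals - 1.0) < 1e-12)
    assert (trace["discounted_qaly"].sum()) == pytest.approx(res.lifetime_qaly)


# --- evaluate_strategy / evaluate_all --------------------------------------

def test_ge_us_no_imaging_qaly_within_calibration_band(ge_us):
    out = evaluate_strategy(ge_us, "no_imaging")
    assert 11.0 <= out.lifetime_qaly <= 13.0


def test_useless_test_matches_no_imaging_health_outcomes():
    s = make_scenario(fn_return_prob=0.0)
    s = s.replace(test_profiles={**s.test_profiles,
                                 "cmr": TestProfile(0.0, 0.87, 800.0)})
    cmr = evaluate_strategy(s, "cmr")
    none = evaluate_strategy(s, "no_imaging")
    assert cmr.lifetime_qaly == pytest.approx(none.lifetime_qaly, rel=1e-12)
    part = classify_cohort(s.prevalence, s.test_profiles["cmr"])
    extra = s.test_profiles["cmr"].cost + part.fp * s.ica_cost
    assert cmr.lifetime_cost - none.lifetime_cost == pytest.approx(extra, rel=1e-9)


def test_perfect_free_test_and_treatment_equalize_strategies():
    s = make_scenario(
        ica_cost=0.0, cabg_cost=0.0, pci_cost=0.0,
        medical_therapy_annual_cost=0.0,
        test_profiles={
            name: TestProfile(1.0, 1.0, 0.0) for name in ("cmr", "spect", "ccta")
        },
    )
    outcomes = {o.strategy: o for o in evaluate_all(s)}
    ref = outcomes["ica"]
    for strat in ("cmr", "spect", "ccta"):
        assert outcomes[strat].lifetime_qaly == pytest.approx(
            ref.lifetime_qaly, rel=1e-12
        )
        assert outcomes[strat].lifetime_cost == pytest.approx(
            ref.lifetime_cost, rel=1e-12
        )


def test_evaluate_all_finite_and_ordered(ge_us):
    outcomes = evaluate_all(ge_us)
    assert [o.strategy for o in outcomes] == list(STRATEGIES)
    for o in outcomes:
        assert np.isfinite(o.lifetime_cost) and np.isfinite(o.lifetime_qaly)
        assert o.lifetime_cost >= 0 and o.lifetime_qaly >= 0
        # discounted QALYs cannot exceed undiscounted remaining life years
        assert o.lifetime_qaly <= ge_us.horizon_age - ge_us.age


def test_prevalence_zero_makes_ica_most_expensive():
    s = make_scenario(prevalence=0.0)
    outcomes = {o.strategy: o for o in evaluate_all(s)}
    assert outcomes["ica"].lifetime_cost == max(
        o.lifetime_cost for o in outcomes.values()
    )
    # without disease, every strategy yields the same health outcomes
    for o in outcomes.values():
        assert o.lifetime_qaly == pytest.approx(
            outcomes["no_imaging"].lifetime_qaly, rel=1e-12
        )


def test_qaly_monotone_in_sensitivity_and_cost_in_specificity():
    rng = np.random.default_rng(42)
    for _ in range(15):
        s = random_scenario(rng)
        modality = ("cmr", "spect", "ccta")[int(rng.integers(3))]
        profile = s.test_profiles[modality]
        se_grid = np.linspace(0.4, 0.99, 5)
        qalys = []
        for se in se_grid:
            s_se = s.replace(test_profiles={
                **s.test_profiles,
                modality: TestProfile(float(se), profile.specificity, profile.cost),
            })
            qalys.append(evaluate_strategy(s_se, modality).lifetime_qaly)
        assert np.all(np.diff(qalys) >= -1e-9)

        sp_grid = np.linspace(0.4, 0.99, 5)
        costs = []
        for sp in sp_grid:
            s_sp = s.replace(test_profiles={
                **s.test_profiles,
                modality: TestProfile(profile.sensitivity, float(sp), profile.cost),
            })
            costs.append(evaluate_strategy(s_sp, modality).lifetime_cost)
        assert np.all(np.diff(costs) <= 1e-9)


def test_zero_discount_dominates_discounted_totals():
    rng = np.random.default_rng(7)
    for _ in range(5):
        s = random_scenario(rng).replace(discount_rate=0.03)
        s0 = s.replace(discount_rate=0.0)
        for strat in STRATEGIES:
            disc = evaluate_strategy(s, strat)
            undisc = evaluate_strategy(s0, strat)
            assert undisc.lifetime_qaly >= disc.lifetime_qaly - 1e-9
            assert undisc.lifetime_cost >= disc.lifetime_cost - 1e-9


def test_evaluation_is_deterministic(ge_us):
    a = evaluate_all(ge_us)
    b = evaluate_all(ge_us)
    assert a == b
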