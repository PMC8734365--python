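"""ICERs, dominance frontier, NMB and value classes.

The frontier implementation (iterative weak- and extended-dominance removal)
is checked against an independent brute-force oracle that applies the
definitions directly: a strategy is dominated if a single rival weakly
dominates it, and extended-dominated if a convex blend of two rivals
delivers its QALYs at lower cost.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cadcea import StrategyOutcome, dominance_frontier, icer, incremental_nmb, nmb, value_class
from cadcea.cea import results_table
from cadcea.scenarios import AnalysisSettings


def O(name, cost, qaly):  # noqa: E743 - terse test helper
    return StrategyOutcome(name, cost, qaly)


# --- icer ------------------------------------------------------------------

def test_icer_from_published_table_increments():
    ref = O("no_imaging", 19223.0, 12.160)
    comp = O("cmr", 21962.0, 12.204)
    r = icer(ref, comp)
    assert r.delta_cost == pytest.approx(2739.0)
    assert r.delta_qaly == pytest.approx(0.044, abs=1e-9)
    assert r.icer == pytest.approx(62250.0, rel=1e-6)
    assert r.marker is None


def test_icer_dominated_marker():
    r = icer(O("cmr", 21962.0, 12.204), O("ccta", 22578.0, 12.203))
    assert r.marker == "dominated" and r.icer is None


def test_icer_equal_outcomes_are_equivalent():
    o = O("a", 100.0, 1.0)
    r = icer(o, O("b", 100.0, 1.0))
    assert r.marker == "equivalent"


def test_icer_both_negative_reports_reference_favoring_ratio():
    r = icer(O("a", 1000.0, 2.0), O("b", 500.0, 1.0))
    assert r.direction == "reference_vs_comparator"
    assert r.icer == pytest.approx(500.0)
    assert r.icer > 0


def test_icer_pair_classification_is_exclusive():
    rng = np.random.default_rng(3)
    for _ in range(200):
        a = O("a", rng.uniform(0, 1e4), rng.uniform(0, 20))
        b = O("b", rng.uniform(0, 1e4), rng.uniform(0, 20))
        r = icer(a, b)
        kinds = [r.marker == "dominated", r.marker == "dominant",
                 r.marker == "equivalent", r.icer is not None]
        assert sum(kinds) == 1


# --- nmb -------------------------------------------------------------------

def test_nmb_arithmetic():
    assert nmb(O("x", 0.0, 0.0), 100_000.0) == 0.0
    assert nmb(O("cmr", 14289.0, 12.884), 100_000.0) == pytest.approx(1_274_111.0)


def test_incremental_nmb_sign_flips_at_the_icer():
    ref = O("no_imaging", 1000.0, 1.0)
    comp = O("cmr", 3000.0, 1.5)
    breakeven = 2000.0 / 0.5
    assert incremental_nmb(comp, ref, breakeven) == pytest.approx(0.0, abs=1e-9)
    assert incremental_nmb(comp, ref, breakeven + 1) > 0
    assert incremental_nmb(comp, ref, breakeven - 1) < 0
    assert incremental_nmb(ref, ref, 50_000.0) == 0.0


# --- value_class -----------------------------------------------------------

@pytest.mark.parametrize(
    "value, expected",
    [
        (49_999.0, "high"),
        (50_000.0, "intermediate"),
        (52_000.0, "intermediate"),
        (150_000.0, "intermediate"),
        (150_001.0, "low"),
    ],
)
def test_value_class_bands(value, expected):
    assert value_class(value) == expected


def test_value_class_rejects_negative_ratios():
    with pytest.raises(ValueError):
        value_class(-10.0)
    with pytest.raises(ValueError):
        value_class(float("nan"))


def test_value_class_honors_custom_thresholds():
    settings_ = AnalysisSettings(high_value_threshold=10_000.0,
                                 low_value_threshold=20_000.0)
    assert value_class(15_000.0, settings_) == "intermediate"
    assert value_class(25_000.0, settings_) == "low"


# --- dominance frontier ----------------------------------------------------

def oracle_labels(outcomes):
    """Definition-level frontier oracle (exact rational arithmetic)."""
    from fractions import Fraction as F

    labels = {}
    undominated = []
    for o in outcomes:
        dom = any(
            r.lifetime_cost <= o.lifetime_cost
            and r.lifetime_qaly >= o.lifetime_qaly
            and (r.lifetime_cost < o.lifetime_cost
                 or r.lifetime_qaly > o.lifetime_qaly)
            for r in outcomes if r is not o
        )
        if dom:
            labels[o.strategy] = "dominated"
        else:
            undominated.append(o)
    for o in undominated:
        co, qo = F(o.lifetime_cost), F(o.lifetime_qaly)
        ext = False
        rivals = [r for r in undominated if r is not o]
        for j, k in itertools.combinations(rivals, 2):
            qj, qk = F(j.lifetime_qaly), F(k.lifetime_qaly)
            if qj == qk:
                continue
            t = (qo - qj) / (qk - qj)
            if 0 <= t <= 1:
                blend_cost = (1 - t) * F(j.lifetime_cost) + t * F(k.lifetime_cost)
                if blend_cost < co:
                    ext = True
                    break
        labels[o.strategy] = "extended_dominated" if ext else "on_frontier"
    return labels


def random_outcomes(rng, n):
    return [O(f"s{i}", float(rng.uniform(0, 50_000)), float(rng.uniform(5, 15)))
            for i in range(n)]


def test_frontier_two_points_simple_dominance():
    res = dominance_frontier([O("a", 100.0, 2.0), O("b", 200.0, 1.0)])
    assert res.labels == {"a": "on_frontier", "b": "dominated"}


def test_frontier_collinear_middle_point_on_frontier():
    res = dominance_frontier([O("a", 0.0, 0.0), O("b", 100.0, 1.0), O("c", 200.0, 2.0)])
    assert all(lbl == "on_frontier" for lbl in res.labels.values())
    assert res.sequential_icers["b"] == pytest.approx(100.0)
    assert res.sequential_icers["c"] == pytest.approx(100.0)


def test_frontier_rejects_duplicates_and_singletons():
    with pytest.raises(ValueError):
        dominance_frontier([O("a", 1.0, 1.0)])
    with pytest.raises(ValueError):
        dominance_frontier([O("a", 1.0, 1.0), O("a", 2.0, 2.0)])


def test_frontier_matches_oracle_on_random_sets():
    rng = np.random.default_rng(12345)
    for _ in range(400):
        outcomes = random_outcomes(rng, int(rng.integers(2, 7)))
        res = dominance_frontier(outcomes)
        assert res.labels == oracle_labels(outcomes)
        seq = [res.sequential_icers[s] for s in res.frontier[1:]]
        assert all(x < y for x, y in zip(seq, seq[1:]))


@given(st.lists(
    st.tuples(st.floats(0, 5e4), st.floats(5, 15)),
    min_size=2, max_size=6,
))
@settings(max_examples=150, derandomize=True, deadline=None)
def test_frontier_matches_oracle_property(points):
    outcomes = [O(f"s{i}", c, q) for i, (c, q) in enumerate(points)]
    res = dominance_frontier(outcomes)
    assert res.labels == oracle_labels(outcomes)


def test_nmb_maximizer_is_on_frontier():
    rng = np.random.default_rng(99)
    for _ in range(200):
        outcomes = random_outcomes(rng, 6)
        wtp = float(rng.uniform(0, 200_000))
        res = dominance_frontier(outcomes)
        best = max(outcomes, key=lambda o: nmb(o, wtp))
        assert res.labels[best.strategy] == "on_frontier"


def test_results_table_layout(ge_us):
    from cadcea import evaluate_all

    table = results_table(evaluate_all(ge_us), wtp=ge_us.wtp)
    assert list(table.columns) == [
        "strategy", "cost", "qaly", "icer_vs_reference", "nmb",
        "value_class", "frontier",
    ]
    assert len(table) == 5
    assert (table["cost"].diff().dropna() >= 0).all()  # ordered by cost
    ref_row = table[table["strategy"] == "no_imaging"].iloc[0]
    assert ref_row["icer_vs_reference"] == "reference"
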