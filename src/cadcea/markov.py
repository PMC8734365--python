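"""Diagnostic decision tree and four-state Markov cohort engine.

Five strategies for a cohort with suspected obstructive coronary artery
disease are simulated: ``no_imaging``, ``cmr``, ``spect``, ``ccta`` and
immediate ``ica``.  Noninvasive imaging routes test-positives to invasive
coronary angiography (ICA, treated as a perfect reference test); ICA-positive
patients receive medical therapy plus revascularization for a configurable
fraction.  A share of false negatives (58% by default) returns with
escalating symptoms within the first year and is rerouted through ICA and
treatment, i.e. experiences the same outcomes as true positives.

After the diagnostic year the cohort cycles annually through four health
states — no MACE history, one MACE, more than one MACE, and death — with
occupancy tagged by disease/treatment status (no CAD, treated CAD, untreated
CAD).  Cycle rewards (utilities and state costs) accrue at cycle start and
are discounted at ``(1 + r)^-t`` with the first cycle undiscounted; acute
MACE costs accrue in the event cycle.

All arithmetic is array-native: every sampled parameter may be a scalar or
an ``(n,)`` vector, so a probabilistic sensitivity analysis with tens of
thousands of draws runs as one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .scenarios import CohortParams, Scenario, TestProfile

__all__ = [
    "STRATEGIES",
    "STATUSES",
    "HEALTH_STATES",
    "DiagnosticPartition",
    "StateDistribution",
    "StrategyOutcome",
    "MarkovRunResult",
    "classify_cohort",
    "first_year_pathway",
    "step_markov",
    "run_markov",
    "evaluate_strategy",
    "evaluate_all",
    "evaluate_batch",
]

STRATEGIES = ("no_imaging", "cmr", "spect", "ccta", "ica")
IMAGING_STRATEGIES = ("cmr", "spect", "ccta")
STATUSES = ("no_cad", "treated_cad", "untreated_cad")
HEALTH_STATES = ("no_mace", "one_mace", "multi_mace", "dead")
_ALIVE = ("no_mace", "one_mace", "multi_mace")

_CONSERVATION_TOL = 1e-12


@dataclass(frozen=True)
class DiagnosticPartition:
    """Cohort split by true disease status and test result."""

    tp: float
    fn: float
    fp: float
    tn: float

    @property
    def prevalence(self) -> float:
        return self.tp + self.fn


@dataclass
class StateDistribution:
    """Cohort occupancy over health states, tagged by disease/treatment status.

    ``occupancy`` maps ``(status, health_state)`` for the alive states plus
    the untagged absorbing key ``"dead"``.
    """

    occupancy: dict

    @classmethod
    def from_arrays(cls, occ: np.ndarray, dead: float) -> "StateDistribution":
        d = {
            (s, h): float(occ[i, j])
            for i, s in enumerate(STATUSES)
            for j, h in enumerate(_ALIVE)
        }
        d["dead"] = float(dead)
        return cls(d)

    def to_arrays(self) -> tuple[np.ndarray, float]:
        occ = np.zeros((len(STATUSES), len(_ALIVE)))
        for i, s in enumerate(STATUSES):
            for j, h in enumerate(_ALIVE):
                occ[i, j] = self.occupancy.get((s, h), 0.0)
        return occ, float(self.occupancy.get("dead", 0.0))

    def total(self) -> float:
        return float(sum(self.occupancy.values()))

    def check(self) -> None:
        total = self.total()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy must sum to 1 (got {total!r})")
        if any(v < -1e-12 for v in self.occupancy.values()):
            raise ValueError("occupancy fractions must be nonnegative")


@dataclass(frozen=True)
class StrategyOutcome:
    """Lifetime discounted cost and QALYs for one diagnostic strategy."""

    strategy: str
    lifetime_cost: float
    lifetime_qaly: float


@dataclass
class MarkovRunResult:
    lifetime_cost: float
    lifetime_qaly: float
    trace: pd.DataFrame | None = None

    def __iter__(self):
        return iter((self.lifetime_cost, self.lifetime_qaly))


def _check_prob(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1]")


def classify_cohort(prevalence, test: TestProfile) -> DiagnosticPartition:
    """Split the cohort into TP/FN/FP/TN fractions for one noninvasive test."""
    _check_prob("prevalence", prevalence)
    _check_prob("sensitivity", test.sensitivity)
    _check_prob("specificity", test.specificity)
    tp = prevalence * test.sensitivity
    fn = prevalence * (1.0 - test.sensitivity)
    fp = (1.0 - prevalence) * (1.0 - test.specificity)
    tn = (1.0 - prevalence) * test.specificity
    return DiagnosticPartition(tp=tp, fn=fn, fp=fp, tn=tn)


def _revasc_unit_cost(s: Scenario, cabg_cost, pci_cost):
    mix = s.cabg_share * cabg_cost + (1.0 - s.cabg_share) * pci_cost
    return s.revascularization_fraction * mix


def _pathway_arrays(params: Mapping[str, np.ndarray], s: Scenario, strategy: str,
                    partition: DiagnosticPartition | None = None):
    """Year-0 decision tree: returns (occ, dead, cost, qaly) as arrays.

    ``occ`` has shape ``(..., 3 statuses, 3 alive states)``; the whole cohort
    starts alive in the no-MACE state, tagged treated/untreated/no-CAD by the
    diagnostic pathway.
    """
    p = np.asarray(params["prevalence"], dtype=float)
    ica = np.asarray(params["ica_cost"], dtype=float)
    treat = _revasc_unit_cost(s, np.asarray(params["cabg_cost"], dtype=float),
                              np.asarray(params["pci_cost"], dtype=float))
    med = s.medical_therapy_annual_cost
    ret = s.fn_return_prob

    if strategy in IMAGING_STRATEGIES:
        if partition is None:
            se = np.asarray(params[f"{strategy}_sensitivity"], dtype=float)
            sp = np.asarray(params[f"{strategy}_specificity"], dtype=float)
            tp = p * se
            fn = p * (1.0 - se)
            fp = (1.0 - p) * (1.0 - sp)
            tn = (1.0 - p) * sp
        else:
            tp, fn, fp, tn = (np.asarray(x, dtype=float)
                              for x in (partition.tp, partition.fn,
                                        partition.fp, partition.tn))
        test_cost = np.asarray(params[f"{strategy}_cost"], dtype=float)
        treated = tp + ret * fn
        untreated = (1.0 - ret) * fn
        no_cad = fp + tn
        cost = (test_cost
                + ica * (tp + fp + ret * fn)
                + (treat + med) * treated)
    elif strategy == "ica":
        treated = np.asarray(p, dtype=float)
        untreated = np.zeros_like(treated)
        no_cad = 1.0 - treated
        cost = ica + (treat + med) * treated
    elif strategy == "no_imaging":
        treated = ret * p
        untreated = (1.0 - ret) * p
        no_cad = 1.0 - p
        cost = (ica + treat + med) * treated
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")

    shape = np.broadcast_shapes(np.shape(no_cad), np.shape(treated),
                                np.shape(untreated), np.shape(cost))
    occ = np.zeros(shape + (3, 3))
    occ[..., 0, 0] = no_cad
    occ[..., 1, 0] = treated
    occ[..., 2, 0] = untreated
    dead = np.zeros(shape)
    qaly = np.broadcast_to(np.asarray(params["utility_no_mace"], dtype=float),
                           shape).copy()
    cost = np.broadcast_to(cost, shape).copy()
    return occ, dead, cost, qaly


def first_year_pathway(partition: DiagnosticPartition | None, s: Scenario,
                       strategy: str):
    """Run the diagnostic year and return ``(StateDistribution, cost, qaly)``.

    For the imaging strategies a :class:`DiagnosticPartition` must be given
    (normally from :func:`classify_cohort`); ``ica`` and ``no_imaging``
    bypass noninvasive testing and may pass ``None``.
    """
    if strategy in IMAGING_STRATEGIES and partition is None:
        raise ValueError(f"strategy {strategy!r} requires a DiagnosticPartition")
    params = s.parameter_means()
    occ, dead, cost, qaly = _pathway_arrays(params, s, strategy, partition)
    dist = StateDistribution.from_arrays(occ, float(dead))
    return dist, float(cost), float(qaly)


def _mortality_interp(cp: CohortParams):
    ages = np.array(sorted(cp.background_mortality), dtype=float)
    qs = np.array([cp.background_mortality[a] for a in sorted(cp.background_mortality)],
                  dtype=float)

    def q_at(age: float) -> float:
        if age < ages[0] - 1e-9 or age > ages[-1] + 1e-9:
            raise ValueError(
                f"age {age} outside background mortality table "
                f"[{ages[0]}, {ages[-1]}]"
            )
        return float(np.interp(age, ages, qs))

    return q_at


def _transition(occ: np.ndarray, dead: np.ndarray, rates, multiplier: float,
                fatality: float, q: float):
    """One annual cycle of state transitions.

    ``rates`` is the per-status first-MACE probability array of shape
    ``(..., 3)``; recurrent events from MACE-history states occur at
    ``multiplier`` times the status rate (capped at 1).  Returns the new
    occupancy, new dead fraction, and the total MACE event flow (used for
    acute event costing).
    """
    level_mult = np.array([1.0, multiplier, multiplier])
    p_event = np.clip(rates[..., :, None] * level_mult, 0.0, 1.0)
    events = occ * p_event
    ev_dead = events * fatality
    ev_surv = events - ev_dead

    occ2 = occ - events
    occ2 = occ2.copy()
    occ2[..., 1] += ev_surv[..., 0]
    occ2[..., 2] += ev_surv[..., 1] + ev_surv[..., 2]

    dead2 = dead + ev_dead.sum(axis=(-1, -2))
    alive = occ2.sum(axis=(-1, -2))
    occ3 = occ2 * (1.0 - q)
    dead3 = dead2 + alive * q
    return occ3, dead3, events.sum(axis=(-1, -2))


def _status_rates(params: Mapping[str, np.ndarray], shape) -> np.ndarray:
    return np.stack(
        [np.broadcast_to(np.asarray(params[k], dtype=float), shape)
         for k in ("first_mace_prob_no_cad", "first_mace_prob_treated_cad",
                   "first_mace_prob_untreated_cad")],
        axis=-1,
    )


def step_markov(d: StateDistribution, cp: CohortParams, age: float) -> StateDistribution:
    """Advance a cohort distribution by one annual cycle."""
    d.check()
    occ, dead = d.to_arrays()
    q = _mortality_interp(cp)(age)
    rates = np.array([
        cp.annual_first_mace_prob_no_cad,
        cp.annual_first_mace_prob_treated_cad,
        cp.annual_first_mace_prob_untreated_cad,
    ])
    occ2, dead2, _ = _transition(occ, dead, rates, cp.recurrent_mace_multiplier,
                                 cp.mace_case_fatality, q)
    out = StateDistribution.from_arrays(occ2, float(dead2))
    assert abs(out.total() - d.total()) < _CONSERVATION_TOL * 10
    return out


def _run_arrays(occ: np.ndarray, dead: np.ndarray,
                params: Mapping[str, np.ndarray], s: Scenario,
                start_age: float, t0: int,
                trace: list | None = None):
    """Cycle the cohort from ``start_age`` to the horizon, accruing rewards.

    Rewards of cycle ``t`` (0-based from ``start_age``) are discounted by
    ``(1 + r)^-(t + t0)``; acute MACE costs accrue with the cycle in which the
    event occurs.  Returns discounted (cost, qaly) arrays.
    """
    cp = s.cohort_params
    q_at = _mortality_interp(cp)
    n_cycles = int(np.ceil(s.horizon_age - start_age))
    if n_cycles <= 0:
        raise ValueError("horizon_age must exceed the starting age")

    shape = occ.shape[:-2]
    u_no = np.broadcast_to(np.asarray(params["utility_no_mace"], dtype=float), shape)
    u_mace = np.broadcast_to(np.asarray(params["utility_mace"], dtype=float), shape)
    c_acute = np.broadcast_to(np.asarray(params["mace_first_year_cost"], dtype=float), shape)
    c_chronic = np.broadcast_to(np.asarray(params["mace_subsequent_annual_cost"], dtype=float), shape)
    med = s.medical_therapy_annual_cost
    rates = _status_rates(params, shape)

    disc = 1.0 / (1.0 + s.discount_rate)
    total_cost = np.zeros(shape)
    total_qaly = np.zeros(shape)
    for t in range(n_cycles):
        age_t = start_age + t
        by_state = occ.sum(axis=-2)                      # (..., 3 alive states)
        in_mace = by_state[..., 1] + by_state[..., 2]
        qaly_t = by_state[..., 0] * u_no + in_mace * u_mace
        cost_t = med * occ[..., 1, :].sum(axis=-1) + c_chronic * in_mace

        occ, dead, events = _transition(
            occ, dead, rates, cp.recurrent_mace_multiplier,
            cp.mace_case_fatality, q_at(age_t),
        )
        cost_t = cost_t + c_acute * events

        w = disc ** (t + t0)
        total_cost += w * cost_t
        total_qaly += w * qaly_t
        if trace is not None:
            trace.append((t, age_t, occ.copy(), float(np.asarray(dead)),
                          float(np.asarray(cost_t)), float(np.asarray(qaly_t)),
                          float(np.asarray(w * cost_t)), float(np.asarray(w * qaly_t))))
    return total_cost, total_qaly


def run_markov(initial: StateDistribution, s: Scenario, *,
               start_age: float | None = None, t0: int = 0,
               collect_trace: bool = False) -> MarkovRunResult:
    """Run annual cycles from ``start_age`` (default the scenario age) to the
    horizon and return discounted lifetime cost and QALYs.

    With ``collect_trace=True`` a per-cycle cohort trace is attached as a
    :class:`pandas.DataFrame` (exportable with ``.to_csv``).
    """
    initial.check()
    occ, dead = initial.to_arrays()
    params = s.parameter_means()
    start = s.age if start_age is None else start_age
    rows: list | None = [] if collect_trace else None
    cost, qaly = _run_arrays(occ, dead, params, s, start, t0, trace=rows)
    trace_df = None
    if rows is not None:
        records = []
        for (t, age_t, occ_t, dead_t, c, q, dc, dq) in rows:
            rec = {"cycle": t, "age": age_t}
            for i, st in enumerate(STATUSES):
                for j, h in enumerate(_ALIVE):
                    rec[f"{st}.{h}"] = occ_t[i, j]
            rec["dead"] = dead_t
            rec["cycle_cost"] = c
            rec["cycle_qaly"] = q
            rec["discounted_cost"] = dc
            rec["discounted_qaly"] = dq
            records.append(rec)
        trace_df = pd.DataFrame.from_records(records)
    return MarkovRunResult(float(cost), float(qaly), trace_df)


def _evaluate_arrays(s: Scenario, params: Mapping[str, np.ndarray], strategy: str):
    occ, dead, cost0, qaly0 = _pathway_arrays(params, s, strategy)
    cost, qaly = _run_arrays(occ, dead, params, s, start_age=s.age + 1.0, t0=1)
    return cost0 + cost, qaly0 + qaly


def evaluate_strategy(s: Scenario, strategy: str) -> StrategyOutcome:
    """Lifetime discounted cost and QALYs for one strategy under a scenario."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    cost, qaly = _evaluate_arrays(s, s.parameter_means(), strategy)
    return StrategyOutcome(strategy, float(cost), float(qaly))


def evaluate_all(s: Scenario) -> list[StrategyOutcome]:
    """Evaluate the five strategies in stable order."""
    return [evaluate_strategy(s, strategy) for strategy in STRATEGIES]


def evaluate_batch(s: Scenario, params: Mapping[str, np.ndarray]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Vectorized evaluation of all strategies for a batch of parameter draws.

    ``params`` maps each sampled parameter name to an ``(n,)`` array (scalars
    broadcast).  Returns ``{strategy: (cost, qaly)}`` arrays — the engine
    behind the probabilistic sensitivity analysis.
    """
    return {strategy: _evaluate_arrays(s, params, strategy)
            for strategy in STRATEGIES}
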