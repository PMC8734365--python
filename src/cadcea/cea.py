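"""Cost-effectiveness metrics: ICERs, dominance frontier, NMB, value classes.

Conventions follow standard CEA practice.  Pairwise comparisons report the
incremental cost-effectiveness ratio Δcost/ΔQALY when the comparator buys
health for money (or loses both, in which case the ratio is reported in the
reference-favouring direction), and the markers ``dominated`` / ``dominant``
/ ``equivalent`` otherwise.  The efficiency frontier removes strictly and
weakly dominated strategies first, then extended-dominated ones (a strategy
whose sequential ICER exceeds that of the next more effective frontier
member).  Value classes use the ACC/AHA bands: below $50,000/QALY high
value, $50,000–150,000/QALY intermediate, above low value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .markov import StrategyOutcome
from .scenarios import AnalysisSettings

__all__ = [
    "ComparisonResult",
    "FrontierResult",
    "icer",
    "dominance_frontier",
    "nmb",
    "incremental_nmb",
    "value_class",
    "results_table",
    "write_report",
]

DOMINATED = "dominated"
DOMINANT = "dominant"
EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise incremental comparison of ``comparator`` against ``reference``."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    marker: str | None
    #: "comparator_vs_reference" for the usual ratio; "reference_vs_comparator"
    #: when both deltas are negative and the ratio favours the reference.
    direction: str = "comparator_vs_reference"

    @property
    def label(self) -> str:
        if self.marker is not None:
            return self.marker
        suffix = " (reference-favoring)" if self.direction == "reference_vs_comparator" else ""
        return f"{self.icer:,.0f}/QALY{suffix}"


@dataclass
class FrontierResult:
    """Strategies ordered by cost with frontier labels and sequential ICERs."""

    ordered: list[StrategyOutcome]
    labels: dict[str, str]          # strategy -> on_frontier | dominated | extended_dominated
    frontier: list[str]             # on-frontier strategies, by increasing cost
    sequential_icers: dict[str, float]  # frontier strategy -> ICER vs previous member


def icer(reference: StrategyOutcome, comparator: StrategyOutcome) -> ComparisonResult:
    """Incremental comparison ``comparator - reference``."""
    dc = comparator.lifetime_cost - reference.lifetime_cost
    dq = comparator.lifetime_qaly - reference.lifetime_qaly
    base = dict(reference=reference.strategy, comparator=comparator.strategy,
                delta_cost=dc, delta_qaly=dq)
    if dc == 0.0 and dq == 0.0:
        return ComparisonResult(icer=None, marker=EQUIVALENT, **base)
    if dq <= 0.0 and dc >= 0.0:
        return ComparisonResult(icer=None, marker=DOMINATED, **base)
    if dq >= 0.0 and dc <= 0.0:
        return ComparisonResult(icer=None, marker=DOMINANT, **base)
    if dq > 0.0 and dc > 0.0:
        return ComparisonResult(icer=dc / dq, marker=None, **base)
    # both negative: the reference buys health for money relative to the
    # comparator; report the (positive) reference-favoring ratio.
    return ComparisonResult(icer=dc / dq, marker=None,
                            direction="reference_vs_comparator", **base)


def _weakly_dominated(o: StrategyOutcome, others: list[StrategyOutcome]) -> bool:
    for other in others:
        if other is o:
            continue
        if (other.lifetime_cost <= o.lifetime_cost
                and other.lifetime_qaly >= o.lifetime_qaly
                and (other.lifetime_cost < o.lifetime_cost
                     or other.lifetime_qaly > o.lifetime_qaly)):
            return True
    return False


def dominance_frontier(outcomes: list[StrategyOutcome]) -> FrontierResult:
    """Label strategies on/off the cost-effectiveness efficiency frontier."""
    if len(outcomes) < 2:
        raise ValueError("need at least two strategy outcomes")
    names = [o.strategy for o in outcomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names in outcomes")

    ordered = sorted(outcomes,
                     key=lambda o: (o.lifetime_cost, o.lifetime_qaly, o.strategy))
    labels: dict[str, str] = {}
    survivors = [o for o in ordered if not _weakly_dominated(o, ordered)]
    for o in ordered:
        if o not in survivors:
            labels[o.strategy] = "dominated"

    # exact-duplicate (cost, qaly) points act as one frontier node; group
    # them so extended dominance sees each point once.
    groups: dict[tuple[float, float], list[StrategyOutcome]] = {}
    for o in survivors:
        groups.setdefault((o.lifetime_cost, o.lifetime_qaly), []).append(o)
    reps = [members[0] for members in groups.values()]
    reps.sort(key=lambda o: (o.lifetime_cost, o.lifetime_qaly, o.strategy))

    # extended dominance: drop nodes whose sequential ICER exceeds the ICER
    # of the next more effective node, until the sequence is nondecreasing
    # (collinear points stay on the frontier with equal adjacent ICERs).
    while len(reps) > 2:
        icers = [
            (reps[i + 1].lifetime_cost - reps[i].lifetime_cost)
            / (reps[i + 1].lifetime_qaly - reps[i].lifetime_qaly)
            for i in range(len(reps) - 1)
        ]
        removed = False
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                dropped = reps[i + 1]
                for member in groups[(dropped.lifetime_cost, dropped.lifetime_qaly)]:
                    labels[member.strategy] = "extended_dominated"
                del reps[i + 1]
                removed = True
                break
        if not removed:
            break

    seq: dict[str, float] = {}
    for i in range(1, len(reps)):
        dq = reps[i].lifetime_qaly - reps[i - 1].lifetime_qaly
        dc = reps[i].lifetime_cost - reps[i - 1].lifetime_cost
        value = dc / dq if dq != 0.0 else math.inf
        for member in groups[(reps[i].lifetime_cost, reps[i].lifetime_qaly)]:
            seq[member.strategy] = value
    frontier_names = []
    for rep in reps:
        for member in groups[(rep.lifetime_cost, rep.lifetime_qaly)]:
            labels[member.strategy] = "on_frontier"
            frontier_names.append(member.strategy)
    return FrontierResult(
        ordered=ordered,
        labels=labels,
        frontier=frontier_names,
        sequential_icers=seq,
    )


def nmb(o: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit: WTP × QALYs − cost."""
    if wtp < 0.0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return wtp * o.lifetime_qaly - o.lifetime_cost


def incremental_nmb(o: StrategyOutcome, reference: StrategyOutcome, wtp: float) -> float:
    """NMB of ``o`` minus NMB of ``reference``; positive iff ``o`` preferred."""
    return nmb(o, wtp) - nmb(reference, wtp)


def value_class(icer_value: float, settings: AnalysisSettings | None = None) -> str:
    """ACC/AHA-style value class for a nonnegative cost-per-QALY ratio."""
    settings = settings or AnalysisSettings()
    if not math.isfinite(icer_value) or icer_value < 0.0:
        raise ValueError(
            "value_class expects a finite, nonnegative ICER; use dominance "
            "markers for dominated/dominant comparisons"
        )
    if icer_value < settings.high_value_threshold:
        return "high"
    if icer_value <= settings.low_value_threshold:
        return "intermediate"
    return "low"


def results_table(outcomes: list[StrategyOutcome], wtp: float,
                  settings: AnalysisSettings | None = None,
                  reference: str = "no_imaging") -> pd.DataFrame:
    """Strategy-level report: cost, QALYs, ICER vs reference, NMB, value class,
    frontier label — one row per strategy, ordered by cost."""
    settings = settings or AnalysisSettings()
    by_name = {o.strategy: o for o in outcomes}
    if reference not in by_name:
        raise ValueError(f"reference strategy {reference!r} not among outcomes")
    ref = by_name[reference]
    frontier = dominance_frontier(outcomes)
    rows = []
    for o in frontier.ordered:
        comp = icer(ref, o)
        if o.strategy == reference:
            icer_repr: str | float = "reference"
            vclass = ""
        elif comp.marker is not None:
            icer_repr = comp.marker
            vclass = "high" if comp.marker == DOMINANT else ("low" if comp.marker == DOMINATED else "")
        else:
            icer_repr = comp.icer
            vclass = value_class(comp.icer, settings)
        rows.append({
            "strategy": o.strategy,
            "cost": o.lifetime_cost,
            "qaly": o.lifetime_qaly,
            "icer_vs_reference": icer_repr,
            "nmb": nmb(o, wtp),
            "value_class": vclass,
            "frontier": frontier.labels[o.strategy],
        })
    return pd.DataFrame(rows)


def write_report(table: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    """Persist a results table as CSV or JSON."""
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(table.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
    return path
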