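"""One-way threshold analysis.

Finds the value of a single scalar input at which two strategies swap
cost-effectiveness ranking, i.e. the root of their incremental net monetary
benefit as a function of that input at a given willingness-to-pay.  The
search runs by bisection (to a relative tolerance of 1e-4) against either
the full Markov engine or a fitted metamodel; monotonicity of the NMB
difference is screened on a coarse grid and a warning is issued if the
function is not monotone over the bounds (bisection then returns one root).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from typing import Callable

from .cea import incremental_nmb
from .markov import STRATEGIES, evaluate_strategy
from .metamodel import MetamodelSet
from .scenarios import SAMPLED_PARAMETERS, Scenario

__all__ = ["ThresholdResult", "find_threshold"]

_REL_TOL = 1e-4


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    base_value: float
    threshold: float | None     # None when no sign change within bounds
    multiplier: float | None    # threshold / base value
    wtp: float
    strategy_a: str
    strategy_b: str
    engine: str
    bounds: tuple[float, float]
    note: str = ""

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["bounds"] = list(d["bounds"])
        return json.dumps(d, indent=2)


def _resolve_param(s: Scenario, param: str) -> float:
    """Base value of a flat sampled-parameter name or dotted scenario path."""
    if param in SAMPLED_PARAMETERS:
        return s.parameter_means()[param]
    parts = param.split(".")
    obj: object = s
    for p in parts:
        if isinstance(obj, dict):
            obj = obj[p]
        else:
            obj = getattr(obj, p)
    if not isinstance(obj, (int, float)):
        raise ValueError(f"parameter {param!r} is not a scalar scenario field")
    return float(obj)


def _set_param(s: Scenario, param: str, value: float) -> Scenario:
    if param in SAMPLED_PARAMETERS:
        return s.with_parameters({param: value})
    parts = param.split(".")
    if len(parts) == 1:
        return s.replace(**{param: value})
    if parts[0] == "test_profiles" and len(parts) == 3:
        return s.with_parameters({f"{parts[1]}_{parts[2]}": value})
    if parts[0] == "cohort_params" and len(parts) == 2:
        cp = dataclasses.replace(s.cohort_params, **{parts[1]: value})
        return s.replace(cohort_params=cp)
    raise ValueError(f"cannot set parameter path {param!r}")


def _nmb_difference_fn(s: Scenario, param: str, strategy_a: str, strategy_b: str,
                       wtp: float, engine: str,
                       metamodel: MetamodelSet | None) -> Callable[[float], float]:
    if engine == "markov":
        def g(x: float) -> float:
            sx = _set_param(s, param, x)
            a = evaluate_strategy(sx, strategy_a)
            b = evaluate_strategy(sx, strategy_b)
            return incremental_nmb(a, b, wtp)
        return g
    if engine == "metamodel":
        if metamodel is None:
            raise ValueError("metamodel engine requires a fitted MetamodelSet")
        if param not in SAMPLED_PARAMETERS:
            raise ValueError(
                f"metamodel engine can only vary sampled parameters, not {param!r}"
            )
        base_inputs = s.parameter_means()

        def g(x: float) -> float:
            inputs = dict(base_inputs)
            inputs[param] = x
            preds = metamodel.predict_strategies(inputs)
            return incremental_nmb(preds[strategy_a], preds[strategy_b], wtp)
        return g
    raise ValueError(f"unknown engine {engine!r}; expected 'markov' or 'metamodel'")


def find_threshold(s: Scenario, param: str, bounds: tuple[float, float],
                   strategy_a: str, strategy_b: str, *,
                   wtp: float | None = None, engine: str = "metamodel",
                   metamodel: MetamodelSet | None = None,
                   rel_tol: float = _REL_TOL,
                   grid_points: int = 10) -> ThresholdResult:
    """Bisection search for the input value equalizing two strategies' NMB."""
    for strat in (strategy_a, strategy_b):
        if strat not in STRATEGIES:
            raise ValueError(f"unknown strategy {strat!r}")
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    wtp = s.wtp if wtp is None else float(wtp)
    base = _resolve_param(s, param)
    g = _nmb_difference_fn(s, param, strategy_a, strategy_b, wtp, engine, metamodel)

    grid = [lo + (hi - lo) * i / (grid_points - 1) for i in range(grid_points)]
    values = [g(x) for x in grid]
    sign_changes = sum(
        1 for i in range(len(values) - 1)
        if (values[i] > 0) != (values[i + 1] > 0)
    )
    if sign_changes > 1:
        warnings.warn(
            f"NMB difference is not monotone in {param!r} over {bounds}; "
            "bisection returns one root", stacklevel=2
        )

    f_lo, f_hi = values[0], values[-1]
    result = dict(parameter=param, base_value=base, wtp=wtp,
                  strategy_a=strategy_a, strategy_b=strategy_b,
                  engine=engine, bounds=(lo, hi))
    if (f_lo > 0) == (f_hi > 0):
        return ThresholdResult(threshold=None, multiplier=None,
                               note="none in bounds", **result)
    a, b, fa = lo, hi, f_lo
    while (b - a) > rel_tol * max(abs(a), abs(b), 1e-300):
        mid = 0.5 * (a + b)
        fm = g(mid)
        if fm == 0.0:
            a = b = mid
            break
        if (fm > 0) == (fa > 0):
            a, fa = mid, fm
        else:
            b = mid
    root = 0.5 * (a + b)
    return ThresholdResult(
        threshold=root,
        multiplier=(root / base) if base != 0.0 else None,
        **result,
    )
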