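"""Probabilistic sensitivity analysis (second-order Monte Carlo).

Each sampled parameter gets an uncertainty distribution around its scenario
value: beta (method-of-moments) for probabilities and utilities, gamma for
costs, with a default 15% coefficient of variation; any parameter may be
overridden or held fixed.  Draws are evaluated through the vectorized Markov
engine, and each record pairs the parameter vector with the ten model
outputs that the metamodel emulates: the no-imaging lifetime discounted QALY
and cost, and the incremental QALY and cost versus no imaging for the CMR,
SPECT, CCTA and immediate-ICA strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import evaluate_batch
from .scenarios import (
    COST_PARAMETERS,
    PROBABILITY_PARAMETERS,
    SAMPLED_PARAMETERS,
    AnalysisSettings,
    Scenario,
)

__all__ = [
    "OUTPUT_NAMES",
    "ParameterDistribution",
    "PSARecord",
    "build_distributions",
    "sample_parameters",
    "run_psa",
    "outputs_from_strategy_results",
    "records_to_frames",
    "frames_to_records",
    "save_records_csv",
    "load_records_csv",
]

logger = logging.getLogger(__name__)

#: The ten emulated outputs, in canonical order.
OUTPUT_NAMES = (
    "no_imaging_qaly", "no_imaging_cost",
    "cmr_inc_qaly", "cmr_inc_cost",
    "spect_inc_qaly", "spect_inc_cost",
    "ccta_inc_qaly", "ccta_inc_cost",
    "ica_inc_qaly", "ica_inc_cost",
)

DEFAULT_CV = 0.15


@dataclass(frozen=True)
class ParameterDistribution:
    """Uncertainty spec for one sampled parameter.

    ``spread`` is a coefficient of variation (sd/mean) for the non-fixed
    families.  Beta distributions are resolved by method of moments and are
    only valid for [0, 1]-valued parameters; gamma for nonnegative ones.
    """

    name: str
    family: str  # beta | gamma | normal | fixed
    mean: float
    spread: float = DEFAULT_CV

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "normal", "fixed"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.family != "fixed" and not self.spread > 0.0:
            raise ValueError(f"{self.name}: spread must be > 0 unless fixed")

    def beta_shapes(self) -> tuple[float, float]:
        m, sd = self.mean, self.spread * self.mean
        var = sd * sd
        if not (0.0 < m < 1.0):
            raise ValueError(f"{self.name}: beta requires mean in (0, 1), got {m}")
        if var >= m * (1.0 - m):
            raise ValueError(
                f"{self.name}: spread {self.spread} too large for a beta "
                f"distribution with mean {m}"
            )
        k = m * (1.0 - m) / var - 1.0
        return m * k, (1.0 - m) * k

    def gamma_shapes(self) -> tuple[float, float]:
        cv = self.spread
        return 1.0 / (cv * cv), self.mean * cv * cv  # shape, scale


@dataclass(frozen=True)
class PSARecord:
    """One sampled parameter vector with its ten model outputs."""

    draw: Mapping[str, float]
    outputs: Mapping[str, float]


def build_distributions(
    s: Scenario,
    overrides: Mapping[str, ParameterDistribution] | None = None,
    default_cv: float = DEFAULT_CV,
) -> dict[str, ParameterDistribution]:
    """Resolve the full per-parameter uncertainty spec for a scenario.

    Defaults: beta for probabilities/utilities, gamma for costs, all at
    ``default_cv``; parameters whose scenario value is exactly 0 or 1 are
    held fixed (their beta/gamma moments would be degenerate).
    """
    means = s.parameter_means()
    spec: dict[str, ParameterDistribution] = {}
    for name in SAMPLED_PARAMETERS:
        mean = means[name]
        if overrides and name in overrides:
            d = overrides[name]
            if d.name != name:
                d = replace(d, name=name)
            spec[name] = d
            continue
        if name in PROBABILITY_PARAMETERS:
            family = "beta" if 0.0 < mean < 1.0 else "fixed"
        elif name in COST_PARAMETERS:
            family = "gamma" if mean > 0.0 else "fixed"
        else:  # pragma: no cover - all sampled params are probs or costs
            family = "normal"
        spec[name] = ParameterDistribution(name, family, mean, default_cv)
        if family == "beta":
            spec[name].beta_shapes()  # fail fast if infeasible
    return spec


#: Pairwise ordering invariants the joint draw must satisfy (lower, upper);
#: enforced by re-drawing violating rows, i.e. conditioning the independent
#: product distribution on the ordered region.  Applied only when the
#: scenario means themselves respect the ordering.
ORDERED_PAIRS = (
    ("utility_mace", "utility_no_mace"),
    ("first_mace_prob_treated_cad", "first_mace_prob_untreated_cad"),
)


def _draw_one(rng: np.random.Generator, d: ParameterDistribution, n: int) -> np.ndarray:
    if d.family == "fixed":
        return np.full(n, d.mean)
    if d.family == "beta":
        a, b = d.beta_shapes()
        return rng.beta(a, b, size=n)
    if d.family == "gamma":
        shape, scale = d.gamma_shapes()
        return rng.gamma(shape, scale, size=n)
    return rng.normal(d.mean, d.spread * abs(d.mean), size=n)


def sample_parameters(
    spec: Mapping[str, ParameterDistribution], n: int, seed: int
) -> dict[str, np.ndarray]:
    """Draw ``n`` independent parameter vectors; reproducible given ``seed``.

    Draws are independent across parameters and records, except that rows
    violating a modelled ordering (MACE-state utility above the event-free
    utility; treated above untreated MACE risk) are redrawn, which conditions
    the joint distribution on the ordered region.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for name in sorted(spec):
        draws[name] = _draw_one(rng, spec[name], n)
    for low, high in ORDERED_PAIRS:
        if low not in spec or high not in spec:
            continue
        if spec[low].mean > spec[high].mean:
            continue  # user deliberately inverted the means; leave draws alone
        for _ in range(1000):
            bad = np.flatnonzero(draws[low] > draws[high])
            if bad.size == 0:
                break
            draws[low][bad] = _draw_one(rng, spec[low], bad.size)
            draws[high][bad] = _draw_one(rng, spec[high], bad.size)
        else:  # pragma: no cover - implies a near-degenerate spec
            raise RuntimeError(
                f"could not enforce {low} <= {high} after 1000 redraws"
            )
    return draws


def outputs_from_strategy_results(
    results: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> dict[str, np.ndarray]:
    """Map per-strategy (cost, qaly) arrays to the ten emulated outputs."""
    base_cost, base_qaly = results["no_imaging"]
    out = {
        "no_imaging_qaly": np.asarray(base_qaly, dtype=float),
        "no_imaging_cost": np.asarray(base_cost, dtype=float),
    }
    for strat in ("cmr", "spect", "ccta", "ica"):
        cost, qaly = results[strat]
        out[f"{strat}_inc_qaly"] = np.asarray(qaly - base_qaly, dtype=float)
        out[f"{strat}_inc_cost"] = np.asarray(cost - base_cost, dtype=float)
    return {k: out[k] for k in OUTPUT_NAMES}


def _make_records(draws: Mapping[str, np.ndarray],
                  outputs: Mapping[str, np.ndarray],
                  indices: Iterable[int]) -> list[PSARecord]:
    names = sorted(draws)
    return [
        PSARecord(
            draw={nm: float(draws[nm][i]) for nm in names},
            outputs={nm: float(outputs[nm][i]) for nm in OUTPUT_NAMES},
        )
        for i in indices
    ]


def run_psa(
    s: Scenario,
    settings: AnalysisSettings | None = None,
    overrides: Mapping[str, ParameterDistribution] | None = None,
) -> tuple[list[PSARecord], list[PSARecord]]:
    """Sample, simulate, and split records into (train, test) sets.

    ``n_train + n_test`` draws come from a single seeded stream, evaluated in
    one vectorized pass through the Markov engine; the first ``n_train``
    records form the training set, the remainder the disjoint test set.
    Draws whose outputs are non-finite are logged by index and dropped; the
    run fails if more than 0.1% of draws are affected.
    """
    settings = settings or AnalysisSettings()
    spec = build_distributions(s, overrides)
    n = settings.n_train + settings.n_test
    logger.info("PSA on scenario %s: %d draws (train %d / test %d), seed %d",
                s.name, n, settings.n_train, settings.n_test, settings.seed)
    draws = sample_parameters(spec, n, settings.seed)
    outputs = outputs_from_strategy_results(evaluate_batch(s, draws))

    ok = np.ones(n, dtype=bool)
    for name in OUTPUT_NAMES:
        ok &= np.isfinite(outputs[name])
    failed = np.flatnonzero(~ok)
    if failed.size:
        logger.warning("PSA: %d failed draw(s) at indices %s",
                       failed.size, failed.tolist())
        if failed.size > 0.001 * n:
            raise RuntimeError(
                f"{failed.size} of {n} PSA draws failed (> 0.1%); "
                f"first failing indices: {failed[:10].tolist()}"
            )
    idx = np.flatnonzero(ok)
    train_idx = [int(i) for i in idx if i < settings.n_train]
    test_idx = [int(i) for i in idx if i >= settings.n_train]
    train = _make_records(draws, outputs, train_idx)
    test = _make_records(draws, outputs, test_idx)
    logger.info("PSA complete: %d train / %d test records", len(train), len(test))
    return train, test


def records_to_frames(records: Sequence[PSARecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into a parameter frame and an output frame (aligned rows)."""
    if not records:
        raise ValueError("no records")
    X = pd.DataFrame([dict(r.draw) for r in records], columns=sorted(records[0].draw))
    Y = pd.DataFrame([dict(r.outputs) for r in records], columns=list(OUTPUT_NAMES))
    return X, Y


def frames_to_records(X: pd.DataFrame, Y: pd.DataFrame) -> list[PSARecord]:
    if len(X) != len(Y):
        raise ValueError("parameter and output frames must have equal length")
    return [
        PSARecord(draw=X.iloc[i].to_dict(), outputs=Y.iloc[i].to_dict())
        for i in range(len(X))
    ]


def save_records_csv(records: Sequence[PSARecord], path: str | Path) -> Path:
    """Flat CSV, one row per draw: parameters then the ten outputs."""
    X, Y = records_to_frames(records)
    df = pd.concat([X, Y], axis=1)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_records_csv(path: str | Path) -> list[PSARecord]:
    df = pd.read_csv(path)
    out_cols = [c for c in OUTPUT_NAMES if c in df.columns]
    if len(out_cols) != len(OUTPUT_NAMES):
        missing = set(OUTPUT_NAMES) - set(out_cols)
        raise ValueError(f"records file missing output column(s): {sorted(missing)}")
    param_cols = [c for c in df.columns if c not in OUTPUT_NAMES]
    return frames_to_records(df[param_cols], df[list(OUTPUT_NAMES)])
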