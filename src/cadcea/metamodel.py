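"""Linear-regression metamodel: the cost-effectiveness calculator.

Ten ordinary-least-squares regressions — one per emulated output (no-imaging
lifetime discounted QALY and cost, and incremental QALY/cost versus no
imaging for CMR, SPECT, CCTA and immediate ICA) — are fitted on PSA
input–output records.  Variable selection is backward elimination: the
regressor with the largest p-value at or above the significance level is
dropped (ties broken by name) and the model refitted until every retained
coefficient is significant; the intercept is always kept.  A held-out test
set yields, per output, the adjusted r² and the percentage deviation —
100 × (mean prediction − mean observation)/mean observation, an
external-calibration metric.

The module follows the statsmodels model/results idiom:
``CostEffectivenessCalculator(records).fit()`` returns a
:class:`MetamodelSet` carrying the coefficients, ``summary()``,
``predict()``, ``validate()`` and JSON round-trip IO.  Thin functional
wrappers (``fit_metamodel`` etc.) are also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .markov import StrategyOutcome
from .psa import OUTPUT_NAMES, PSARecord, records_to_frames
from .scenarios import AnalysisSettings

__all__ = [
    "SCHEMA_VERSION",
    "OutputModel",
    "MetamodelSet",
    "ValidationReport",
    "CostEffectivenessCalculator",
    "fit_metamodel",
    "predict",
    "validate",
    "save_metamodel",
    "load_metamodel",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class OutputModel:
    """One fitted linear predictor: intercept plus retained coefficients."""

    output: str
    intercept: float
    coefficients: Mapping[str, float]
    pvalues: Mapping[str, float] = field(default_factory=dict, compare=False)

    def predict(self, inputs: Mapping[str, float]) -> float:
        value = self.intercept
        for name, coef in self.coefficients.items():
            if name not in inputs:
                raise KeyError(
                    f"missing retained regressor {name!r} for output {self.output!r}"
                )
            value += coef * float(inputs[name])
        return value


@dataclass(frozen=True)
class ValidationRow:
    output: str
    adjusted_r2: float
    percentage_deviation: float | None  # None when the observed mean is zero


@dataclass(frozen=True)
class ValidationReport:
    """Held-out goodness-of-fit: adjusted r² and percentage deviation per output."""

    rows: tuple[ValidationRow, ...]
    n_test: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"output": r.output, "adjusted_r2": r.adjusted_r2,
              "percentage_deviation": r.percentage_deviation} for r in self.rows]
        )

    @property
    def min_adjusted_r2(self) -> float:
        return min(r.adjusted_r2 for r in self.rows)

    @property
    def max_abs_percentage_deviation(self) -> float:
        devs = [abs(r.percentage_deviation) for r in self.rows
                if r.percentage_deviation is not None]
        return max(devs)


@dataclass(frozen=True)
class MetamodelSet:
    """The ten fitted meta-models plus training metadata (a results object)."""

    outputs: Mapping[str, OutputModel]
    candidate_regressors: tuple[str, ...]
    n_train: int
    selection_alpha: float
    seed: int | None = None
    scenario: str | None = None

    def __post_init__(self) -> None:
        missing = set(OUTPUT_NAMES) - set(self.outputs)
        if missing:
            raise ValueError(f"metamodel set missing output(s): {sorted(missing)}")
        for m in self.outputs.values():
            bad = set(m.coefficients) - set(self.candidate_regressors)
            if bad:
                raise ValueError(
                    f"output {m.output!r} retains unknown regressor(s): {sorted(bad)}"
                )

    def predict(self, inputs: Mapping[str, float]) -> dict[str, float]:
        """Evaluate the ten linear predictors at one input vector."""
        return {name: self.outputs[name].predict(inputs) for name in OUTPUT_NAMES}

    def predict_strategies(self, inputs: Mapping[str, float]) -> dict[str, StrategyOutcome]:
        """Reconstruct absolute per-strategy cost/QALY from the ten outputs."""
        out = self.predict(inputs)
        results = {
            "no_imaging": StrategyOutcome(
                "no_imaging", out["no_imaging_cost"], out["no_imaging_qaly"]
            )
        }
        for strat in ("cmr", "spect", "ccta", "ica"):
            results[strat] = StrategyOutcome(
                strat,
                out["no_imaging_cost"] + out[f"{strat}_inc_cost"],
                out["no_imaging_qaly"] + out[f"{strat}_inc_qaly"],
            )
        return results

    def validate(self, test: Sequence[PSARecord]) -> ValidationReport:
        """Score the metamodels on held-out records (adjusted r², % deviation)."""
        X, Y = records_to_frames(test)
        rows = []
        for name in OUTPUT_NAMES:
            m = self.outputs[name]
            y = Y[name].to_numpy()
            yhat = np.full(len(X), m.intercept)
            for reg, coef in m.coefficients.items():
                if reg not in X.columns:
                    raise KeyError(f"test records lack regressor {reg!r}")
                yhat = yhat + coef * X[reg].to_numpy()
            n, k = len(y), len(m.coefficients)
            if n <= k + 1:
                raise ValueError(
                    f"n_test={n} too small for adjusted r² with {k} regressors"
                )
            ss_res = float(np.sum((y - yhat) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
            ybar = float(y.mean())
            dev = None if ybar == 0.0 else 100.0 * (float(yhat.mean()) - ybar) / ybar
            rows.append(ValidationRow(name, adj, dev))
        return ValidationReport(tuple(rows), n_test=len(X))

    def summary(self, report: ValidationReport | None = None) -> str:
        lines = [
            "Cost-effectiveness calculator (linear meta-models)",
            f"  trained on n={self.n_train} PSA records"
            + (f" from scenario '{self.scenario}'" if self.scenario else "")
            + (f", seed={self.seed}" if self.seed is not None else ""),
            f"  backward elimination at alpha={self.selection_alpha}",
            "",
        ]
        for name in OUTPUT_NAMES:
            m = self.outputs[name]
            lines.append(f"{name}: intercept={m.intercept:.6g}, "
                         f"{len(m.coefficients)} retained regressor(s)")
            for reg in sorted(m.coefficients):
                p = m.pvalues.get(reg)
                ptxt = f", p={p:.2e}" if p is not None else ""
                lines.append(f"    {reg:32s} {m.coefficients[reg]:+.6g}{ptxt}")
        if report is not None:
            lines.append("")
            lines.append(f"Validation on n_test={report.n_test}:")
            for r in report.rows:
                dev = ("undefined (zero mean)" if r.percentage_deviation is None
                       else f"{r.percentage_deviation:+.3f}%")
                lines.append(f"    {r.output:20s} adj r2={r.adjusted_r2:.4f}  "
                             f"deviation={dev}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "metadata": {
                "n_train": self.n_train,
                "selection_alpha": self.selection_alpha,
                "seed": self.seed,
                "scenario": self.scenario,
            },
            "candidate_regressors": list(self.candidate_regressors),
            "outputs": {
                name: {
                    "intercept": self.outputs[name].intercept,
                    "coefficients": dict(self.outputs[name].coefficients),
                }
                for name in OUTPUT_NAMES
            },
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


class CostEffectivenessCalculator:
    """Model object: OLS meta-models of the Markov engine's ten outputs.

    Construct from PSA records (or explicit X/Y frames) and call
    :meth:`fit`, which returns a :class:`MetamodelSet` results object.
    """

    def __init__(self, X: pd.DataFrame, Y: pd.DataFrame, *,
                 seed: int | None = None, scenario: str | None = None):
        if len(X) != len(Y):
            raise ValueError("X and Y must have equal length")
        missing = set(OUTPUT_NAMES) - set(Y.columns)
        if missing:
            raise ValueError(f"output frame missing column(s): {sorted(missing)}")
        self.X = X.reset_index(drop=True)
        self.Y = Y.reset_index(drop=True)
        self.seed = seed
        self.scenario = scenario
        # zero-variance columns are collinear with the intercept; exclude
        # them from the candidate pool up front.
        self.candidates = tuple(
            c for c in sorted(X.columns) if float(X[c].std()) > 0.0
        )

    @classmethod
    def from_records(cls, records: Sequence[PSARecord], *,
                     seed: int | None = None,
                     scenario: str | None = None) -> "CostEffectivenessCalculator":
        X, Y = records_to_frames(records)
        return cls(X, Y, seed=seed, scenario=scenario)

    def _check_rank(self, cols: Sequence[str]) -> None:
        mat = np.column_stack(
            [np.ones(len(self.X))] + [self.X[c].to_numpy() for c in cols]
        )
        rank = np.linalg.matrix_rank(mat)
        if rank < mat.shape[1]:
            # identify offending columns via pivoted QR: the columns pivoted
            # beyond the numerical rank are linearly dependent on the rest.
            from scipy.linalg import qr

            _, _, piv = qr(mat, mode="economic", pivoting=True)
            dependent = sorted(
                (["const"] + list(cols))[j] for j in piv[rank:]
            )
            raise ValueError(f"rank-deficient design; collinear regressors: {dependent}")

    def _fit_one(self, output: str, alpha: float, backward: bool) -> OutputModel:
        y = self.Y[output].to_numpy()
        y_scale = max(float(np.std(y)), abs(float(np.mean(y))), 1e-300)
        x_sd = {c: float(self.X[c].std()) for c in self.candidates}
        retained = list(self.candidates)
        while True:
            exog = sm.add_constant(self.X[retained], has_constant="add") if retained \
                else pd.DataFrame({"const": np.ones(len(self.X))})
            res = sm.OLS(y, exog).fit()
            # a regressor whose standardized coefficient is at rounding level
            # contributes nothing; treat it as insignificant regardless of its
            # (numerically meaningless) p-value — this covers exact fits,
            # where residuals are pure floating-point noise.
            pvals = {
                name: (1.0
                       if abs(float(res.params[name])) * x_sd[name] <= 1e-10 * y_scale
                       else float(res.pvalues[name]))
                for name in retained
            }
            if not retained:
                break
            if backward:
                worst = max(retained, key=lambda nm: (pvals[nm], nm))
                if pvals[worst] >= alpha or np.isnan(pvals[worst]):
                    retained.remove(worst)
                    continue
                break
            else:  # single-shot pruning
                retained = [nm for nm in retained
                            if pvals[nm] < alpha and not np.isnan(pvals[nm])]
                exog = sm.add_constant(self.X[retained], has_constant="add") if retained \
                    else pd.DataFrame({"const": np.ones(len(self.X))})
                res = sm.OLS(y, exog).fit()
                pvals = {name: float(res.pvalues[name]) for name in retained}
                break
        params = res.params
        return OutputModel(
            output=output,
            intercept=float(params["const"]),
            coefficients={nm: float(params[nm]) for nm in retained},
            pvalues={nm: pvals[nm] for nm in retained},
        )

    def fit(self, settings: AnalysisSettings | None = None, *,
            alpha: float | None = None, method: str = "backward") -> MetamodelSet:
        """Fit the ten meta-models with significance-based variable selection.

        ``method`` is ``"backward"`` (iterated worst-p elimination, the
        default) or ``"single_shot"`` (one pruning pass).
        """
        if method not in ("backward", "single_shot"):
            raise ValueError("method must be 'backward' or 'single_shot'")
        if alpha is None:
            alpha = (settings or AnalysisSettings()).selection_alpha
        n, k = len(self.X), len(self.candidates)
        if n <= 2 * k:
            raise ValueError(
                f"n_train={n} too small for {k} candidate regressors (need > {2 * k})"
            )
        self._check_rank(self.candidates)
        outputs = {
            name: self._fit_one(name, alpha, backward=(method == "backward"))
            for name in OUTPUT_NAMES
        }
        return MetamodelSet(
            outputs=outputs,
            candidate_regressors=self.candidates,
            n_train=n,
            selection_alpha=alpha,
            seed=self.seed,
            scenario=self.scenario,
        )


# ---------------------------------------------------------------------------
# functional wrappers

def fit_metamodel(train: Sequence[PSARecord],
                  settings: AnalysisSettings | None = None, *,
                  method: str = "backward",
                  seed: int | None = None,
                  scenario: str | None = None) -> MetamodelSet:
    settings = settings or AnalysisSettings()
    model = CostEffectivenessCalculator.from_records(
        train, seed=seed if seed is not None else settings.seed, scenario=scenario
    )
    return model.fit(settings, method=method)


def predict(m: MetamodelSet, inputs: Mapping[str, float]) -> dict[str, float]:
    return m.predict(inputs)


def validate(m: MetamodelSet, test: Sequence[PSARecord]) -> ValidationReport:
    return m.validate(test)


def save_metamodel(m: MetamodelSet, path: str | Path) -> Path:
    return m.save(path)


def load_metamodel(path: str | Path) -> MetamodelSet:
    """Load a metamodel JSON file, validating schema and regressor names."""
    raw = json.loads(Path(path).read_text())
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"metamodel file {path}: schema version {version!r} != {SCHEMA_VERSION}"
        )
    candidates = tuple(raw["candidate_regressors"])
    meta = raw.get("metadata", {})
    outputs = {}
    for name, spec in raw["outputs"].items():
        if name not in OUTPUT_NAMES:
            raise ValueError(f"metamodel file {path}: unknown output {name!r}")
        outputs[name] = OutputModel(
            output=name,
            intercept=float(spec["intercept"]),
            coefficients={k: float(v) for k, v in spec["coefficients"].items()},
        )
    return MetamodelSet(
        outputs=outputs,
        candidate_regressors=candidates,
        n_train=int(meta.get("n_train", 0)),
        selection_alpha=float(meta.get("selection_alpha", 0.05)),
        seed=meta.get("seed"),
        scenario=meta.get("scenario"),
    )
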