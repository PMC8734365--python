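"""Model-input configurations for the CAD imaging cost-effectiveness model.

A :class:`Scenario` bundles every input the decision-tree + Markov cohort
engine needs for one population/setting: prevalence of obstructive coronary
artery disease, the diagnostic test profiles (sensitivity, specificity,
cost) of the noninvasive modalities, procedure and treatment costs,
health-state utilities and costs, the discount rate, and the cohort
transition parameters.  Scenarios are plain YAML/JSON files with strict key
checking; three named scenarios replicating published US analyses ship with
the package (``ge_us``, ``genders_us``, ``genders_plus_ge_accuracy``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "TestProfile",
    "CohortParams",
    "Scenario",
    "AnalysisSettings",
    "ScenarioValidationError",
    "PACKAGED_SCENARIOS",
    "SAMPLED_PARAMETERS",
    "PROBABILITY_PARAMETERS",
    "COST_PARAMETERS",
    "DEFAULT_LIFE_TABLE",
    "load_scenario",
    "save_scenario",
    "validate_scenario",
]

#: Abridged all-cause annual death probabilities by age (both sexes combined),
#: approximating a contemporary US period life table.  Linearly interpolated
#: between ages; configurable per scenario.
DEFAULT_LIFE_TABLE: dict[float, float] = {
    40.0: 0.0020,
    45.0: 0.0030,
    50.0: 0.0043,
    55.0: 0.0062,
    60.0: 0.0092,
    65.0: 0.0133,
    70.0: 0.0203,
    75.0: 0.0310,
    80.0: 0.0512,
    85.0: 0.0855,
    90.0: 0.1390,
    95.0: 0.2160,
    100.0: 0.3130,
    105.0: 0.4000,
}

PACKAGED_SCENARIOS = ("ge_us", "genders_us", "genders_plus_ge_accuracy")

#: The parameters sampled in probabilistic sensitivity analysis and exposed
#: as candidate regressors to the metamodel, in canonical (sorted) order.
SAMPLED_PARAMETERS = tuple(sorted([
    "prevalence",
    "cmr_sensitivity", "cmr_specificity", "cmr_cost",
    "spect_sensitivity", "spect_specificity", "spect_cost",
    "ccta_sensitivity", "ccta_specificity", "ccta_cost",
    "ica_cost", "cabg_cost", "pci_cost",
    "utility_no_mace", "utility_mace",
    "mace_first_year_cost", "mace_subsequent_annual_cost",
    "first_mace_prob_no_cad",
    "first_mace_prob_treated_cad",
    "first_mace_prob_untreated_cad",
]))

PROBABILITY_PARAMETERS = frozenset(
    p for p in SAMPLED_PARAMETERS
    if p.endswith(("sensitivity", "specificity"))
    or p.startswith(("utility", "first_mace_prob"))
    or p == "prevalence"
)
COST_PARAMETERS = frozenset(p for p in SAMPLED_PARAMETERS if p.endswith("cost"))


class ScenarioValidationError(ValueError):
    """A scenario violated one or more field invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid scenario: " + "; ".join(violations))


@dataclass(frozen=True)
class TestProfile:
    """Diagnostic operating characteristics and cost of one imaging modality."""

    sensitivity: float
    specificity: float
    cost: float


@dataclass(frozen=True)
class CohortParams:
    """Markov transition parameters for the four-state cohort model.

    The annual first-MACE probabilities are conditional on disease/treatment
    status; recurrent events (from a MACE-history state) occur at
    ``recurrent_mace_multiplier`` times the status-specific first-event rate.
    Every MACE event is fatal with probability ``mace_case_fatality``;
    background all-cause mortality comes from an age-indexed table that is
    linearly interpolated and must cover the simulated age span.
    """

    annual_first_mace_prob_treated_cad: float = 0.025
    annual_first_mace_prob_untreated_cad: float = 0.060
    annual_first_mace_prob_no_cad: float = 0.006
    recurrent_mace_multiplier: float = 2.0
    mace_case_fatality: float = 0.15
    background_mortality: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_LIFE_TABLE)
    )


@dataclass(frozen=True)
class Scenario:
    """All user-facing inputs for one cost-effectiveness setting."""

    prevalence: float
    age: float
    male_fraction: float
    test_profiles: Mapping[str, TestProfile]
    ica_cost: float
    cabg_cost: float
    pci_cost: float
    medical_therapy_annual_cost: float
    revascularization_fraction: float
    cabg_share: float
    utility_no_mace: float
    utility_mace: float
    mace_first_year_cost: float
    mace_subsequent_annual_cost: float
    discount_rate: float
    wtp: float
    fn_return_prob: float
    horizon_age: float
    cohort_params: CohortParams = field(default_factory=CohortParams)
    name: str = "custom"
    currency: str = "USD"
    sources: Mapping[str, str] = field(default_factory=dict)

    def parameter_means(self) -> dict[str, float]:
        """Flat mapping of the PSA-sampled parameters to their scenario values."""
        cp = self.cohort_params
        out = {
            "prevalence": self.prevalence,
            "ica_cost": self.ica_cost,
            "cabg_cost": self.cabg_cost,
            "pci_cost": self.pci_cost,
            "utility_no_mace": self.utility_no_mace,
            "utility_mace": self.utility_mace,
            "mace_first_year_cost": self.mace_first_year_cost,
            "mace_subsequent_annual_cost": self.mace_subsequent_annual_cost,
            "first_mace_prob_no_cad": cp.annual_first_mace_prob_no_cad,
            "first_mace_prob_treated_cad": cp.annual_first_mace_prob_treated_cad,
            "first_mace_prob_untreated_cad": cp.annual_first_mace_prob_untreated_cad,
        }
        for modality, profile in self.test_profiles.items():
            out[f"{modality}_sensitivity"] = profile.sensitivity
            out[f"{modality}_specificity"] = profile.specificity
            out[f"{modality}_cost"] = profile.cost
        return {k: out[k] for k in SAMPLED_PARAMETERS}

    def replace(self, **changes: Any) -> "Scenario":
        return dataclasses.replace(self, **changes)

    def with_parameters(self, params: Mapping[str, float]) -> "Scenario":
        """Return a copy with flat sampled-parameter names written back."""
        s = self
        profiles = dict(s.test_profiles)
        cp_changes: dict[str, float] = {}
        top_changes: dict[str, float] = {}
        for name, value in params.items():
            if name not in SAMPLED_PARAMETERS:
                raise KeyError(f"unknown sampled parameter {name!r}")
            if name.startswith("first_mace_prob_"):
                cp_changes[f"annual_{name}"] = value
            elif "_" not in name:
                top_changes[name] = value
            else:
                modality, attr = name.rsplit("_", 1)
                if modality in profiles and attr in ("sensitivity", "specificity", "cost"):
                    profiles[modality] = dataclasses.replace(profiles[modality], **{attr: value})
                else:
                    top_changes[name] = value
        cp = dataclasses.replace(s.cohort_params, **cp_changes) if cp_changes else s.cohort_params
        return dataclasses.replace(s, test_profiles=profiles, cohort_params=cp, **top_changes)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "currency": self.currency,
            "prevalence": self.prevalence,
            "age": self.age,
            "male_fraction": self.male_fraction,
            "test_profiles": {
                k: dataclasses.asdict(v) for k, v in self.test_profiles.items()
            },
            "ica_cost": self.ica_cost,
            "cabg_cost": self.cabg_cost,
            "pci_cost": self.pci_cost,
            "medical_therapy_annual_cost": self.medical_therapy_annual_cost,
            "revascularization_fraction": self.revascularization_fraction,
            "cabg_share": self.cabg_share,
            "utility_no_mace": self.utility_no_mace,
            "utility_mace": self.utility_mace,
            "mace_first_year_cost": self.mace_first_year_cost,
            "mace_subsequent_annual_cost": self.mace_subsequent_annual_cost,
            "discount_rate": self.discount_rate,
            "wtp": self.wtp,
            "fn_return_prob": self.fn_return_prob,
            "horizon_age": self.horizon_age,
            "cohort_params": {
                "annual_first_mace_prob_treated_cad": self.cohort_params.annual_first_mace_prob_treated_cad,
                "annual_first_mace_prob_untreated_cad": self.cohort_params.annual_first_mace_prob_untreated_cad,
                "annual_first_mace_prob_no_cad": self.cohort_params.annual_first_mace_prob_no_cad,
                "recurrent_mace_multiplier": self.cohort_params.recurrent_mace_multiplier,
                "mace_case_fatality": self.cohort_params.mace_case_fatality,
                "background_mortality": {
                    float(a): float(q)
                    for a, q in self.cohort_params.background_mortality.items()
                },
            },
        }
        if self.sources:
            d["sources"] = dict(self.sources)
        return d


@dataclass(frozen=True)
class AnalysisSettings:
    """Knobs for PSA training/validation and value classification."""

    n_train: int = 100_000
    n_test: int = 1_000
    selection_alpha: float = 0.05
    high_value_threshold: float = 50_000.0
    low_value_threshold: float = 150_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_test <= 0:
            raise ValueError("n_train and n_test must be positive")
        if not (0.0 < self.selection_alpha < 1.0):
            raise ValueError("selection_alpha must lie in (0, 1)")
        if not (self.high_value_threshold < self.low_value_threshold):
            raise ValueError("high_value_threshold must be below low_value_threshold")


_SCENARIO_KEYS = {
    "name", "currency", "sources", "prevalence", "age", "male_fraction",
    "test_profiles", "ica_cost", "cabg_cost", "pci_cost",
    "medical_therapy_annual_cost", "revascularization_fraction", "cabg_share",
    "utility_no_mace", "utility_mace", "mace_first_year_cost",
    "mace_subsequent_annual_cost", "discount_rate", "wtp", "fn_return_prob",
    "horizon_age", "cohort_params",
}
_COHORT_KEYS = {
    "annual_first_mace_prob_treated_cad", "annual_first_mace_prob_untreated_cad",
    "annual_first_mace_prob_no_cad", "recurrent_mace_multiplier",
    "mace_case_fatality", "background_mortality",
}
_PROFILE_KEYS = {"sensitivity", "specificity", "cost"}


def _scenario_from_dict(raw: Mapping[str, Any], origin: str) -> Scenario:
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(
            f"{origin}: unknown scenario key(s): {', '.join(sorted(unknown))}"
        )
    missing = _SCENARIO_KEYS - set(raw) - {"name", "currency", "sources", "cohort_params"}
    if missing:
        raise ValueError(
            f"{origin}: missing scenario key(s): {', '.join(sorted(missing))}"
        )
    profiles_raw = raw["test_profiles"]
    if not isinstance(profiles_raw, Mapping) or not profiles_raw:
        raise ValueError(f"{origin}: test_profiles must be a non-empty mapping")
    profiles: dict[str, TestProfile] = {}
    for modality, p in profiles_raw.items():
        unknown_p = set(p) - _PROFILE_KEYS
        if unknown_p:
            raise ValueError(
                f"{origin}: test_profiles.{modality}: unknown key(s): "
                f"{', '.join(sorted(unknown_p))}"
            )
        missing_p = _PROFILE_KEYS - set(p)
        if missing_p:
            raise ValueError(
                f"{origin}: test_profiles.{modality}: missing key(s): "
                f"{', '.join(sorted(missing_p))}"
            )
        profiles[str(modality)] = TestProfile(
            sensitivity=float(p["sensitivity"]),
            specificity=float(p["specificity"]),
            cost=float(p["cost"]),
        )
    cp_raw = raw.get("cohort_params", {})
    unknown_cp = set(cp_raw) - _COHORT_KEYS
    if unknown_cp:
        raise ValueError(
            f"{origin}: cohort_params: unknown key(s): {', '.join(sorted(unknown_cp))}"
        )
    cp_kwargs: dict[str, Any] = {}
    for k in _COHORT_KEYS - {"background_mortality"}:
        if k in cp_raw:
            cp_kwargs[k] = float(cp_raw[k])
    if "background_mortality" in cp_raw:
        cp_kwargs["background_mortality"] = {
            float(a): float(q) for a, q in cp_raw["background_mortality"].items()
        }
    cohort = CohortParams(**cp_kwargs)
    scalar = {
        k: float(raw[k])
        for k in (
            "prevalence", "age", "male_fraction", "ica_cost", "cabg_cost",
            "pci_cost", "medical_therapy_annual_cost",
            "revascularization_fraction", "cabg_share", "utility_no_mace",
            "utility_mace", "mace_first_year_cost",
            "mace_subsequent_annual_cost", "discount_rate", "wtp",
            "fn_return_prob", "horizon_age",
        )
    }
    return Scenario(
        test_profiles=profiles,
        cohort_params=cohort,
        name=str(raw.get("name", "custom")),
        currency=str(raw.get("currency", "USD")),
        sources=dict(raw.get("sources", {})),
        **scalar,
    )


def _prob(violations: list[str], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        violations.append(f"{name} must lie in [0, 1] (got {value!r})")


def _nonneg(violations: list[str], name: str, value: float) -> None:
    if not value >= 0.0:
        violations.append(f"{name} must be >= 0 (got {value!r})")


def validate_scenario(s: Scenario) -> list[str]:
    """Report every violated invariant; an empty list means the scenario is valid."""
    v: list[str] = []
    import math

    for fname in (
        "prevalence", "age", "male_fraction", "ica_cost", "cabg_cost",
        "pci_cost", "medical_therapy_annual_cost", "revascularization_fraction",
        "cabg_share", "utility_no_mace", "utility_mace", "mace_first_year_cost",
        "mace_subsequent_annual_cost", "discount_rate", "wtp",
        "fn_return_prob", "horizon_age",
    ):
        if not math.isfinite(getattr(s, fname)):
            v.append(f"{fname} must be finite")
    _prob(v, "prevalence", s.prevalence)
    _prob(v, "male_fraction", s.male_fraction)
    _prob(v, "revascularization_fraction", s.revascularization_fraction)
    _prob(v, "cabg_share", s.cabg_share)
    _prob(v, "utility_no_mace", s.utility_no_mace)
    _prob(v, "utility_mace", s.utility_mace)
    _prob(v, "fn_return_prob", s.fn_return_prob)
    if s.utility_mace > s.utility_no_mace:
        v.append("utility_mace must not exceed utility_no_mace")
    if not s.discount_rate >= 0.0:
        v.append("discount_rate must be >= 0")
    if not s.horizon_age > s.age:
        v.append("horizon_age must exceed age")
    for cname in (
        "ica_cost", "cabg_cost", "pci_cost", "medical_therapy_annual_cost",
        "mace_first_year_cost", "mace_subsequent_annual_cost", "wtp",
    ):
        _nonneg(v, cname, getattr(s, cname))
    for modality, p in s.test_profiles.items():
        _prob(v, f"test_profiles.{modality}.sensitivity", p.sensitivity)
        _prob(v, f"test_profiles.{modality}.specificity", p.specificity)
        _nonneg(v, f"test_profiles.{modality}.cost", p.cost)
    cp = s.cohort_params
    _prob(v, "cohort_params.annual_first_mace_prob_treated_cad",
          cp.annual_first_mace_prob_treated_cad)
    _prob(v, "cohort_params.annual_first_mace_prob_untreated_cad",
          cp.annual_first_mace_prob_untreated_cad)
    _prob(v, "cohort_params.annual_first_mace_prob_no_cad",
          cp.annual_first_mace_prob_no_cad)
    _prob(v, "cohort_params.mace_case_fatality", cp.mace_case_fatality)
    if not cp.recurrent_mace_multiplier >= 1.0:
        v.append("cohort_params.recurrent_mace_multiplier must be >= 1")
    table = cp.background_mortality
    if not table:
        v.append("cohort_params.background_mortality must be non-empty")
    else:
        ages = sorted(table)
        if ages[0] > s.age or ages[-1] < s.horizon_age - 1.0:
            v.append(
                "cohort_params.background_mortality must cover "
                f"[{s.age}, {s.horizon_age - 1.0}] (covers [{ages[0]}, {ages[-1]}])"
            )
        for a, q in table.items():
            _prob(v, f"cohort_params.background_mortality[{a}]", q)
    return v


def _packaged_path(name: str) -> Path:
    ref = resources.files("cadcea").joinpath("data", f"scenario_{name}.yaml")
    with resources.as_file(ref) as p:
        return Path(p)


def load_scenario(path_or_name: str | Path) -> Scenario:
    """Load and validate a scenario from a file or a packaged name.

    Packaged names: ``ge_us``, ``genders_us``, ``genders_plus_ge_accuracy``.
    Files may be YAML (``.yaml``/``.yml``) or JSON (``.json``); unknown keys
    are rejected to catch typos.
    """
    name = str(path_or_name)
    if name in PACKAGED_SCENARIOS:
        path = _packaged_path(name)
    else:
        path = Path(path_or_name)
        if not path.exists():
            raise FileNotFoundError(
                f"no such scenario file or packaged name: {path_or_name!r} "
                f"(packaged: {', '.join(PACKAGED_SCENARIOS)})"
            )
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"could not parse scenario file {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ValueError(f"scenario file {path} must hold a mapping at top level")
    scenario = _scenario_from_dict(raw, origin=str(path))
    violations = validate_scenario(scenario)
    if violations:
        raise ScenarioValidationError(violations)
    return scenario


def save_scenario(s: Scenario, path: str | Path) -> Path:
    """Write a scenario to YAML or JSON (by suffix); round-trips exactly."""
    path = Path(path)
    d = s.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path
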