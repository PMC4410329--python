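"""JSON configuration: schema, defaults and validation.

Any field left out of the configuration falls back to the bundled national
defaults (National Study counts, MEPS 2010 costs, Census 2010 profile),
mirroring the spreadsheet's override behavior: an empty object reproduces the
national worksheet verbatim. Validation errors carry JSON-pointer paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Optional

from . import fixtures
from .errors import ConfigError, InvalidScenarioError
from .model import (
    AgeDistribution,
    Category,
    CostSchedule,
    ProgramCostModel,
    UtilizationSeries,
)
from .projection import (
    ChronicPopulationMethod,
    PopulationProfile,
    ReachScenario,
    ScenarioMode,
)

__all__ = ["SCHEMA_VERSION", "EstimatorConfig", "config_from_dict", "read_config", "default_config"]

#: Bumped if the schema gains fields (e.g. future inflation adjustment).
SCHEMA_VERSION = 1

_TOP_LEVEL_KEYS = {
    "schema_version",
    "age_distribution",
    "er_series",
    "hosp_series",
    "er_costs",
    "hosp_costs",
    "program_cost",
    "population",
    "chronic_population_method",
    "scenario",
}


@dataclass(frozen=True)
class EstimatorConfig:
    """Fully resolved configuration (defaults already applied)."""

    age_distribution: AgeDistribution
    er_series: UtilizationSeries
    hosp_series: UtilizationSeries
    er_costs: CostSchedule
    hosp_costs: CostSchedule
    program_cost: ProgramCostModel
    population: PopulationProfile
    chronic_population_method: ChronicPopulationMethod = ChronicPopulationMethod.OVERALL
    scenario: Optional[ReachScenario] = None


def _expect_object(value: Any, pointer: str) -> dict:
    if not isinstance(value, dict):
        raise ConfigError(pointer, f"expected an object, got {type(value).__name__}")
    return value


def _reject_unknown(obj: dict, allowed: set[str], pointer: str) -> None:
    unknown = sorted(set(obj) - allowed)
    if unknown:
        raise ConfigError(f"{pointer}/{unknown[0]}", "unknown field")


def _number(obj: dict, key: str, pointer: str, default: float) -> float:
    value = obj.get(key, default)
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{pointer}/{key}", f"expected a number, got {value!r}")
    return float(value)


def _integer(obj: dict, key: str, pointer: str, default: int) -> int:
    value = obj.get(key, default)
    if isinstance(value, bool) or not isinstance(value, int):
        raise ConfigError(f"{pointer}/{key}", f"expected an integer, got {value!r}")
    return value


def _age_distribution(obj: Any, pointer: str, default: AgeDistribution) -> AgeDistribution:
    if obj is None:
        return default
    obj = _expect_object(obj, pointer)
    _reject_unknown(obj, {"w18_44", "w45_64", "w65plus"}, pointer)
    try:
        return AgeDistribution(
            _number(obj, "w18_44", pointer, default.w18_44),
            _number(obj, "w45_64", pointer, default.w45_64),
            _number(obj, "w65plus", pointer, default.w65plus),
        )
    except ValueError as exc:
        raise ConfigError(pointer, str(exc)) from None


def _series(obj: Any, pointer: str, default: UtilizationSeries) -> UtilizationSeries:
    if obj is None:
        return default
    obj = _expect_object(obj, pointer)
    keys = {"n_baseline", "events_baseline", "n_6mo", "events_6mo", "n_12mo", "events_12mo"}
    _reject_unknown(obj, keys, pointer)
    try:
        return UtilizationSeries(
            category=default.category,
            n_baseline=_integer(obj, "n_baseline", pointer, default.n_baseline),
            events_baseline=_integer(obj, "events_baseline", pointer, default.events_baseline),
            n_6mo=_integer(obj, "n_6mo", pointer, default.n_6mo),
            events_6mo=_integer(obj, "events_6mo", pointer, default.events_6mo),
            n_12mo=_integer(obj, "n_12mo", pointer, default.n_12mo),
            events_12mo=_integer(obj, "events_12mo", pointer, default.events_12mo),
        )
    except ValueError as exc:
        raise ConfigError(pointer, str(exc)) from None


def _schedule(obj: Any, pointer: str, default: CostSchedule) -> CostSchedule:
    if obj is None:
        return default
    obj = _expect_object(obj, pointer)
    _reject_unknown(obj, {"cost18_44", "cost45_64", "cost65plus", "source_label"}, pointer)
    label = obj.get("source_label", default.source_label)
    if not isinstance(label, str):
        raise ConfigError(f"{pointer}/source_label", "expected a string")
    try:
        return CostSchedule(
            category=default.category,
            cost18_44=_number(obj, "cost18_44", pointer, default.cost18_44),
            cost45_64=_number(obj, "cost45_64", pointer, default.cost45_64),
            cost65plus=_number(obj, "cost65plus", pointer, default.cost65plus),
            source_label=label,
        )
    except ValueError as exc:
        raise ConfigError(pointer, str(exc)) from None


def _program_cost(obj: Any, pointer: str, default: ProgramCostModel) -> ProgramCostModel:
    if obj is None:
        return default
    obj = _expect_object(obj, pointer)
    _reject_unknown(obj, {"workshop_cost", "class_size", "override_per_participant"}, pointer)
    override = obj.get("override_per_participant", default.override_per_participant)
    if override is not None and (isinstance(override, bool) or not isinstance(override, (int, float))):
        raise ConfigError(f"{pointer}/override_per_participant", "expected a number or null")
    return ProgramCostModel(
        workshop_cost=_number(obj, "workshop_cost", pointer, default.workshop_cost),
        class_size=_integer(obj, "class_size", pointer, default.class_size),
        override_per_participant=None if override is None else float(override),
    )


def _population(obj: Any, pointer: str, default: PopulationProfile) -> PopulationProfile:
    if obj is None:
        return default
    obj = _expect_object(obj, pointer)
    keys = {
        "pop18_44",
        "pop45_64",
        "pop65plus",
        "prevalence_overall",
        "prevalence18_44",
        "prevalence45_64",
        "prevalence65plus",
    }
    _reject_unknown(obj, keys, pointer)
    try:
        return PopulationProfile(
            pop18_44=_integer(obj, "pop18_44", pointer, default.pop18_44),
            pop45_64=_integer(obj, "pop45_64", pointer, default.pop45_64),
            pop65plus=_integer(obj, "pop65plus", pointer, default.pop65plus),
            prevalence_overall=_number(obj, "prevalence_overall", pointer, default.prevalence_overall),
            prevalence18_44=_number(obj, "prevalence18_44", pointer, default.prevalence18_44),
            prevalence45_64=_number(obj, "prevalence45_64", pointer, default.prevalence45_64),
            prevalence65plus=_number(obj, "prevalence65plus", pointer, default.prevalence65plus),
        )
    except ValueError as exc:
        raise ConfigError(pointer, str(exc)) from None


def _scenario(obj: Any, pointer: str) -> Optional[ReachScenario]:
    if obj is None:
        return None
    obj = _expect_object(obj, pointer)
    _reject_unknown(
        obj, {"mode", "reach_fraction", "expected18_44", "expected45_64", "expected65plus"}, pointer
    )
    mode_raw = obj.get("mode")
    try:
        mode = ScenarioMode(mode_raw)
    except ValueError:
        raise ConfigError(f"{pointer}/mode", f"expected one of {[m.value for m in ScenarioMode]}, got {mode_raw!r}") from None
    try:
        if mode is ScenarioMode.NATIONAL_FRACTION:
            return ReachScenario(mode, reach_fraction=_number(obj, "reach_fraction", pointer, 0.05))
        return ReachScenario(
            mode,
            expected18_44=_integer(obj, "expected18_44", pointer, 0),
            expected45_64=_integer(obj, "expected45_64", pointer, 0),
            expected65plus=_integer(obj, "expected65plus", pointer, 0),
        )
    except InvalidScenarioError as exc:
        raise ConfigError(pointer, str(exc)) from None


def config_from_dict(data: dict) -> EstimatorConfig:
    """Resolve a raw JSON object against the national defaults and validate."""
    data = _expect_object(data, "")
    _reject_unknown(data, _TOP_LEVEL_KEYS, "")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError("/schema_version", f"unsupported schema version {version!r}")
    ref = fixtures.reference_data()
    method_raw = data.get("chronic_population_method", ChronicPopulationMethod.OVERALL.value)
    try:
        method = ChronicPopulationMethod(method_raw)
    except ValueError:
        raise ConfigError(
            "/chronic_population_method",
            f"expected one of {[m.value for m in ChronicPopulationMethod]}, got {method_raw!r}",
        ) from None
    return EstimatorConfig(
        age_distribution=_age_distribution(data.get("age_distribution"), "/age_distribution", ref.national_age_mix),
        er_series=_series(data.get("er_series"), "/er_series", ref.er_series),
        hosp_series=_series(data.get("hosp_series"), "/hosp_series", ref.hosp_series),
        er_costs=_schedule(data.get("er_costs"), "/er_costs", ref.meps2010_er),
        hosp_costs=_schedule(data.get("hosp_costs"), "/hosp_costs", ref.meps2010_hosp),
        program_cost=_program_cost(data.get("program_cost"), "/program_cost", ref.program_cost),
        population=_population(data.get("population"), "/population", ref.census2010),
        chronic_population_method=method,
        scenario=_scenario(data.get("scenario"), "/scenario"),
    )


def read_config(path: str) -> EstimatorConfig:
    """Parse and validate a configuration file."""
    with open(path, "r", encoding="utf-8") as handle:
        try:
            data = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ConfigError("", f"invalid JSON: {exc}") from None
    return config_from_dict(data)


def default_config() -> EstimatorConfig:
    """The full national-default configuration (empty override object)."""
    return config_from_dict({})
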