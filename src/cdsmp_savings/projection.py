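"""Step 6: reach projections.

Two printed variants are supported:

* **national extrapolation** — Census adult counts and chronic-condition
  prevalence give the eligible population; a reach fraction of it times the
  per-participant net savings gives the national total;
* **local projection** — an expected enrollment with a new age mix; the
  observed utilization reductions are reapplied under cost schedules
  re-standardized to the new mix (a modeling assumption: behavior change is
  not re-estimated by age).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import InvalidScenarioError
from .model import (
    AgeDistribution,
    CostSchedule,
    ReductionPair,
    age_adjusted_cost,
    annual_savings,
    net_savings,
)

__all__ = [
    "ChronicPopulationMethod",
    "PopulationProfile",
    "ScenarioMode",
    "ReachScenario",
    "ProjectionResult",
    "ScenarioComparison",
    "chronic_adult_population",
    "national_savings",
    "local_projection",
    "compare_scenarios",
]


class ChronicPopulationMethod(str, Enum):
    """How to count adults with >=1 chronic condition from a profile.

    OVERALL multiplies the total adult population by the overall prevalence;
    AGE_SPECIFIC sums bin population x bin prevalence. The published chain
    uses OVERALL (it alone reproduces the printed eligible-adult count), so it
    is the default; AGE_SPECIFIC implements the formula the narrative spells
    out and is available behind this explicit flag.
    """

    OVERALL = "overall"
    AGE_SPECIFIC = "age_specific"


class ScenarioMode(str, Enum):
    NATIONAL_FRACTION = "national_fraction"
    LOCAL_COUNTS = "local_counts"


@dataclass(frozen=True)
class PopulationProfile:
    """Adult population counts by age bin plus chronic-condition prevalences."""

    pop18_44: int
    pop45_64: int
    pop65plus: int
    prevalence_overall: float
    prevalence18_44: float
    prevalence45_64: float
    prevalence65plus: float

    def __post_init__(self) -> None:
        counts = (self.pop18_44, self.pop45_64, self.pop65plus)
        if any(c < 0 for c in counts):
            raise ValueError("population counts must be nonnegative")
        if sum(counts) <= 0:
            raise ValueError("total adult population must be positive")
        prevalences = (
            self.prevalence_overall,
            self.prevalence18_44,
            self.prevalence45_64,
            self.prevalence65plus,
        )
        if any(not 0.0 <= p <= 1.0 for p in prevalences):
            raise ValueError("prevalences must be in [0, 1]")

    @property
    def total(self) -> int:
        return self.pop18_44 + self.pop45_64 + self.pop65plus


@dataclass(frozen=True)
class ReachScenario:
    """Either a national reach fraction or a projected local enrollment."""

    mode: ScenarioMode
    reach_fraction: Optional[float] = None
    expected18_44: Optional[int] = None
    expected45_64: Optional[int] = None
    expected65plus: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode is ScenarioMode.NATIONAL_FRACTION:
            if self.reach_fraction is None:
                raise InvalidScenarioError("national scenario requires a reach fraction")
            if not 0.0 <= self.reach_fraction <= 1.0:
                raise InvalidScenarioError(
                    f"reach fraction must be in [0, 1], got {self.reach_fraction}"
                )
        else:
            counts = (self.expected18_44, self.expected45_64, self.expected65plus)
            if any(c is None for c in counts):
                raise InvalidScenarioError("local scenario requires three expected counts")
            for c in counts:
                if not isinstance(c, int) or isinstance(c, bool):
                    raise InvalidScenarioError(
                        f"expected participant counts must be whole persons, got {c!r}"
                    )
                if c < 0:
                    raise InvalidScenarioError("expected participant counts must be nonnegative")
            if sum(counts) <= 0:  # type: ignore[arg-type]
                raise InvalidScenarioError("expected participants must have a positive total")

    @property
    def expected_counts(self) -> tuple[int, int, int]:
        if self.mode is not ScenarioMode.LOCAL_COUNTS:
            raise InvalidScenarioError("expected_counts only applies to LOCAL_COUNTS scenarios")
        return (self.expected18_44, self.expected45_64, self.expected65plus)  # type: ignore[return-value]

    @property
    def expected_total(self) -> int:
        return sum(self.expected_counts)


@dataclass(frozen=True)
class ProjectionResult:
    """Headcount, per-person net and total savings, all carried unrounded."""

    eligible_population: float
    per_person_net: float
    total_savings: float
    scenario: ReachScenario


@dataclass(frozen=True)
class ScenarioComparison:
    """Differences (alternative - base) in total and per-person savings."""

    delta_total: float
    delta_per_person: float


def chronic_adult_population(
    profile: PopulationProfile,
    method: ChronicPopulationMethod | str = ChronicPopulationMethod.OVERALL,
) -> float:
    """Adults 18+ with at least one chronic condition, unrounded persons."""
    method = ChronicPopulationMethod(method)
    if method is ChronicPopulationMethod.OVERALL:
        return profile.total * profile.prevalence_overall
    return (
        profile.pop18_44 * profile.prevalence18_44
        + profile.pop45_64 * profile.prevalence45_64
        + profile.pop65plus * profile.prevalence65plus
    )


def national_savings(
    chronic_population: float,
    per_person_net: float,
    reach_fraction: float,
) -> ProjectionResult:
    """National total at a reach fraction; all inputs consumed unrounded.

    total = chronic_population x reach_fraction x per_person_net. Linear in
    the reach fraction, so result(r) = r x result(1).
    """
    scenario = ReachScenario(ScenarioMode.NATIONAL_FRACTION, reach_fraction=reach_fraction)
    total = chronic_population * reach_fraction * per_person_net
    return ProjectionResult(
        eligible_population=chronic_population,
        per_person_net=per_person_net,
        total_savings=total,
        scenario=scenario,
    )


def local_projection(
    scenario: ReachScenario,
    er: ReductionPair,
    hosp: ReductionPair,
    er_schedule: CostSchedule,
    hosp_schedule: CostSchedule,
    program_cost: float,
) -> ProjectionResult:
    """Project total savings for an expected enrollment with a new age mix.

    Rebuilds the age distribution from the expected bin counts, re-standardizes
    both cost schedules under it, reapplies the observed reductions and the
    same program cost, and multiplies the unrounded per-person net by the total
    expected headcount. The per-person net depends only on the mix, not on its
    magnitude.
    """
    if scenario.mode is not ScenarioMode.LOCAL_COUNTS:
        raise InvalidScenarioError("local_projection requires a LOCAL_COUNTS scenario")
    counts = scenario.expected_counts
    total_expected = sum(counts)
    if total_expected <= 0:
        raise InvalidScenarioError("expected participants must have a positive total")
    mix = AgeDistribution.from_counts(*counts)
    er_cost = age_adjusted_cost(mix, er_schedule)
    hosp_cost = age_adjusted_cost(mix, hosp_schedule)
    breakdown = annual_savings(er, hosp, er_cost, hosp_cost)
    per_person = net_savings(breakdown.annual_savings, program_cost)
    return ProjectionResult(
        eligible_population=float(total_expected),
        per_person_net=per_person,
        total_savings=total_expected * per_person,
        scenario=scenario,
    )


def compare_scenarios(base: ProjectionResult, alternative: ProjectionResult) -> ScenarioComparison:
    """Absolute differences between two projections computed under the same
    cost schedules (alternative minus base)."""
    return ScenarioComparison(
        delta_total=alternative.total_savings - base.total_savings,
        delta_per_person=alternative.per_person_net - base.per_person_net,
    )
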