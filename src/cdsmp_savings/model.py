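"""Core estimator arithmetic: Steps 1-5.

Given a closed cohort assessed at baseline, 6 and 12 months for any ER visit
and any hospitalization in the prior 6 months, the estimator

1. converts wave event counts to whole-percent utilization rates and takes
   baseline-referenced reductions for the two 6-month periods,
2. standardizes per-event MEPS mean costs to a chosen adult age distribution
   (direct standardization over the bins 18-44 / 45-64 / 65+),
3. prices each period's reduction (delta/100 x age-adjusted cost) and sums the
   four components into an annual per-participant savings,
4. derives the per-participant program delivery cost from workshop economics,
5. subtracts it to give the annual net savings per participant.

Everything downstream consumes unrounded values; only the whole-percent
reductions and the whole-dollar program cost are rounded before use, because
the published chain demonstrably does so.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .errors import InvalidProgramCostError, UndefinedDenominatorError
from .money import round_half_away

__all__ = [
    "Category",
    "AGE_BIN_LABELS",
    "AgeDistribution",
    "CostSchedule",
    "UtilizationSeries",
    "ReductionPair",
    "ProgramCostModel",
    "SavingsBreakdown",
    "proportion_whole_percent",
    "reduction_pair",
    "age_adjusted_cost",
    "period_savings",
    "annual_savings",
    "per_participant_cost",
    "net_savings",
    "complete_breakdown",
    "stability_check",
    "MIN_STABLE_PARTICIPANTS",
]

#: Adult age bins used throughout (the program targets adults 18+).
AGE_BIN_LABELS = ("18-44", "45-64", "65+")

#: Cohorts smaller than this produce unstable whole-percent estimates.
MIN_STABLE_PARTICIPANTS = 100

_WEIGHT_SUM_TOL = 1e-9


class Category(str, Enum):
    """Utilization category tracked by the cohort assessments."""

    ER = "ER"
    HOSPITALIZATION = "HOSPITALIZATION"


@dataclass(frozen=True)
class AgeDistribution:
    """Weights over the three adult age bins; must sum to 1.

    Used for direct standardization of per-event costs. Construct from raw
    bin headcounts with :meth:`from_counts`.
    """

    w18_44: float
    w45_64: float
    w65plus: float

    def __post_init__(self) -> None:
        for label, w in zip(AGE_BIN_LABELS, self.weights):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"age weight for {label} must be in [0, 1], got {w}")
        total = sum(self.weights)
        if abs(total - 1.0) > _WEIGHT_SUM_TOL:
            raise ValueError(f"age weights must sum to 1 (got {total!r})")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w18_44, self.w45_64, self.w65plus)

    @classmethod
    def from_counts(cls, n18_44: int, n45_64: int, n65plus: int) -> "AgeDistribution":
        counts = (n18_44, n45_64, n65plus)
        if any(c < 0 for c in counts):
            raise ValueError("age bin counts must be nonnegative")
        total = sum(counts)
        if total <= 0:
            raise ValueError("age bin counts must have a positive total")
        return cls(*(c / total for c in counts))


@dataclass(frozen=True)
class CostSchedule:
    """Mean cost per event by age bin for one utilization category (2010 USD)."""

    category: Category
    cost18_44: float
    cost45_64: float
    cost65plus: float
    source_label: str = ""

    def __post_init__(self) -> None:
        for label, c in zip(AGE_BIN_LABELS, self.costs):
            if c < 0:
                raise ValueError(f"cost for {label} must be nonnegative, got {c}")

    @property
    def costs(self) -> tuple[float, float, float]:
        return (self.cost18_44, self.cost45_64, self.cost65plus)


@dataclass(frozen=True)
class UtilizationSeries:
    """Wave denominators and event counts for one category (closed cohort)."""

    category: Category
    n_baseline: int
    events_baseline: int
    n_6mo: int
    events_6mo: int
    n_12mo: int
    events_12mo: int

    def __post_init__(self) -> None:
        waves = (
            ("baseline", self.n_baseline, self.events_baseline),
            ("6-month", self.n_6mo, self.events_6mo),
            ("12-month", self.n_12mo, self.events_12mo),
        )
        for wave, n, events in waves:
            if n < 0 or events < 0:
                raise ValueError(f"{self.category.value} {wave}: counts must be nonnegative")
            if events > n:
                raise ValueError(
                    f"{self.category.value} {wave}: events ({events}) exceed respondents ({n})"
                )
        if self.n_6mo > self.n_baseline or self.n_12mo > self.n_baseline:
            raise ValueError(
                f"{self.category.value}: follow-up respondents cannot exceed baseline "
                "(closed cohort with attrition)"
            )


@dataclass(frozen=True)
class ReductionPair:
    """Baseline-referenced utilization reductions, in whole percentage points.

    ``delta_first``  = baseline% - first-6-months%;
    ``delta_second`` = baseline% - second-6-months% (also baseline-referenced).
    Negative values are legal and represent increased utilization.
    """

    category: Category
    delta_first: int
    delta_second: int

    def __post_init__(self) -> None:
        for name, d in (("delta_first", self.delta_first), ("delta_second", self.delta_second)):
            if not -100 <= d <= 100:
                raise ValueError(f"{name} must be in [-100, 100], got {d}")


@dataclass(frozen=True)
class ProgramCostModel:
    """Workshop economics: fixed delivery cost split over the class size.

    The published menu ($3,500 workshops at class sizes 16/14/12/10/8/6) gives
    per-participant costs 219/250/292/350/438/583; an explicit override wins.
    """

    workshop_cost: float = 3500.0
    class_size: int = 10
    override_per_participant: Optional[float] = None


@dataclass(frozen=True)
class SavingsBreakdown:
    """Per-period and annual per-participant savings, carried unrounded.

    ``program_cost``/``net_savings`` are ``None`` until Step 5 completes the
    breakdown (see :func:`complete_breakdown`).
    """

    er_savings_first: float
    er_savings_second: float
    hosp_savings_first: float
    hosp_savings_second: float
    annual_savings: float
    program_cost: Optional[float] = None
    net_savings: Optional[float] = None

    def __post_init__(self) -> None:
        components = (
            self.er_savings_first
            + self.er_savings_second
            + self.hosp_savings_first
            + self.hosp_savings_second
        )
        if abs(self.annual_savings - components) > 1e-9:
            raise ValueError("annual_savings must equal the sum of the four period components")
        if (self.program_cost is None) != (self.net_savings is None):
            raise ValueError("program_cost and net_savings must be set together")
        if self.net_savings is not None and self.program_cost is not None:
            if abs(self.net_savings - (self.annual_savings - self.program_cost)) > 1e-9:
                raise ValueError("net_savings must equal annual_savings - program_cost")


def proportion_whole_percent(events: int, n: int, wave: str = "") -> int:
    """Share of respondents with an event, as whole percentage points.

    100*events/n rounded half-away-from-zero to the nearest integer, matching
    the printed wave percentages (211/1170 -> 18, 118/903 -> 13).
    """
    if n == 0:
        raise UndefinedDenominatorError(wave or "unknown")
    if not 0 <= events <= n:
        raise ValueError(f"events must be in [0, n], got {events}/{n}")
    return int(round_half_away(100.0 * events / n))


def reduction_pair(series: UtilizationSeries) -> ReductionPair:
    """Step 1: baseline-referenced whole-percent reductions for both periods.

    Wave proportions are rounded to whole percent *before* differencing, so the
    deltas agree with the printed "Change in %" column; both periods are
    referenced to baseline, not chained.
    """
    label = series.category.value
    p_base = proportion_whole_percent(series.events_baseline, series.n_baseline, f"{label} baseline")
    p_6mo = proportion_whole_percent(series.events_6mo, series.n_6mo, f"{label} 6-month")
    p_12mo = proportion_whole_percent(series.events_12mo, series.n_12mo, f"{label} 12-month")
    return ReductionPair(series.category, p_base - p_6mo, p_base - p_12mo)


def age_adjusted_cost(dist: AgeDistribution, schedule: CostSchedule) -> float:
    """Step 2: directly standardized mean cost per event, unrounded.

    The inner product of the age weights with the bin costs; lies between the
    minimum and maximum bin cost for any valid distribution.
    """
    return sum(w * c for w, c in zip(dist.weights, schedule.costs))


def period_savings(delta: int, adjusted_cost: float) -> float:
    """Savings per participant for one 6-month period: (delta/100) x cost.

    Negative deltas (utilization rose) yield negative savings.
    """
    if adjusted_cost < 0:
        raise ValueError("adjusted_cost must be nonnegative")
    return (delta / 100.0) * adjusted_cost


def annual_savings(
    er: ReductionPair,
    hosp: ReductionPair,
    er_cost: float,
    hosp_cost: float,
) -> SavingsBreakdown:
    """Step 3: price both categories over both periods and sum, unrounded.

    The annual total is the sum of the *unrounded* components, which is why
    75.6525 + 75.6525 renders as 151.31 although each cell renders 75.65.
    Net fields are left unset; see :func:`complete_breakdown`.
    """
    parts = (
        period_savings(er.delta_first, er_cost),
        period_savings(er.delta_second, er_cost),
        period_savings(hosp.delta_first, hosp_cost),
        period_savings(hosp.delta_second, hosp_cost),
    )
    return SavingsBreakdown(*parts, annual_savings=sum(parts))


def per_participant_cost(model: ProgramCostModel) -> float:
    """Step 4: per-participant program cost in whole dollars.

    The explicit override wins; otherwise workshop_cost / class_size rounded
    half-away-from-zero to whole dollars (3500/16 = 218.75 -> 219).
    """
    if model.override_per_participant is not None:
        cost = float(model.override_per_participant)
        if cost <= 0:
            raise InvalidProgramCostError(f"override per-participant cost must be > 0, got {cost}")
        return cost
    if model.class_size < 1:
        raise InvalidProgramCostError(
            f"class size must be >= 1 (got {model.class_size}) unless an override is given"
        )
    if model.workshop_cost < 0:
        raise InvalidProgramCostError("workshop cost must be nonnegative")
    cost = round_half_away(model.workshop_cost / model.class_size)
    if cost <= 0:
        raise InvalidProgramCostError("derived per-participant cost must be > 0")
    return cost


def net_savings(annual: float, program_cost: float) -> float:
    """Step 5: annual savings minus program cost, unrounded; may be negative."""
    return annual - program_cost


def complete_breakdown(breakdown: SavingsBreakdown, program_cost: float) -> SavingsBreakdown:
    """Attach Step-4/5 results to a Step-3 breakdown."""
    return replace(
        breakdown,
        program_cost=program_cost,
        net_savings=net_savings(breakdown.annual_savings, program_cost),
    )


def stability_check(n_baseline: int) -> Optional[str]:
    """Warn (never block) when the baseline cohort is below 100 participants."""
    if n_baseline < 0:
        raise ValueError("n_baseline must be nonnegative")
    if n_baseline < MIN_STABLE_PARTICIPANTS:
        return (
            f"cohort has {n_baseline} baseline participants; at least "
            f"{MIN_STABLE_PARTICIPANTS} are recommended for stable estimates"
        )
    return None
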