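"""Report assembly and rendering (TEXT / JSON / CSV).

The TEXT layout mirrors the six numbered sections of the published worksheet.
All quantities are carried unrounded in the report object; rendering applies
half-away-from-zero rounding at display precision (cents for currency, whole
persons for populations). The JSON format carries both the unrounded value
and its rendered string for every quantity; identical inputs render to
byte-identical documents in every format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .cohort import ParticipantRecord, aggregate
from .config import EstimatorConfig
from .errors import ReportFormatError
from .model import (
    AgeDistribution,
    ReductionPair,
    SavingsBreakdown,
    UtilizationSeries,
    age_adjusted_cost,
    annual_savings,
    complete_breakdown,
    per_participant_cost,
    proportion_whole_percent,
    reduction_pair,
    stability_check,
)
from .money import percent, usd, whole
from .projection import (
    ProjectionResult,
    ReachScenario,
    ScenarioMode,
    chronic_adult_population,
    local_projection,
    national_savings,
)

__all__ = ["EstimateReport", "build_report", "attach_projection", "render_report"]


@dataclass
class EstimateReport:
    """Everything Steps 1-6 computed, at full precision, plus warnings."""

    er_series: UtilizationSeries
    hosp_series: UtilizationSeries
    age_mix_used: AgeDistribution
    observed_age_mix: Optional[AgeDistribution]
    er_reduction: ReductionPair
    hosp_reduction: ReductionPair
    er_adjusted_cost: float
    hosp_adjusted_cost: float
    breakdown: SavingsBreakdown  # complete (program cost and net set)
    program_cost_note: str
    warnings: list[str] = field(default_factory=list)
    projection: Optional[ProjectionResult] = None
    full_reach_total: Optional[float] = None  # national mode: savings at reach 1.0


def build_report(
    config: EstimatorConfig,
    records: Optional[list[ParticipantRecord]] = None,
) -> EstimateReport:
    """Run Steps 1-5.

    With ``records``, utilization series come from aggregating the participant
    file and the observed age mix is reported; the age distribution used for
    cost standardization is always the configured one (its own input in the
    worksheet), which callers may set from the observed mix if they wish.
    """
    observed_mix: Optional[AgeDistribution] = None
    if records is not None:
        er_series, hosp_series, observed_mix = aggregate(records)
    else:
        er_series, hosp_series = config.er_series, config.hosp_series

    er_red = reduction_pair(er_series)
    hosp_red = reduction_pair(hosp_series)
    mix = config.age_distribution
    er_cost = age_adjusted_cost(mix, config.er_costs)
    hosp_cost = age_adjusted_cost(mix, config.hosp_costs)
    program_cost = per_participant_cost(config.program_cost)
    breakdown = complete_breakdown(annual_savings(er_red, hosp_red, er_cost, hosp_cost), program_cost)

    if config.program_cost.override_per_participant is not None:
        note = "user override"
    else:
        note = (
            f"workshop {usd(config.program_cost.workshop_cost)} / "
            f"class size {config.program_cost.class_size}"
        )

    warnings: list[str] = []
    stability = stability_check(er_series.n_baseline)
    if stability is not None:
        warnings.append(stability)
    for red in (er_red, hosp_red):
        negatives = [d for d in (red.delta_first, red.delta_second) if d < 0]
        if negatives:
            warnings.append(
                f"{red.category.value} utilization increased "
                f"({', '.join(f'{d:+d} points' for d in negatives)}); "
                "the corresponding savings are negative"
            )

    return EstimateReport(
        er_series=er_series,
        hosp_series=hosp_series,
        age_mix_used=mix,
        observed_age_mix=observed_mix,
        er_reduction=er_red,
        hosp_reduction=hosp_red,
        er_adjusted_cost=er_cost,
        hosp_adjusted_cost=hosp_cost,
        breakdown=breakdown,
        program_cost_note=note,
        warnings=warnings,
    )


def attach_projection(
    report: EstimateReport,
    config: EstimatorConfig,
    scenario: ReachScenario,
) -> EstimateReport:
    """Run Step 6 for the given scenario and attach the result to the report."""
    assert report.breakdown.net_savings is not None
    if scenario.mode is ScenarioMode.NATIONAL_FRACTION:
        chronic = chronic_adult_population(config.population, config.chronic_population_method)
        report.projection = national_savings(
            chronic, report.breakdown.net_savings, scenario.reach_fraction or 0.0
        )
        report.full_reach_total = national_savings(chronic, report.breakdown.net_savings, 1.0).total_savings
    else:
        report.projection = local_projection(
            scenario,
            report.er_reduction,
            report.hosp_reduction,
            config.er_costs,
            config.hosp_costs,
            report.breakdown.program_cost or 0.0,
        )
        report.full_reach_total = None
    return report


def _wave_rows(series: UtilizationSeries, red: ReductionPair) -> list[str]:
    label = series.category.value
    p0 = proportion_whole_percent(series.events_baseline, series.n_baseline, f"{label} baseline")
    p1 = proportion_whole_percent(series.events_6mo, series.n_6mo, f"{label} 6-month")
    p2 = proportion_whole_percent(series.events_12mo, series.n_12mo, f"{label} 12-month")
    return [
        f"    baseline:        n={series.n_baseline:<7,} events={series.events_baseline:<6,} {p0}%",
        f"    first 6 months:  n={series.n_6mo:<7,} events={series.events_6mo:<6,} {p1}%   change {red.delta_first}%",
        f"    second 6 months: n={series.n_12mo:<7,} events={series.events_12mo:<6,} {p2}%   change {red.delta_second}%",
    ]


def _mix_text(mix: AgeDistribution) -> str:
    return (
        f"18-44 {percent(mix.w18_44)}, 45-64 {percent(mix.w45_64)}, 65+ {percent(mix.w65plus)}"
    )


def _render_text(report: EstimateReport) -> str:
    b = report.breakdown
    er_total = b.er_savings_first + b.er_savings_second
    hosp_total = b.hosp_savings_first + b.hosp_savings_second
    lines = [
        "HEALTHCARE COST SAVINGS ESTIMATOR: CDSMP",
        "========================================",
        "",
        "1. PATTERN OF HEALTH CARE UTILIZATION",
        "  Emergency room (ER) visits",
        *_wave_rows(report.er_series, report.er_reduction),
        "  Hospitalizations",
        *_wave_rows(report.hosp_series, report.hosp_reduction),
        "",
        "2. AGE-ADJUSTED MEAN COSTS PER EVENT (2010 USD)",
        f"  Age distribution used: {_mix_text(report.age_mix_used)}",
    ]
    if report.observed_age_mix is not None:
        lines.append(f"  Observed cohort age mix: {_mix_text(report.observed_age_mix)}")
    lines += [
        "  ER visits",
        f"    age-adjusted cost: {usd(report.er_adjusted_cost)}",
        f"    savings per person, first 6 months:  {usd(b.er_savings_first)}",
        f"    savings per person, second 6 months: {usd(b.er_savings_second)}",
        f"    total: {usd(er_total)}",
        "  Hospitalizations",
        f"    age-adjusted cost: {usd(report.hosp_adjusted_cost)}",
        f"    savings per person, first 6 months:  {usd(b.hosp_savings_first)}",
        f"    savings per person, second 6 months: {usd(b.hosp_savings_second)}",
        f"    total: {usd(hosp_total)}",
        "",
        "3. ANNUAL HEALTH CARE SAVINGS PER PARTICIPANT",
        f"  {usd(b.annual_savings)}",
        "",
        "4. PROGRAM DELIVERY COST PER PARTICIPANT",
        f"  {usd(b.program_cost or 0.0)} ({report.program_cost_note})",
        "",
        "5. NET SAVINGS PER PARTICIPANT",
        f"  {usd(b.net_savings or 0.0)}",
        "",
    ]
    proj = report.projection
    if proj is None:
        lines += ["6. PROJECTION", "  (not requested)"]
    elif proj.scenario.mode is ScenarioMode.NATIONAL_FRACTION:
        lines += [
            "6. NATIONAL EXTRAPOLATION",
            f"  Adults 18+ with at least one chronic condition: {whole(proj.eligible_population)}",
            f"  Savings if you could reach ALL of them: {usd(report.full_reach_total or 0.0)}",
            f"  Reach: {percent(proj.scenario.reach_fraction or 0.0)}",
            f"  Projected savings at this reach: {usd(proj.total_savings)}",
        ]
    else:
        c = proj.scenario.expected_counts
        new_mix = AgeDistribution.from_counts(*c)
        lines += [
            "6. LOCAL PROJECTION (expected enrollment, new age mix)",
            f"  Expected participants: {whole(proj.eligible_population)} "
            f"(18-44: {c[0]:,}, 45-64: {c[1]:,}, 65+: {c[2]:,})",
            f"  New age mix: {_mix_text(new_mix)}",
            f"  Net savings per participant under the new mix: {usd(proj.per_person_net)}",
            f"  Projected total net savings: {usd(proj.total_savings)}",
            "  Note: assumes the observed utilization reductions apply unchanged",
            "  under the new age mix.",
        ]
    lines.append("")
    if report.warnings:
        lines.append("WARNINGS")
        lines += [f"  - {w}" for w in report.warnings]
    else:
        lines.append("WARNINGS: none")
    lines.append("")
    return "\n".join(lines)


def _quantities(report: EstimateReport) -> dict[str, float]:
    """Currency/population quantities in a fixed order, unrounded."""
    b = report.breakdown
    q = {
        "er_adjusted_cost": report.er_adjusted_cost,
        "hosp_adjusted_cost": report.hosp_adjusted_cost,
        "er_savings_first": b.er_savings_first,
        "er_savings_second": b.er_savings_second,
        "er_savings_total": b.er_savings_first + b.er_savings_second,
        "hosp_savings_first": b.hosp_savings_first,
        "hosp_savings_second": b.hosp_savings_second,
        "hosp_savings_total": b.hosp_savings_first + b.hosp_savings_second,
        "annual_savings": b.annual_savings,
        "program_cost": b.program_cost or 0.0,
        "net_savings": b.net_savings or 0.0,
    }
    proj = report.projection
    if proj is not None:
        q["projection_headcount"] = proj.eligible_population
        q["projection_per_person_net"] = proj.per_person_net
        q["projection_total_savings"] = proj.total_savings
        if report.full_reach_total is not None:
            q["projection_full_reach_savings"] = report.full_reach_total
    return q


def _render_json(report: EstimateReport) -> str:
    quantities = {
        name: {"value": value, "rendered": usd(value)}
        for name, value in _quantities(report).items()
    }
    if report.projection is not None:
        # headcounts render as whole persons, not cents
        quantities["projection_headcount"]["rendered"] = whole(report.projection.eligible_population)
    payload = {
        "cohort": {
            "er": _series_dict(report.er_series),
            "hospitalization": _series_dict(report.hosp_series),
            "age_mix_used": _mix_dict(report.age_mix_used),
            "observed_age_mix": (
                None if report.observed_age_mix is None else _mix_dict(report.observed_age_mix)
            ),
        },
        "reductions": {
            "er": [report.er_reduction.delta_first, report.er_reduction.delta_second],
            "hospitalization": [
                report.hosp_reduction.delta_first,
                report.hosp_reduction.delta_second,
            ],
        },
        "quantities": quantities,
        "warnings": report.warnings,
    }
    return json.dumps(payload, indent=2) + "\n"


def _series_dict(series: UtilizationSeries) -> dict:
    return {
        "n_baseline": series.n_baseline,
        "events_baseline": series.events_baseline,
        "n_6mo": series.n_6mo,
        "events_6mo": series.events_6mo,
        "n_12mo": series.n_12mo,
        "events_12mo": series.events_12mo,
    }


def _mix_dict(mix: AgeDistribution) -> dict:
    return {"w18_44": mix.w18_44, "w45_64": mix.w45_64, "w65plus": mix.w65plus}


def _render_csv(report: EstimateReport) -> str:
    lines = ["quantity,value,rendered"]
    for name, value in _quantities(report).items():
        rendered = whole(value) if name == "projection_headcount" else usd(value)
        lines.append(f"{name},{value!r},\"{rendered}\"")
    for red in (report.er_reduction, report.hosp_reduction):
        key = "er" if red.category.name == "ER" else "hosp"
        lines.append(f"{key}_delta_first,{red.delta_first},{red.delta_first}%")
        lines.append(f"{key}_delta_second,{red.delta_second},{red.delta_second}%")
    return "\n".join(lines) + "\n"


def render_report(report: EstimateReport, format: str = "text") -> str:
    """Render the report; formats are ``text``, ``json`` and ``csv``."""
    renderers = {"text": _render_text, "json": _render_json, "csv": _render_csv}
    key = str(format).lower()
    if key not in renderers:
        raise ReportFormatError(f"unknown report format {format!r} (expected text/json/csv)")
    return renderers[key](report)
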