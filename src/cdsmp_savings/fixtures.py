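"""Bundled reference constants and a synthetic cohort generator.

The reference constants transcribe the published national defaults: the
National Study utilization counts (2010-2012), 2010 MEPS mean per-event costs
and chronic-condition prevalences, and 2010 Census adult population counts.
The generator produces synthetic participant files so every pipeline stage is
testable offline: EXACT mode places indicators deterministically so that
aggregation reproduces a target set of counts; STOCHASTIC mode draws response
and events per participant from the spec's fractions with a mandatory seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .cohort import CSV_COLUMNS, ParticipantRecord
from .errors import InfeasibleSpecError
from .model import (
    AGE_BIN_LABELS,
    AgeDistribution,
    Category,
    CostSchedule,
    ProgramCostModel,
    UtilizationSeries,
)
from .money import round_half_away
from .projection import PopulationProfile

__all__ = [
    "GenerationMode",
    "CohortSpec",
    "ReferenceData",
    "reference_data",
    "national_cohort_spec",
    "generate_cohort",
    "write_participants_csv",
    "cohort_spec_from_dict",
    "cohort_spec_to_dict",
]


class GenerationMode(str, Enum):
    EXACT = "exact"
    STOCHASTIC = "stochastic"


@dataclass(frozen=True)
class CohortSpec:
    """Target shape of a synthetic cohort.

    Rates are per-wave fractions of respondents with any event; retention
    fractions are the shares of the baseline cohort answering each follow-up.
    STOCHASTIC mode requires an explicit seed (no wall-clock default).
    """

    n_baseline: int
    retention_6mo: float
    retention_12mo: float
    er_rates: tuple[float, float, float]
    hosp_rates: tuple[float, float, float]
    age_mix: AgeDistribution
    mode: GenerationMode = GenerationMode.EXACT
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_baseline <= 0:
            raise ValueError("n_baseline must be positive")
        for name, r in (("retention_6mo", self.retention_6mo), ("retention_12mo", self.retention_12mo)):
            if not 0.0 < r <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {r}")
        for name, rates in (("er_rates", self.er_rates), ("hosp_rates", self.hosp_rates)):
            if len(rates) != 3 or any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError(f"{name} must be three fractions in [0, 1]")
        if self.mode is GenerationMode.STOCHASTIC and self.seed is None:
            raise ValueError("STOCHASTIC mode requires an explicit seed")


@dataclass(frozen=True)
class ReferenceData:
    """National defaults: study counts, MEPS 2010 costs, Census 2010 profile."""

    er_series: UtilizationSeries
    hosp_series: UtilizationSeries
    meps2010_er: CostSchedule
    meps2010_hosp: CostSchedule
    census2010: PopulationProfile
    national_age_mix: AgeDistribution
    program_cost: ProgramCostModel


def reference_data() -> ReferenceData:
    """Return the bundled national constants (a fresh immutable instance)."""
    return ReferenceData(
        er_series=UtilizationSeries(Category.ER, 1170, 211, 903, 118, 825, 108),
        hosp_series=UtilizationSeries(Category.HOSPITALIZATION, 1170, 164, 903, 100, 825, 116),
        meps2010_er=CostSchedule(Category.ER, 1465.0, 1738.0, 1403.0, "MEPS 2010"),
        meps2010_hosp=CostSchedule(
            Category.HOSPITALIZATION, 11501.0, 21462.0, 18554.0, "MEPS 2010"
        ),
        census2010=PopulationProfile(
            pop18_44=112_806_642,
            pop45_64=81_489_445,
            pop65plus=40_267_984,
            prevalence_overall=0.77,
            prevalence18_44=0.71,
            prevalence45_64=0.84,
            prevalence65plus=0.94,
        ),
        national_age_mix=AgeDistribution(0.10, 0.31, 0.59),
        program_cost=ProgramCostModel(workshop_cost=3500.0, class_size=10),
    )


def national_cohort_spec() -> CohortSpec:
    """EXACT spec whose generated cohort aggregates back to the national counts."""
    ref = reference_data()
    er, hosp = ref.er_series, ref.hosp_series
    return CohortSpec(
        n_baseline=er.n_baseline,
        retention_6mo=er.n_6mo / er.n_baseline,
        retention_12mo=er.n_12mo / er.n_baseline,
        er_rates=(
            er.events_baseline / er.n_baseline,
            er.events_6mo / er.n_6mo,
            er.events_12mo / er.n_12mo,
        ),
        hosp_rates=(
            hosp.events_baseline / hosp.n_baseline,
            hosp.events_6mo / hosp.n_6mo,
            hosp.events_12mo / hosp.n_12mo,
        ),
        age_mix=ref.national_age_mix,
        mode=GenerationMode.EXACT,
    )


def _exact_count(x: float, label: str, limit: int) -> int:
    """Round a target to whole persons; reject counts exceeding their denominator."""
    count = int(round_half_away(x))
    if count > limit:
        raise InfeasibleSpecError(f"{label}: rounded count {count} exceeds denominator {limit}")
    return count


def _generate_exact(spec: CohortSpec) -> list[ParticipantRecord]:
    n = spec.n_baseline
    bin_counts = [int(round_half_away(w * n)) for w in spec.age_mix.weights]
    if sum(bin_counts) != n:
        raise InfeasibleSpecError(
            f"age mix: rounded bin counts {bin_counts} do not sum to n_baseline {n}"
        )
    n6 = _exact_count(spec.retention_6mo * n, "6-month retention", n)
    n12 = _exact_count(spec.retention_12mo * n, "12-month retention", n)
    events = {}
    for cat, rates in (("er", spec.er_rates), ("hosp", spec.hosp_rates)):
        for wave, denom, rate in (("baseline", n, rates[0]), ("6mo", n6, rates[1]), ("12mo", n12, rates[2])):
            events[(cat, wave)] = _exact_count(rate * denom, f"{cat} {wave} events", denom)

    width = len(str(n))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]  # lexicographic == numeric
    ages: list[str] = []
    for label, count in zip(AGE_BIN_LABELS, bin_counts):
        ages.extend([label] * count)

    def indicator(cat: str, wave: str, denom: int, i: int) -> Optional[bool]:
        if i >= denom:
            return None
        return i < events[(cat, wave)]

    records = []
    for i, (pid, age) in enumerate(zip(ids, ages)):
        records.append(
            ParticipantRecord(
                participant_id=pid,
                age_group=age,
                er_baseline=i < events[("er", "baseline")],
                er_6mo=indicator("er", "6mo", n6, i),
                er_12mo=indicator("er", "12mo", n12, i),
                hosp_baseline=i < events[("hosp", "baseline")],
                hosp_6mo=indicator("hosp", "6mo", n6, i),
                hosp_12mo=indicator("hosp", "12mo", n12, i),
            )
        )
    return records


def _generate_stochastic(spec: CohortSpec) -> list[ParticipantRecord]:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_baseline
    # Fixed draw order => bit-for-bit reproducibility from (spec, seed).
    bins = rng.choice(3, size=n, p=list(spec.age_mix.weights))
    respond6 = rng.random(n) < spec.retention_6mo
    respond12 = rng.random(n) < spec.retention_12mo  # independent of 6-month response
    draws = {
        (cat, w): rng.random(n) < rates[w]
        for cat, rates in (("er", spec.er_rates), ("hosp", spec.hosp_rates))
        for w in range(3)
    }

    width = len(str(n))
    records = []
    for i in range(n):
        def follow(cat: str, wave: int, responded: bool) -> Optional[bool]:
            return bool(draws[(cat, wave)][i]) if responded else None

        records.append(
            ParticipantRecord(
                participant_id=f"P{i + 1:0{width}d}",
                age_group=AGE_BIN_LABELS[bins[i]],
                er_baseline=bool(draws[("er", 0)][i]),
                er_6mo=follow("er", 1, respond6[i]),
                er_12mo=follow("er", 2, respond12[i]),
                hosp_baseline=bool(draws[("hosp", 0)][i]),
                hosp_6mo=follow("hosp", 1, respond6[i]),
                hosp_12mo=follow("hosp", 2, respond12[i]),
            )
        )
    return records


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Generate a synthetic cohort realizing the spec.

    EXACT mode assigns events to the lexicographically first participants in
    each wave's respondent set, so the output is deterministic without a seed
    and aggregation reproduces the (rounded) target counts exactly.
    """
    if spec.mode is GenerationMode.EXACT:
        return _generate_exact(spec)
    return _generate_stochastic(spec)


def _cell(value: Optional[bool]) -> str:
    if value is None:
        return ""
    return "1" if value else "0"


def write_participants_csv(records: list[ParticipantRecord], path: str) -> None:
    """Write records in the participant CSV dialect (UTF-8, LF, header)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.age_group,
                    _cell(r.er_baseline),
                    _cell(r.er_6mo),
                    _cell(r.er_12mo),
                    _cell(r.hosp_baseline),
                    _cell(r.hosp_6mo),
                    _cell(r.hosp_12mo),
                ]
            )


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    """Serialize a spec to the JSON shape the CLI's fixtures command reads."""
    return {
        "n_baseline": spec.n_baseline,
        "retention_6mo": spec.retention_6mo,
        "retention_12mo": spec.retention_12mo,
        "er_rates": list(spec.er_rates),
        "hosp_rates": list(spec.hosp_rates),
        "age_mix": {
            "w18_44": spec.age_mix.w18_44,
            "w45_64": spec.age_mix.w45_64,
            "w65plus": spec.age_mix.w65plus,
        },
        "mode": spec.mode.value,
    }


def cohort_spec_from_dict(data: dict, seed: Optional[int] = None) -> CohortSpec:
    """Build a spec from its JSON form; ``seed`` overrides any stored seed."""
    mix = data["age_mix"]
    return CohortSpec(
        n_baseline=int(data["n_baseline"]),
        retention_6mo=float(data["retention_6mo"]),
        retention_12mo=float(data["retention_12mo"]),
        er_rates=tuple(float(r) for r in data["er_rates"]),
        hosp_rates=tuple(float(r) for r in data["hosp_rates"]),
        age_mix=AgeDistribution(float(mix["w18_44"]), float(mix["w45_64"]), float(mix["w65plus"])),
        mode=GenerationMode(data.get("mode", "exact")),
        seed=seed if seed is not None else data.get("seed"),
    )
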