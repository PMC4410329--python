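"""Participant-level records: CSV ingestion and cohort aggregation.

The CSV dialect is comma-separated UTF-8 with a mandatory header and columns

    participant_id, age_group,
    er_baseline, er_6mo, er_12mo,
    hosp_baseline, hosp_6mo, hosp_12mo

``age_group`` is one of ``18-44`` / ``45-64`` / ``65+`` or an integer age
(mapped to its bin; ages below 18 are rejected — the program targets adults).
Indicator cells accept 0/1/true/false; the empty string means the participant
did not answer that wave (attrition). Raw visit counts above 1 are collapsed
to "any event" with a warning, since the estimator consumes participant
proportions, not event counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import IngestionError, UndefinedDenominatorError, UnderageParticipantError
from .model import AgeDistribution, Category, UtilizationSeries

__all__ = [
    "CSV_COLUMNS",
    "ParticipantRecord",
    "CollapsedCountWarning",
    "read_participants",
    "aggregate",
]

CSV_COLUMNS = (
    "participant_id",
    "age_group",
    "er_baseline",
    "er_6mo",
    "er_12mo",
    "hosp_baseline",
    "hosp_6mo",
    "hosp_12mo",
)

_AGE_GROUP_ALIASES = {
    "18-44": "18-44",
    "18–44": "18-44",  # en dash as printed
    "45-64": "45-64",
    "45–64": "45-64",
    "65+": "65+",
    "65plus": "65+",
}

_TRUE_STRINGS = {"true", "t", "yes", "y"}
_FALSE_STRINGS = {"false", "f", "no", "n"}


class CollapsedCountWarning(UserWarning):
    """A raw visit count > 1 was collapsed to a boolean 'any event'."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's age bin and any-event indicators at the three waves.

    Baseline indicators are mandatory; follow-up indicators may be ``None``
    (attrition), and a missing 6-month answer with a present 12-month answer
    is legal (wave-specific response).
    """

    participant_id: str
    age_group: str  # one of AGE_BIN_LABELS
    er_baseline: bool
    er_6mo: Optional[bool]
    er_12mo: Optional[bool]
    hosp_baseline: bool
    hosp_6mo: Optional[bool]
    hosp_12mo: Optional[bool]

    def __post_init__(self) -> None:
        if self.age_group not in _AGE_GROUP_ALIASES.values():
            raise ValueError(f"unknown age group {self.age_group!r}")


def _parse_age_group(raw: str, line: int) -> str:
    text = raw.strip()
    if text in _AGE_GROUP_ALIASES:
        return _AGE_GROUP_ALIASES[text]
    try:
        age = int(text)
    except ValueError:
        raise IngestionError(f"unknown age group {raw!r}", line) from None
    if age < 18:
        raise UnderageParticipantError(
            f"participant age {age} is below 18; the program targets adults", line
        )
    if age < 45:
        return "18-44"
    if age < 65:
        return "45-64"
    return "65+"


def _parse_indicator(raw: str, column: str, line: int, required: bool) -> Optional[bool]:
    text = raw.strip()
    if text == "":
        if required:
            raise IngestionError(f"column {column!r} is required at baseline", line)
        return None
    lowered = text.lower()
    if lowered in _TRUE_STRINGS:
        return True
    if lowered in _FALSE_STRINGS:
        return False
    try:
        count = int(text)
    except ValueError:
        raise IngestionError(f"column {column!r}: cannot parse indicator {raw!r}", line) from None
    if count < 0:
        raise IngestionError(f"column {column!r}: negative count {count}", line)
    if count > 1:
        warnings.warn(
            f"line {line}, column {column!r}: raw visit count {count} collapsed to "
            "'any event' (the estimator uses participant proportions)",
            CollapsedCountWarning,
            stacklevel=3,
        )
    return count > 0


def read_participants(path: str) -> list[ParticipantRecord]:
    """Read and validate a participant CSV; malformed rows name their line."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise IngestionError("file is empty; a header row is required") from None
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise IngestionError(f"missing required columns: {', '.join(missing)}")

    records: list[ParticipantRecord] = []
    seen_ids: set[str] = set()
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2  # header is line 1
        pid = str(getattr(row, "participant_id")).strip()
        if not pid:
            raise IngestionError("blank participant_id", line)
        if pid in seen_ids:
            raise IngestionError(f"duplicate participant_id {pid!r}", line)
        seen_ids.add(pid)
        records.append(
            ParticipantRecord(
                participant_id=pid,
                age_group=_parse_age_group(str(getattr(row, "age_group")), line),
                er_baseline=_parse_indicator(str(row.er_baseline), "er_baseline", line, True),
                er_6mo=_parse_indicator(str(row.er_6mo), "er_6mo", line, False),
                er_12mo=_parse_indicator(str(row.er_12mo), "er_12mo", line, False),
                hosp_baseline=_parse_indicator(str(row.hosp_baseline), "hosp_baseline", line, True),
                hosp_6mo=_parse_indicator(str(row.hosp_6mo), "hosp_6mo", line, False),
                hosp_12mo=_parse_indicator(str(row.hosp_12mo), "hosp_12mo", line, False),
            )
        )
    return records


def _series_for(records: Iterable[ParticipantRecord], category: Category) -> UtilizationSeries:
    prefix = "er" if category is Category.ER else "hosp"
    counts = {}
    for wave, attr in (("baseline", "baseline"), ("6mo", "6mo"), ("12mo", "12mo")):
        values = [getattr(r, f"{prefix}_{attr}") for r in records]
        present = [v for v in values if v is not None]
        counts[wave] = (len(present), sum(present))
    return UtilizationSeries(
        category=category,
        n_baseline=counts["baseline"][0],
        events_baseline=counts["baseline"][1],
        n_6mo=counts["6mo"][0],
        events_6mo=counts["6mo"][1],
        n_12mo=counts["12mo"][0],
        events_12mo=counts["12mo"][1],
    )


def aggregate(
    records: list[ParticipantRecord],
) -> tuple[UtilizationSeries, UtilizationSeries, AgeDistribution]:
    """Collapse records into per-category wave counts and the observed age mix.

    Wave denominators are wave- and category-specific respondents (a
    participant answering only the hospitalization item at a wave counts only
    in that category's denominator); events count True indicators. The age
    distribution comes from baseline age-bin headcounts.
    """
    records = list(records)
    if not records:
        raise UndefinedDenominatorError("baseline")
    er = _series_for(records, Category.ER)
    hosp = _series_for(records, Category.HOSPITALIZATION)
    bins = [sum(1 for r in records if r.age_group == label) for label in ("18-44", "45-64", "65+")]
    return er, hosp, AgeDistribution.from_counts(*bins)
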