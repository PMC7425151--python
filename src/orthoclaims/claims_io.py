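"""Reading and writing claims, case, and gold-label tables.

Administrative extracts arrive as delimited text: one row per billed code
(patient id, coding system, code value, service date) and one row per
surgical case (case id, patient id, surgery date, age at surgery, surgeon
panel).  This module parses those tables defensively — malformed rows are
skipped and counted, never silently dropped — assembles each case's
pre-surgical code window, and applies the study eligibility filters
(spine ≥ 21 years, hip/knee ≥ 40 years).

The code window is a closed span of ``window_days`` calendar days ending on,
and including, the surgery date: with the default of 90 days it is
``[surgery_date - 89, surgery_date]``.  Pass ``window_days=91`` for the
alternative reading in which the day 90 days before surgery is also included.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .codebook import Code, CodeSystem, MalformedCodeError, Panel, normalize_code

__all__ = [
    "ClaimEvent",
    "SurgicalCase",
    "GoldLabel",
    "ParseReport",
    "SchemaError",
    "read_claims",
    "write_claims",
    "read_cases",
    "write_cases",
    "read_gold",
    "write_gold",
    "window_events",
    "filter_eligible",
    "ELIGIBLE_AGE",
]

#: Minimum age at surgery, by surgeon panel.
ELIGIBLE_AGE = {Panel.SPINE: 21, Panel.HIP_KNEE: 40}

CLAIMS_COLUMNS = ["patient_id", "system", "code", "service_date"]
CASES_COLUMNS = ["case_id", "patient_id", "surgery_date", "age_years", "panel"]
GOLD_COLUMNS = ["case_id", "procedure_category", "indications", "primary_indication"]


class SchemaError(ValueError):
    """A required column is missing or a table is structurally unusable."""


@dataclass(frozen=True)
class ClaimEvent:
    """One billed code for one patient on one service date."""

    patient_id: str
    code: Code
    service_date: dt.date


@dataclass
class SurgicalCase:
    """A surgery event with patient age, panel, and (after windowing) its claims."""

    case_id: str
    patient_id: str
    surgery_date: dt.date
    age_years: int
    panel: Panel
    window_events: list[ClaimEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"case {self.case_id}: negative age")


@dataclass(frozen=True)
class GoldLabel:
    """Chart-review reference classification for one surgical case."""

    case_id: str
    procedure_category: str  # spinal_surgery | knee_replacement | hip_replacement | other
    indications: frozenset[str]  # subset of {SPS, HD, KOA, HOA, other}
    primary_indication: str  # SPS | HD | KOA | HOA | other

    def __post_init__(self) -> None:
        if self.primary_indication not in (self.indications | {"other"}):
            raise ValueError(
                f"case {self.case_id}: primary indication {self.primary_indication!r} "
                f"not among indications {sorted(self.indications)}"
            )
        if self.procedure_category == "other" and not self.indications <= {"other"}:
            raise ValueError(
                f"case {self.case_id}: 'other' procedure cannot carry study indications"
            )


@dataclass
class ParseReport:
    """Row-level accounting for a table read."""

    rows_read: int = 0
    rows_kept: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def skip(self, row: int, reason: str) -> None:
        self.skipped.append((row, reason))

    @property
    def reasons(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.skipped:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text.strip())


def read_claims(path: str | Path) -> tuple[list[ClaimEvent], ParseReport]:
    """Read a claims table, normalizing codes and skipping unusable rows."""
    df = _read_table(path, CLAIMS_COLUMNS)
    events: list[ClaimEvent] = []
    report = ParseReport(rows_read=len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        raw_system = str(row.system).strip().upper().replace("-", "")
        if raw_system not in (s.value for s in CodeSystem):
            report.skip(i, "unsupported system")
            continue
        try:
            code = normalize_code(str(row.code), CodeSystem(raw_system))
        except MalformedCodeError:
            report.skip(i, "malformed code")
            continue
        try:
            date = _parse_date(str(row.service_date))
        except ValueError:
            report.skip(i, "bad date")
            continue
        pid = str(row.patient_id).strip()
        if not pid:
            report.skip(i, "missing patient_id")
            continue
        events.append(ClaimEvent(pid, code, date))
    report.rows_kept = len(events)
    return events, report


def write_claims(events: Iterable[ClaimEvent], path: str | Path) -> None:
    rows = [
        (e.patient_id, e.code.system.value, e.code.value, e.service_date.isoformat())
        for e in events
    ]
    pd.DataFrame(rows, columns=CLAIMS_COLUMNS).to_csv(path, index=False)


def read_cases(path: str | Path) -> list[SurgicalCase]:
    """Read a surgical-case table (no window populated yet)."""
    df = _read_table(path, CASES_COLUMNS)
    cases = []
    for row in df.itertuples(index=False):
        cases.append(
            SurgicalCase(
                case_id=str(row.case_id).strip(),
                patient_id=str(row.patient_id).strip(),
                surgery_date=_parse_date(str(row.surgery_date)),
                age_years=int(row.age_years),
                panel=Panel(str(row.panel).strip()),
            )
        )
    return cases


def write_cases(cases: Iterable[SurgicalCase], path: str | Path) -> None:
    rows = [
        (c.case_id, c.patient_id, c.surgery_date.isoformat(), c.age_years, c.panel.value)
        for c in cases
    ]
    pd.DataFrame(rows, columns=CASES_COLUMNS).to_csv(path, index=False)


def read_gold(path: str | Path) -> list[GoldLabel]:
    """Read a gold-standard label table (indications semicolon-joined)."""
    df = _read_table(path, GOLD_COLUMNS)
    labels = []
    for row in df.itertuples(index=False):
        indications = frozenset(
            part.strip() for part in str(row.indications).split(";") if part.strip()
        )
        labels.append(
            GoldLabel(
                case_id=str(row.case_id).strip(),
                procedure_category=str(row.procedure_category).strip(),
                indications=indications,
                primary_indication=str(row.primary_indication).strip(),
            )
        )
    return labels


def write_gold(labels: Iterable[GoldLabel], path: str | Path) -> None:
    rows = [
        (
            g.case_id,
            g.procedure_category,
            ";".join(sorted(g.indications)),
            g.primary_indication,
        )
        for g in labels
    ]
    pd.DataFrame(rows, columns=GOLD_COLUMNS).to_csv(path, index=False)


def window_events(
    case: SurgicalCase, claims: Sequence[ClaimEvent], window_days: int = 90
) -> SurgicalCase:
    """Return the case with its pre-surgical code window populated.

    Keeps events of the case's patient whose service date lies in the closed
    span of ``window_days`` calendar days ending on the surgery date, i.e.
    ``surgery_date - (window_days - 1) <= service_date <= surgery_date``.
    Input ordering is preserved; the operation is idempotent.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    start = case.surgery_date - dt.timedelta(days=window_days - 1)
    kept = [
        e
        for e in claims
        if e.patient_id == case.patient_id and start <= e.service_date <= case.surgery_date
    ]
    return replace(case, window_events=kept)


def filter_eligible(
    cases: Iterable[SurgicalCase],
) -> tuple[list[SurgicalCase], dict[Panel, int]]:
    """Apply the study age-eligibility filters; returns (kept, removals per panel)."""
    kept: list[SurgicalCase] = []
    removed = {Panel.SPINE: 0, Panel.HIP_KNEE: 0}
    for case in cases:
        if case.age_years >= ELIGIBLE_AGE[case.panel]:
            kept.append(case)
        else:
            removed[case.panel] += 1
    return kept, removed
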