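"""Two-step rule-based classification of surgical cases.

Step 1 (inclusion): a case is flagged for a combination when its code window
contains at least one inclusion CPT code AND at least one inclusion ICD-10
code for that combination.  A window with only one of the two, or neither,
leaves the combination unmatched and the case headed for "other".

Spine tie-break: a spine case flagged for both spinal stenosis and herniated
disc is resolved by age — at or above the codebook threshold (default 50
years) it is kept as stenosis, below it as herniated disc.  The losing
combination is fully unmatched afterwards.

Step 2 (exclusion): among flagged combinations, any window ICD-10 code
matching the combination's exclusion list (fracture, neoplasm, infection and
other non-elective indications) demotes the condition to a *secondary*
indication; the primary indication becomes "other".  With no exclusion hit
the condition is the primary indication.

Each combination's rules are applied only to cases from its own surgeon
panel (spine vs hip/knee) unless ``panel_restriction=False``, which evaluates
all four rule sets for every case.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .claims_io import SurgicalCase
from .codebook import (
    Code,
    CodePattern,
    CodeSystem,
    Codebook,
    CombinationDefinition,
    ComboId,
    Panel,
    pattern_matches,
)

__all__ = [
    "Status",
    "ComboResult",
    "CaseClassification",
    "step1_inclusion",
    "resolve_spine_tie",
    "step2_exclusion",
    "classify_case",
    "classify_cohort",
    "classifications_to_frame",
    "write_classifications",
    "read_classifications",
]

logger = logging.getLogger(__name__)


class Status(str, enum.Enum):
    """Final standing of one combination for one case."""

    PRIMARY = "primary"
    SECONDARY = "secondary"
    NOT_INDICATED = "not_indicated"


@dataclass
class ComboResult:
    """Per-combination outcome: inclusion match, final status, and evidence."""

    indication_matched: bool = False
    status: Status = Status.NOT_INDICATED
    matched_cpt: set[Code] = field(default_factory=set)
    matched_icd: set[Code] = field(default_factory=set)
    exclusion_hits: set[tuple[CodePattern, Code]] = field(default_factory=set)


@dataclass
class CaseClassification:
    """Two-level algorithm output for one surgical case.

    ``overall_label`` is the combination identified as the case's primary
    indication, ``other`` when none is, or ``ambiguous`` in the undefined
    situation where two combinations of the same panel both end primary.
    """

    case_id: str
    panel: Panel
    combos: Mapping[ComboId, ComboResult]
    overall_label: str = "other"
    tie_break_applied: bool = False

    def status_of(self, combo: ComboId) -> Status:
        result = self.combos.get(combo)
        return result.status if result is not None else Status.NOT_INDICATED

    def matched(self, combo: ComboId) -> bool:
        result = self.combos.get(combo)
        return result.indication_matched if result is not None else False


def step1_inclusion(
    case: SurgicalCase, definition: CombinationDefinition
) -> tuple[bool, set[Code], set[Code]]:
    """Inclusion matching: require both a CPT and an ICD-10 inclusion hit."""
    matched_cpt = {
        e.code
        for e in case.window_events
        if e.code.system is CodeSystem.CPT and e.code in definition.inclusion_cpt
    }
    matched_icd = {
        e.code
        for e in case.window_events
        if e.code.system is CodeSystem.ICD10
        and any(pattern_matches(p, e.code) for p in definition.inclusion_icd)
    }
    return bool(matched_cpt) and bool(matched_icd), matched_cpt, matched_icd


def resolve_spine_tie(
    case: SurgicalCase, sps_matched: bool, hd_matched: bool, threshold_years: int
) -> tuple[bool, bool, bool]:
    """Resolve a dual spinal-stenosis/herniated-disc match by patient age.

    Returns ``(sps_final, hd_final, tie_break_applied)``.  Ages at or above
    the threshold resolve to stenosis; younger ages to herniated disc.  With
    no dual match the inputs pass through unchanged.
    """
    if sps_matched and hd_matched:
        if case.age_years >= threshold_years:
            return True, False, True
        return False, True, True
    return sps_matched, hd_matched, False


def step2_exclusion(
    case: SurgicalCase, definition: CombinationDefinition, indication_matched: bool
) -> tuple[Status, set[tuple[CodePattern, Code]]]:
    """Exclusion screening: demote a matched indication to secondary on any hit."""
    if not indication_matched:
        return Status.NOT_INDICATED, set()
    hits = {
        (p, e.code)
        for e in case.window_events
        if e.code.system is CodeSystem.ICD10
        for p in definition.exclusion_icd
        if pattern_matches(p, e.code)
    }
    return (Status.SECONDARY if hits else Status.PRIMARY), hits


def classify_case(
    case: SurgicalCase, codebook: Codebook, *, panel_restriction: bool = True
) -> CaseClassification:
    """Run the full two-step algorithm on one windowed, eligible case."""
    if panel_restriction:
        definitions = codebook.for_panel(case.panel)
    else:
        definitions = list(codebook.definitions.values())

    combos: dict[ComboId, ComboResult] = {}
    for definition in definitions:
        matched, cpt, icd = step1_inclusion(case, definition)
        combos[definition.id] = ComboResult(
            indication_matched=matched, matched_cpt=cpt, matched_icd=icd
        )

    tie_break = False
    if ComboId.SPS in combos and ComboId.HD in combos:
        sps, hd, tie_break = resolve_spine_tie(
            case,
            combos[ComboId.SPS].indication_matched,
            combos[ComboId.HD].indication_matched,
            codebook.spine_age_threshold_years,
        )
        if tie_break:
            loser = ComboId.HD if sps else ComboId.SPS
            combos[loser] = ComboResult()  # fully unmatched after the tie-break

    for combo_id, result in combos.items():
        status, hits = step2_exclusion(
            case, codebook[combo_id], result.indication_matched
        )
        result.status = status
        result.exclusion_hits = hits

    primaries = [c for c, r in combos.items() if r.status is Status.PRIMARY]
    if len(primaries) == 1:
        overall = primaries[0].value
    elif not primaries:
        overall = "other"
    else:
        logger.warning(
            "case %s: multiple primary indications %s; labeling ambiguous",
            case.case_id,
            [c.value for c in primaries],
        )
        overall = "ambiguous"

    return CaseClassification(
        case_id=case.case_id,
        panel=case.panel,
        combos=combos,
        overall_label=overall,
        tie_break_applied=tie_break,
    )


def classify_cohort(
    cases: Sequence[SurgicalCase], codebook: Codebook, *, panel_restriction: bool = True
) -> list[CaseClassification]:
    """Classify every case, preserving order; rejects duplicate case ids."""
    ids = Counter(c.case_id for c in cases)
    dupes = sorted(i for i, n in ids.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate case_id(s): {dupes}")
    out = [
        classify_case(c, codebook, panel_restriction=panel_restriction) for c in cases
    ]
    counts = Counter(c.overall_label for c in out)
    logger.info("classified %d cases: %s", len(out), dict(sorted(counts.items())))
    return out


_STATUS_COLUMNS = {
    ComboId.SPS: "sps_status",
    ComboId.HD: "hd_status",
    ComboId.KOA: "koa_status",
    ComboId.HOA: "hoa_status",
}


def classifications_to_frame(classifications: Iterable[CaseClassification]) -> pd.DataFrame:
    """Tabular form of classifier output (one row per case)."""
    rows = []
    for c in classifications:
        hits = sorted(
            f"{p.display}:{code.value}"
            for r in c.combos.values()
            for (p, code) in r.exclusion_hits
        )
        row = {
            "case_id": c.case_id,
            "panel": c.panel.value,
            "overall_label": c.overall_label,
            "tie_break_applied": c.tie_break_applied,
            "exclusion_hits": ";".join(hits),
        }
        for combo, col in _STATUS_COLUMNS.items():
            row[col] = c.status_of(combo).value
        rows.append(row)
    columns = [
        "case_id",
        "panel",
        "overall_label",
        "sps_status",
        "hd_status",
        "koa_status",
        "hoa_status",
        "tie_break_applied",
        "exclusion_hits",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_classifications(
    classifications: Iterable[CaseClassification], path: str | Path
) -> None:
    classifications_to_frame(classifications).to_csv(path, index=False)


def read_classifications(path: str | Path) -> list[CaseClassification]:
    """Rebuild classification records from the output table.

    Match evidence (specific codes) is not serialized, so the rebuilt records
    carry statuses and labels only — enough for validation and audit joins.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        panel = Panel(row.panel)
        combos = {}
        for combo, col in _STATUS_COLUMNS.items():
            status = Status(getattr(row, col))
            combos[combo] = ComboResult(
                indication_matched=status is not Status.NOT_INDICATED, status=status
            )
        out.append(
            CaseClassification(
                case_id=row.case_id,
                panel=panel,
                combos=combos,
                overall_label=row.overall_label,
                tie_break_applied=str(row.tie_break_applied).lower() == "true",
            )
        )
    return out
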