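"""Seeded synthetic claims cohorts with known ground truth.

Real administrative claims cannot be shipped, so validation is exercised on
simulated cohorts that reproduce the statistical structure the classifier
and its validation assume: clean elective cases for each of the four
combinations, non-elective look-alikes (fracture, neoplasm), cases whose
record carries a non-specific exclusion diagnosis (osteonecrosis) despite an
elective gold-standard indication, dual-coded spine cases carrying both
stenosis and herniated-disc diagnoses, and off-target procedures performed
by the same surgeon panels.

On top of the archetypes, independent per-case Bernoulli corruptions emulate
the documented failure modes of claims extracts: the procedure's billing
code missing from the data (``p_drop_cpt``), the inclusion diagnosis missing
(``p_drop_icd``), a stray exclusion diagnosis in the window
(``p_add_exclusion``), and cross-coding of the two spine conditions
(``p_dual_spine_coding``).

Every generated case records its archetype and the corruptions applied in a
truth table, from which the classification the rule engine *should* produce
is computable case by case (:func:`expected_label`) — a full-cohort oracle
for end-to-end tests.  Identical config and seed give byte-identical output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .claims_io import (
    ClaimEvent,
    GoldLabel,
    SurgicalCase,
    window_events,
    write_cases,
    write_claims,
    write_gold,
)
from .codebook import CodeSystem, ComboId, Panel, normalize_code

__all__ = [
    "ArchetypeSpec",
    "ARCHETYPES",
    "SimulationConfig",
    "CohortDataset",
    "generate_cohort",
    "generate_dual_spine_case",
    "expected_label",
]

#: First surgery date of the simulated enrollment window (two calendar months).
_BASE_DATE = dt.date(2018, 6, 1)
_ENROLL_DAYS = 61

#: Exclusion code guaranteed to fire for every combination of the panel
#: (a child of a wildcard pattern shared by both of the panel's lists).
_PANEL_EXCLUSION = {Panel.SPINE: "R15.9", Panel.HIP_KNEE: "M80.051"}

#: Inclusion ICD-10 added by the dual-spine-coding corruption.
_DUAL_ICD = {"clean_sps": "M51.26", "clean_hd": "M48.062"}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Recipe for one kind of surgical case.

    ``matched_combos`` declares which combinations the emitted codes satisfy
    at the inclusion step; ``base_excluded`` whether the recipe's own
    diagnoses fire the exclusion screen for those combinations.  Gold labels
    are fixed per archetype — corruptions perturb the *data*, never the truth.
    """

    name: str
    panel: Panel
    procedure_category: str
    indications: frozenset[str]
    primary_indication: str
    cpt: tuple[str, ...]
    icd: tuple[str, ...]
    base_exclusion_icd: tuple[str, ...]
    matched_combos: frozenset[ComboId]
    base_excluded: bool
    age_range: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        floor = 21 if self.panel is Panel.SPINE else 40
        if lo < floor or hi < lo:
            raise ValueError(f"{self.name}: age range {self.age_range} below eligibility")


def _arch(**kw) -> ArchetypeSpec:
    kw.setdefault("base_exclusion_icd", ())
    kw.setdefault("base_excluded", False)
    kw["indications"] = frozenset(kw["indications"])
    kw["matched_combos"] = frozenset(kw["matched_combos"])
    return ArchetypeSpec(**kw)


ARCHETYPES: Mapping[str, ArchetypeSpec] = {
    a.name: a
    for a in [
        _arch(
            name="clean_sps",
            panel=Panel.SPINE,
            procedure_category="spinal_surgery",
            indications={"SPS"},
            primary_indication="SPS",
            cpt=("63047",),
            icd=("M48.062",),
            matched_combos={ComboId.SPS},
            age_range=(45, 85),
        ),
        _arch(
            name="clean_hd",
            panel=Panel.SPINE,
            procedure_category="spinal_surgery",
            indications={"HD"},
            primary_indication="HD",
            cpt=("63047", "63030"),
            icd=("M51.26",),
            matched_combos={ComboId.HD},
            age_range=(25, 70),
        ),
        _arch(
            name="dual_spine_sps",
            panel=Panel.SPINE,
            procedure_category="spinal_surgery",
            indications={"SPS", "HD"},
            primary_indication="SPS",
            cpt=("63047",),
            icd=("M48.062", "M51.26"),
            matched_combos={ComboId.SPS, ComboId.HD},
            age_range=(45, 85),
        ),
        _arch(
            name="dual_spine_hd",
            panel=Panel.SPINE,
            procedure_category="spinal_surgery",
            indications={"SPS", "HD"},
            primary_indication="HD",
            cpt=("63047",),
            icd=("M48.062", "M51.26"),
            matched_combos={ComboId.SPS, ComboId.HD},
            age_range=(30, 65),
        ),
        _arch(
            name="clean_koa",
            panel=Panel.HIP_KNEE,
            procedure_category="knee_replacement",
            indications={"KOA"},
            primary_indication="KOA",
            cpt=("27447",),
            icd=("M17.11",),
            matched_combos={ComboId.KOA},
            age_range=(45, 85),
        ),
        _arch(
            name="neoplasm_koa",
            panel=Panel.HIP_KNEE,
            procedure_category="knee_replacement",
            indications={"KOA"},
            primary_indication="other",  # metastatic disease drove the surgery
            cpt=("27447",),
            icd=("M17.11",),
            base_exclusion_icd=("C79.51",),
            matched_combos={ComboId.KOA},
            base_excluded=True,
            age_range=(45, 85),
        ),
        _arch(
            name="clean_hoa",
            panel=Panel.HIP_KNEE,
            procedure_category="hip_replacement",
            indications={"HOA"},
            primary_indication="HOA",
            cpt=("27130",),
            icd=("M16.11",),
            matched_combos={ComboId.HOA},
            age_range=(40, 85),
        ),
        _arch(
            name="osteonecrosis_hoa",
            panel=Panel.HIP_KNEE,
            procedure_category="hip_replacement",
            indications={"HOA"},
            primary_indication="HOA",  # chart review: elective despite the M87 code
            cpt=("27130",),
            icd=("M16.11",),
            base_exclusion_icd=("M87.051",),
            matched_combos={ComboId.HOA},
            base_excluded=True,
            age_range=(40, 85),
        ),
        _arch(
            name="fracture_hoa",
            panel=Panel.HIP_KNEE,
            procedure_category="hip_replacement",
            indications={"HOA"},
            primary_indication="other",  # femoral-neck fracture drove the surgery
            cpt=("27130",),
            icd=("M16.11",),
            base_exclusion_icd=("S72.001",),
            matched_combos={ComboId.HOA},
            base_excluded=True,
            age_range=(40, 85),
        ),
        _arch(
            name="other_spine",
            panel=Panel.SPINE,
            procedure_category="spinal_surgery",
            indications={"other"},
            primary_indication="other",
            cpt=("22551",),  # cervical fusion: not in the lumbar lists
            icd=("M50.21",),
            matched_combos=set(),
            age_range=(25, 80),
        ),
        _arch(
            name="other_hip_knee",
            panel=Panel.HIP_KNEE,
            procedure_category="other",
            indications={"other"},
            primary_indication="other",
            cpt=("29881",),  # knee arthroscopy: not an arthroplasty code
            icd=("M25.561",),
            matched_combos=set(),
            age_range=(40, 80),
        ),
    ]
}

#: Archetype mix emulating the study cohort's distribution of indications
#: (roughly 17% HOA, 15% KOA, 17% SpS, 7% HD, 44% other).
DEFAULT_MIX: Mapping[str, float] = {
    "clean_sps": 0.14,
    "clean_hd": 0.05,
    "dual_spine_sps": 0.015,
    "dual_spine_hd": 0.01,
    "clean_koa": 0.14,
    "neoplasm_koa": 0.005,
    "clean_hoa": 0.14,
    "osteonecrosis_hoa": 0.015,
    "fracture_hoa": 0.01,
    "other_spine": 0.21,
    "other_hip_knee": 0.265,
}

_CORRUPTIONS = ("drop_cpt", "drop_icd", "add_exclusion", "dual_spine_coding")


@dataclass
class SimulationConfig:
    """Cohort size, archetype mix, corruption rates, and the seed."""

    n_cases: int = 790
    mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    p_drop_cpt: float = 0.06
    p_drop_icd: float = 0.02
    p_add_exclusion: float = 0.05
    p_dual_spine_coding: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        unknown = set(self.mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s) in mix: {sorted(unknown)}")
        if any(v < 0 for v in self.mix.values()):
            raise ValueError("mix proportions must be nonnegative")
        if abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"mix proportions must sum to 1, got {sum(self.mix.values())}")
        for name in ("p_drop_cpt", "p_drop_icd", "p_add_exclusion", "p_dual_spine_coding"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "SimulationConfig":
        kw = dict(doc)
        if "mix" in kw:
            kw["mix"] = dict(kw["mix"])
        return cls(**kw)


def expected_label(
    archetype: str,
    age: int,
    *,
    drop_cpt: bool = False,
    drop_icd: bool = False,
    add_exclusion: bool = False,
    dual_spine_coding: bool = False,
    spine_age_threshold: int = 50,
) -> str:
    """Overall label the rule engine should assign, from archetype + corruptions.

    This is declarative bookkeeping over the archetype recipes, independent
    of the classifier's code paths, and serves as the end-to-end oracle.
    """
    spec = ARCHETYPES[archetype]
    matched = set(spec.matched_combos)
    if dual_spine_coding and archetype in _DUAL_ICD:
        matched = {ComboId.SPS, ComboId.HD}
    if drop_cpt or drop_icd:
        matched = set()
    if {ComboId.SPS, ComboId.HD} <= matched:
        matched = {ComboId.SPS} if age >= spine_age_threshold else {ComboId.HD}
    excluded = spec.base_excluded or add_exclusion
    primaries = set() if excluded else matched
    if len(primaries) == 1:
        return next(iter(primaries)).value
    return "other" if not primaries else "ambiguous"


@dataclass
class CohortDataset:
    """A generated cohort: parallel object lists plus the truth table."""

    claims: list[ClaimEvent]
    cases: list[SurgicalCase]
    gold: list[GoldLabel]
    truth: pd.DataFrame

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write claims/cases/gold/truth as delimited text; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "claims": directory / "claims.csv",
            "cases": directory / "cases.csv",
            "gold": directory / "gold.csv",
            "truth": directory / "truth.csv",
        }
        write_claims(self.claims, paths["claims"])
        write_cases(self.cases, paths["cases"])
        write_gold(self.gold, paths["gold"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _icd(display: str):
    return normalize_code(display, CodeSystem.ICD10)


def _cpt(display: str):
    return normalize_code(display, CodeSystem.CPT)


def _emit_case(
    idx: int,
    spec: ArchetypeSpec,
    age: int,
    surgery_date: dt.date,
    flags: Mapping[str, bool],
) -> tuple[SurgicalCase, GoldLabel, list[ClaimEvent]]:
    pid = f"P{idx:05d}"
    case = SurgicalCase(
        case_id=f"C{idx:05d}",
        patient_id=pid,
        surgery_date=surgery_date,
        age_years=age,
        panel=spec.panel,
    )
    gold = GoldLabel(
        case_id=case.case_id,
        procedure_category=spec.procedure_category,
        indications=spec.indications,
        primary_indication=spec.primary_indication,
    )
    on = lambda off: surgery_date - dt.timedelta(days=off)
    events: list[ClaimEvent] = []
    if not flags["drop_cpt"]:
        for c in spec.cpt:
            events.append(ClaimEvent(pid, _cpt(c), on(0)))
    if not flags["drop_icd"]:
        for c in spec.icd:
            events.append(ClaimEvent(pid, _icd(c), on(10)))
        if flags["dual_spine_coding"]:
            events.append(ClaimEvent(pid, _icd(_DUAL_ICD[spec.name]), on(12)))
    for c in spec.base_exclusion_icd:
        events.append(ClaimEvent(pid, _icd(c), on(5)))
    if flags["add_exclusion"]:
        events.append(ClaimEvent(pid, _icd(_PANEL_EXCLUSION[spec.panel]), on(7)))
    # realistic clutter: a pre-operative encounter code (matches nothing) and
    # an exclusion-list diagnosis safely outside the 90-day window
    events.append(ClaimEvent(pid, _icd("Z01.818"), on(30)))
    events.append(ClaimEvent(pid, _icd(_PANEL_EXCLUSION[spec.panel]), on(120)))
    return case, gold, events


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a reproducible cohort under *config* (same seed → same bytes)."""
    rng = np.random.default_rng(config.seed)
    names = sorted(config.mix)
    probs = np.array([config.mix[n] for n in names])
    probs = probs / probs.sum()
    draws = rng.choice(len(names), size=config.n_cases, p=probs)

    claims: list[ClaimEvent] = []
    cases: list[SurgicalCase] = []
    gold: list[GoldLabel] = []
    truth_rows = []
    for idx, k in enumerate(draws):
        spec = ARCHETYPES[names[k]]
        lo, hi = spec.age_range
        age = int(rng.integers(lo, hi + 1))
        surgery_date = _BASE_DATE + dt.timedelta(days=int(rng.integers(0, _ENROLL_DAYS)))
        flags = {
            "drop_cpt": bool(rng.random() < config.p_drop_cpt),
            "drop_icd": bool(rng.random() < config.p_drop_icd),
            "add_exclusion": bool(rng.random() < config.p_add_exclusion),
            "dual_spine_coding": spec.name in _DUAL_ICD
            and bool(rng.random() < config.p_dual_spine_coding),
        }
        case, label, events = _emit_case(idx, spec, age, surgery_date, flags)
        cases.append(case)
        gold.append(label)
        claims.extend(events)
        truth_rows.append(
            {
                "case_id": case.case_id,
                "archetype": spec.name,
                "age_years": age,
                **{c: flags[c] for c in _CORRUPTIONS},
                "expected_label": expected_label(spec.name, age, **flags),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["case_id", "archetype", "age_years", *_CORRUPTIONS, "expected_label"],
    )
    return CohortDataset(claims=claims, cases=cases, gold=gold, truth=truth)


def generate_dual_spine_case(
    age: int, rng: np.random.Generator, gold_primary: str = "HD"
) -> tuple[SurgicalCase, GoldLabel]:
    """One windowed dual-coded spine case (shared CPT + both spine diagnoses).

    The gold primary indication is declared by the caller; whether the
    engine's age tie-break agrees with it is exactly what this fixture lets
    tests probe.
    """
    if age < 21:
        raise ValueError("spine cases require age >= 21")
    if gold_primary not in ("SPS", "HD"):
        raise ValueError("gold_primary must be SPS or HD")
    name = "dual_spine_sps" if gold_primary == "SPS" else "dual_spine_hd"
    spec = ARCHETYPES[name]
    idx = int(rng.integers(0, 100000))
    surgery_date = _BASE_DATE + dt.timedelta(days=int(rng.integers(0, _ENROLL_DAYS)))
    flags = dict.fromkeys(_CORRUPTIONS, False)
    case, label, events = _emit_case(idx, spec, age, surgery_date, flags)
    return window_events(case, events), label
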