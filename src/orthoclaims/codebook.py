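"""Code sets for the four procedure / primary-indication combinations.

The classification engine matches administrative billing codes (ICD-10-CM
diagnoses and CPT procedures) against per-combination inclusion and exclusion
lists.  ICD-10 is a lexical hierarchy once dots are removed: the children of
``M80`` are exactly the codes whose dot-free string starts with ``M80``, so a
hierarchical ("wildcard") entry reduces to a string-prefix match on normalized
codes.  CPT codes are flat five-character identifiers and are always matched
exactly.

The default codebook shipped with the package covers four elective
surgery/indication pairs: lumbar spinal surgery for spinal stenosis (SPS) or
herniated disc (HD), hip arthroplasty for hip osteoarthritis (HOA), and knee
arthroplasty for knee osteoarthritis (KOA).  Codebooks are data, not code: a
YAML document mirroring those lists can be edited and re-loaded to adapt the
engine to other institutions' coding practice.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "CodeSystem",
    "ComboId",
    "Panel",
    "Code",
    "CodePattern",
    "CombinationDefinition",
    "Codebook",
    "CodebookError",
    "MalformedCodeError",
    "normalize_code",
    "pattern_matches",
    "load_codebook",
    "default_codebook",
    "serialize_codebook",
]

_ICD10_RE = re.compile(r"^[A-Z][0-9A-Z]+$")
_CPT_RE = re.compile(r"^[0-9A-Z]{5}$")


class CodeSystem(str, enum.Enum):
    """Coding system of a billed code."""

    ICD10 = "ICD10"
    CPT = "CPT"


class ComboId(str, enum.Enum):
    """The four procedure / primary-indication combinations."""

    SPS = "SPS"  # spinal surgery / lumbar spinal stenosis
    HD = "HD"    # spinal surgery / lumbar herniated disc
    KOA = "KOA"  # knee arthroplasty / knee osteoarthritis
    HOA = "HOA"  # hip arthroplasty / hip osteoarthritis


class Panel(str, enum.Enum):
    """Surgeon-specialty panel a surgical case belongs to."""

    SPINE = "spine"
    HIP_KNEE = "hip_knee"


PANEL_OF_COMBO: Mapping[ComboId, Panel] = {
    ComboId.SPS: Panel.SPINE,
    ComboId.HD: Panel.SPINE,
    ComboId.KOA: Panel.HIP_KNEE,
    ComboId.HOA: Panel.HIP_KNEE,
}


class CodebookError(ValueError):
    """Raised for structurally invalid codebook configurations."""


class MalformedCodeError(ValueError):
    """Raised when a raw code string cannot be normalized."""


@dataclass(frozen=True, order=True)
class Code:
    """A normalized billed code: uppercase dot-free ICD-10, or 5-char CPT."""

    system: CodeSystem
    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise MalformedCodeError("empty code value")
        if self.system is CodeSystem.ICD10 and not _ICD10_RE.match(self.value):
            raise MalformedCodeError(f"invalid normalized ICD-10 value: {self.value!r}")
        if self.system is CodeSystem.CPT and not _CPT_RE.match(self.value):
            raise MalformedCodeError(f"invalid normalized CPT value: {self.value!r}")


@dataclass(frozen=True, order=True)
class CodePattern:
    """An exact or hierarchical matcher over normalized codes.

    ``hierarchical`` patterns match every child in the ICD-10 hierarchy, i.e.
    every code whose normalized value extends the stem as a string prefix.
    Only ICD-10 patterns may be hierarchical.
    """

    system: CodeSystem
    stem: str
    hierarchical: bool = False

    def __post_init__(self) -> None:
        # reuse Code's normalization invariants for the stem
        Code(self.system, self.stem)
        if self.hierarchical and self.system is not CodeSystem.ICD10:
            raise CodebookError(f"hierarchical pattern on non-ICD-10 stem {self.stem!r}")

    @property
    def display(self) -> str:
        """Stem with a trailing ``*`` when hierarchical (config/report form)."""
        return self.stem + ("*" if self.hierarchical else "")


def normalize_code(raw: str, system: CodeSystem | str) -> Code:
    """Normalize a raw code string into a :class:`Code`.

    ICD-10 codes are uppercased and stripped of dots and whitespace so that
    the hierarchy becomes a string prefix; CPT codes are stripped of
    whitespace only.  Normalization is idempotent.

    Raises
    ------
    MalformedCodeError
        If the string is empty after trimming, a CPT code is not exactly five
        characters, or an ICD-10 code does not start with a letter.
    """
    system = CodeSystem(system)
    value = raw.strip()
    if not value:
        raise MalformedCodeError(f"empty code after trimming: {raw!r}")
    if system is CodeSystem.ICD10:
        value = value.upper().replace(".", "")
        if not _ICD10_RE.match(value):
            raise MalformedCodeError(f"malformed ICD-10 code: {raw!r}")
    else:
        value = value.upper()
        if not _CPT_RE.match(value):
            raise MalformedCodeError(f"malformed CPT code (need 5 characters): {raw!r}")
    return Code(system, value)


def pattern_matches(pattern: CodePattern, code: Code) -> bool:
    """True iff *code* matches *pattern*.

    Exact patterns require string equality with the stem; hierarchical
    patterns match any code whose normalized value starts with the stem.
    """
    if pattern.system is not code.system:
        raise ValueError(
            f"system mismatch: pattern {pattern.system.value} vs code {code.system.value}"
        )
    if pattern.hierarchical:
        return code.value.startswith(pattern.stem)
    return code.value == pattern.stem


def _parse_pattern(entry: str, *, force_hierarchical: bool = False) -> CodePattern:
    entry = entry.strip()
    hierarchical = entry.endswith("*")
    stem = entry[:-1] if hierarchical else entry
    code = normalize_code(stem, CodeSystem.ICD10)
    return CodePattern(CodeSystem.ICD10, code.value, hierarchical or force_hierarchical)


@dataclass(frozen=True)
class CombinationDefinition:
    """Inclusion/exclusion rule set for one procedure/indication combination."""

    id: ComboId
    label: str
    panel: Panel
    inclusion_cpt: frozenset[Code]
    inclusion_icd: frozenset[CodePattern]
    exclusion_icd: frozenset[CodePattern]

    def __post_init__(self) -> None:
        for name in ("inclusion_cpt", "inclusion_icd", "exclusion_icd"):
            if not getattr(self, name):
                raise CodebookError(f"{self.id.value}: empty {name}")
        if PANEL_OF_COMBO[self.id] is not self.panel:
            raise CodebookError(
                f"{self.id.value}: panel must be {PANEL_OF_COMBO[self.id].value}"
            )


@dataclass(frozen=True)
class Codebook:
    """The full rule set: one definition per combination plus the age tie-break.

    ``spine_age_threshold_years`` resolves surgical cases matching both spine
    indications: at or above the threshold the case is called spinal stenosis,
    below it herniated disc.  ``inclusion_hierarchy`` records whether the
    inclusion ICD-10 lists were loaded with hierarchy (prefix) semantics; by
    default only asterisked exclusion entries are hierarchical.
    """

    definitions: Mapping[ComboId, CombinationDefinition]
    spine_age_threshold_years: int = 50
    inclusion_hierarchy: bool = False

    def __post_init__(self) -> None:
        missing = set(ComboId) - set(self.definitions)
        if missing:
            raise CodebookError(
                "missing combinations: " + ", ".join(sorted(m.value for m in missing))
            )
        if self.spine_age_threshold_years <= 0:
            raise CodebookError("spine_age_threshold_years must be positive")

    def __getitem__(self, combo: ComboId) -> CombinationDefinition:
        return self.definitions[combo]

    def for_panel(self, panel: Panel) -> list[CombinationDefinition]:
        """Definitions applicable to one surgeon-specialty panel."""
        return [d for d in self.definitions.values() if d.panel is panel]


def _build_definition(
    raw: Mapping, *, inclusion_hierarchy: bool
) -> CombinationDefinition:
    try:
        combo = ComboId(raw["id"])
    except (KeyError, ValueError) as exc:
        raise CodebookError(f"unknown or missing combination id in {raw!r}") from exc
    for key in ("inclusion_cpt", "inclusion_icd", "exclusion_icd"):
        if not raw.get(key):
            raise CodebookError(f"{combo.value}: missing or empty {key!r}")
    return CombinationDefinition(
        id=combo,
        label=str(raw.get("label", combo.value)),
        panel=Panel(raw["panel"]),
        inclusion_cpt=frozenset(
            normalize_code(str(c), CodeSystem.CPT) for c in raw["inclusion_cpt"]
        ),
        inclusion_icd=frozenset(
            _parse_pattern(str(c), force_hierarchical=inclusion_hierarchy)
            for c in raw["inclusion_icd"]
        ),
        exclusion_icd=frozenset(_parse_pattern(str(c)) for c in raw["exclusion_icd"]),
    )


def load_codebook(
    source: str | Path | Mapping, *, inclusion_hierarchy: bool | None = None
) -> Codebook:
    """Load a codebook from a YAML file path or an already-parsed mapping.

    Parameters
    ----------
    source
        Path to a YAML config, or the equivalent mapping.
    inclusion_hierarchy
        Override the config's ``inclusion_hierarchy`` flag.  When true,
        inclusion ICD-10 entries match hierarchically (all children) even
        without an asterisk; the default (false) matches them exactly.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise CodebookError("codebook config must be a mapping")
    if inclusion_hierarchy is None:
        inclusion_hierarchy = bool(doc.get("inclusion_hierarchy", False))
    combos = doc.get("combinations")
    if not combos:
        raise CodebookError("config declares no combinations")
    definitions: dict[ComboId, CombinationDefinition] = {}
    for raw in combos:
        d = _build_definition(raw, inclusion_hierarchy=inclusion_hierarchy)
        if d.id in definitions:
            raise CodebookError(f"duplicate combination {d.id.value}")
        definitions[d.id] = d
    return Codebook(
        definitions=definitions,
        spine_age_threshold_years=int(doc.get("spine_age_threshold_years", 50)),
        inclusion_hierarchy=inclusion_hierarchy,
    )


def default_codebook(*, inclusion_hierarchy: bool | None = None) -> Codebook:
    """The packaged default code lists."""
    ref = resources.files("orthoclaims.data").joinpath("default_codebook.yaml")
    with resources.as_file(ref) as path:
        return load_codebook(path, inclusion_hierarchy=inclusion_hierarchy)


def serialize_codebook(codebook: Codebook) -> dict:
    """Round-trippable plain-dict form of a codebook (YAML-ready)."""

    def _icd_entries(patterns: Iterable[CodePattern], strip_forced: bool) -> list[str]:
        # when inclusion_hierarchy forced every inclusion pattern hierarchical,
        # serialize those without the asterisk so a reload reproduces them
        out = []
        for p in sorted(patterns):
            if strip_forced and codebook.inclusion_hierarchy:
                out.append(p.stem)
            else:
                out.append(p.display)
        return out

    return {
        "spine_age_threshold_years": codebook.spine_age_threshold_years,
        "inclusion_hierarchy": codebook.inclusion_hierarchy,
        "combinations": [
            {
                "id": d.id.value,
                "label": d.label,
                "panel": d.panel.value,
                "inclusion_cpt": sorted(c.value for c in d.inclusion_cpt),
                "inclusion_icd": _icd_entries(d.inclusion_icd, strip_forced=True),
                "exclusion_icd": _icd_entries(d.exclusion_icd, strip_forced=False),
            }
            for d in (codebook[c] for c in ComboId)
        ],
    }
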