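"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import HealthCheck, settings
from scipy import stats

import orthoclaims as oc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SURGERY = dt.date(2018, 6, 15)


@pytest.fixture(scope="session")
def codebook() -> oc.Codebook:
    return oc.default_codebook()


def make_case(
    case_id: str,
    panel: oc.Panel,
    age: int,
    codes: list[tuple[str, str]],
    *,
    offsets: list[int] | None = None,
    surgery: dt.date = SURGERY,
) -> oc.SurgicalCase:
    """Build a windowed surgical case from (system, display-code) pairs."""
    if offsets is None:
        offsets = [0] * len(codes)
    pid = "pt-" + case_id
    events = [
        oc.ClaimEvent(
            pid,
            oc.normalize_code(code, oc.CodeSystem(system)),
            surgery - dt.timedelta(days=off),
        )
        for (system, code), off in zip(codes, offsets, strict=True)
    ]
    case = oc.SurgicalCase(
        case_id=case_id, patient_id=pid, surgery_date=surgery, age_years=age, panel=panel
    )
    return oc.window_events(case, events)


@pytest.fixture
def case_factory():
    return make_case


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_classify(case: oc.SurgicalCase, codebook: oc.Codebook) -> dict:
    """Naive re-implementation of the two-step rules via raw string scans.

    Works from the codebook's serialized (display-string) form with nested
    loops and startswith/equality only — no shared code paths with the
    engine's matching.  Returns per-combination statuses and the overall
    label.
    """
    from orthoclaims.codebook import serialize_codebook

    doc = serialize_codebook(codebook)
    window_cpt = [e.code.value for e in case.window_events if e.code.system.value == "CPT"]
    window_icd = [e.code.value for e in case.window_events if e.code.system.value == "ICD10"]

    def icd_matches(entry: str, value: str) -> bool:
        entry = entry.upper().replace(".", "")
        if entry.endswith("*"):
            return value.startswith(entry[:-1])
        return value == entry

    matched: dict[str, bool] = {}
    excluded: dict[str, bool] = {}
    for combo in doc["combinations"]:
        if combo["panel"] != case.panel.value:
            matched[combo["id"]] = False
            excluded[combo["id"]] = False
            continue
        has_cpt = any(v == c for v in window_cpt for c in combo["inclusion_cpt"])
        has_icd = False
        for v in window_icd:
            for entry in combo["inclusion_icd"]:
                star = "*" if codebook.inclusion_hierarchy else ""
                if icd_matches(entry + star, v):
                    has_icd = True
        matched[combo["id"]] = has_cpt and has_icd
        hit = False
        for v in window_icd:
            for entry in combo["exclusion_icd"]:
                if icd_matches(entry, v):
                    hit = True
        excluded[combo["id"]] = hit

    if matched.get("SPS") and matched.get("HD"):
        if case.age_years >= doc["spine_age_threshold_years"]:
            matched["HD"] = False
        else:
            matched["SPS"] = False

    status = {}
    for cid in ("SPS", "HD", "KOA", "HOA"):
        if not matched[cid]:
            status[cid] = "not_indicated"
        elif excluded[cid]:
            status[cid] = "secondary"
        else:
            status[cid] = "primary"
    primaries = [c for c, s in status.items() if s == "primary"]
    overall = primaries[0] if len(primaries) == 1 else ("other" if not primaries else "ambiguous")
    return {"status": status, "overall": overall, "matched": matched}


def clopper_pearson_bisect(x: int, n: int, alpha: float = 0.05, tol: float = 1e-12):
    """Exact interval by direct bisection on the binomial tail probabilities."""

    def solve(f, lo: float, hi: float) -> float:
        # f is monotone increasing in p; find f(p) = 0
        for _ in range(100):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else solve(
        lambda p: (1 - stats.binom.cdf(x - 1, n, p)) - alpha / 2, 0.0, 1.0
    )
    upper = 1.0 if x == n else solve(
        lambda p: (alpha / 2) - stats.binom.cdf(x, n, p), 0.0, 1.0
    )
    return lower, upper
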