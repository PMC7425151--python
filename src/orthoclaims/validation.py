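"""Diagnostic-accuracy validation of the classifier against chart review.

The classifier and the gold-standard chart review both label cases at two
levels: whether a combination's condition is *an* indication for the
procedure, and whether it is the *primary* indication.  For each combination
and level this module builds the two-by-two confusion table over the
panel-restricted case set and estimates

    sensitivity  Se = TP / (TP + FN)        (among gold positives)
    specificity  Sp = TN / (TN + FP)        (among gold negatives)

with exact Clopper–Pearson confidence intervals, obtained by inverting the
binomial tail probabilities (equivalently, beta-distribution quantiles):

    lower = BetaInv(alpha/2; x, n - x + 1)       (0 when x = 0)
    upper = BetaInv(1 - alpha/2; x + 1, n - x)   (1 when x = n)

Predictive values at an arbitrary prior probability p (the prevalence of the
target combination in the population the classifier is applied to) follow
from Bayes' rule:

    PPV(p) = Se p / (Se p + (1 - Sp)(1 - p))
    NPV(p) = Sp (1 - p) / (Sp (1 - p) + (1 - Se) p)

Inter-rater agreement of the chart review itself is summarized by Cohen's
kappa, (po - pe) / (1 - pe).

The estimation surface follows the Model/Results convention: build an
:class:`AlgorithmValidation` from predictions and gold labels, call
:meth:`~AlgorithmValidation.fit`, and read estimates off the returned
:class:`ValidationResults` (or print ``results.summary()``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .claims_io import GoldLabel
from .classifier import CaseClassification, Status
from .codebook import ComboId, PANEL_OF_COMBO

__all__ = [
    "Level",
    "ConfusionCounts",
    "MetricEstimate",
    "UndefinedMetricError",
    "confusion",
    "sensitivity",
    "specificity",
    "clopper_pearson",
    "predictive_values",
    "pv_curve",
    "cohens_kappa",
    "misclassification_report",
    "AlgorithmValidation",
    "ValidationResults",
]


class Level(str, enum.Enum):
    """Classification level being validated."""

    INDICATION = "indication"
    PRIMARY_INDICATION = "primary_indication"


class UndefinedMetricError(ZeroDivisionError):
    """A metric was requested with an empty denominator."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-by-two agreement counts for one combination at one level."""

    tp: int
    fp: int
    fn: int
    tn: int
    level: Level
    combination: ComboId

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def gold_positive(self) -> int:
        return self.tp + self.fn

    @property
    def gold_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion estimate with its exact binomial confidence interval."""

    metric: str  # "sensitivity" | "specificity"
    point: float
    ci_low: float
    ci_high: float
    n: int
    alpha: float = 0.05

    def __str__(self) -> str:
        return f"{self.point:.2f} ({self.ci_low:.2f}, {self.ci_high:.2f})"


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided confidence interval for x/n."""
    if not 0 <= x <= n or n < 1:
        raise ValueError(f"require 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def _proportion_estimate(
    metric: str, successes: int, n: int, alpha: float
) -> MetricEstimate:
    if n < 1:
        raise UndefinedMetricError(f"{metric} undefined: empty denominator")
    low, high = clopper_pearson(successes, n, alpha)
    return MetricEstimate(metric, successes / n, low, high, n, alpha)


def sensitivity(counts: ConfusionCounts, alpha: float = 0.05) -> MetricEstimate:
    """Sensitivity tp/(tp+fn) with exact CI; errors on zero gold positives."""
    return _proportion_estimate("sensitivity", counts.tp, counts.gold_positive, alpha)


def specificity(counts: ConfusionCounts, alpha: float = 0.05) -> MetricEstimate:
    """Specificity tn/(tn+fp) with exact CI; errors on zero gold negatives."""
    return _proportion_estimate("specificity", counts.tn, counts.gold_negative, alpha)


def predictive_values(se: float, sp: float, p: float) -> tuple[float, float]:
    """PPV and NPV at prior probability ``p`` via Bayes' rule.

    An undefined value (zero denominator, e.g. PPV at p=0 with perfect
    specificity) is returned as ``nan``, never as 0.
    """
    for name, v in (("sensitivity", se), ("specificity", sp), ("prior", p)):
        if not 0 <= v <= 1 or math.isnan(v):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    ppv_den = se * p + (1 - sp) * (1 - p)
    npv_den = sp * (1 - p) + (1 - se) * p
    ppv = se * p / ppv_den if ppv_den > 0 else math.nan
    npv = sp * (1 - p) / npv_den if npv_den > 0 else math.nan
    return ppv, npv


def pv_curve(
    se: float,
    sp: float,
    grid: Sequence[float],
    *,
    combination: str = "",
    marks: Sequence[float] = (),
) -> pd.DataFrame:
    """Evaluate PPV/NPV over a sorted grid of priors (plus optional marks).

    Returns a frame with columns ``combination, p, ppv, npv, mark`` where
    ``mark`` is true for rows added via *marks* (e.g. a study's observed
    prevalence).
    """
    grid = list(grid)
    if any(not 0 <= p <= 1 for p in grid) or list(grid) != sorted(grid):
        raise ValueError("grid must be sorted and within [0, 1]")
    rows = [(combination, p, *predictive_values(se, sp, p), False) for p in grid]
    rows += [(combination, p, *predictive_values(se, sp, p), True) for p in marks]
    df = pd.DataFrame(rows, columns=["combination", "p", "ppv", "npv", "mark"])
    return df.sort_values(["p", "mark"], kind="stable").reset_index(drop=True)


def cohens_kappa(table) -> float:
    """Unweighted Cohen's kappa from a square rater-by-rater count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"rater table must be square, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("rater table counts must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("rater table must have positive total")
    po = np.trace(arr) / total
    pe = float((arr.sum(axis=1) / total) @ (arr.sum(axis=0) / total))
    if po == 1.0:
        return 1.0
    if pe == 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return (po - pe) / (1 - pe)


def _join(
    predictions: Sequence[CaseClassification], gold: Sequence[GoldLabel]
) -> list[tuple[CaseClassification, GoldLabel]]:
    pred_by_id = {p.case_id: p for p in predictions}
    gold_by_id = {g.case_id: g for g in gold}
    if len(pred_by_id) != len(predictions):
        raise ValueError("duplicate case_id among predictions")
    if len(gold_by_id) != len(gold):
        raise ValueError("duplicate case_id among gold labels")
    orphans = sorted(set(pred_by_id) ^ set(gold_by_id))
    if orphans:
        raise ValueError(f"unmatched case_id(s) between predictions and gold: {orphans}")
    return [(pred_by_id[i], gold_by_id[i]) for i in sorted(pred_by_id)]


def confusion(
    level: Level,
    combination: ComboId,
    predictions: Sequence[CaseClassification],
    gold: Sequence[GoldLabel],
    *,
    panel_restriction: bool = True,
) -> ConfusionCounts:
    """Two-by-two counts for one combination at one classification level.

    Predictions and gold labels must join 1:1 on ``case_id``.  With panel
    restriction (the validated setting) only cases from the combination's own
    surgeon panel enter the table.
    """
    level = Level(level)
    combination = ComboId(combination)
    pairs = _join(predictions, gold)
    panel = PANEL_OF_COMBO[combination]
    tp = fp = fn = tn = 0
    for pred, ref in pairs:
        if panel_restriction and pred.panel is not panel:
            continue
        if level is Level.INDICATION:
            pred_pos = pred.matched(combination)
            gold_pos = combination.value in ref.indications
        else:
            pred_pos = pred.status_of(combination) is Status.PRIMARY
            gold_pos = ref.primary_indication == combination.value
        if pred_pos and gold_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif gold_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn, level, combination)


# ---------------------------------------------------------------------------
# misclassification audit


def _fn_cause(pred: CaseClassification, combination: ComboId) -> str:
    result = pred.combos.get(combination)
    if result is None:
        return "unresolved"
    if result.status is Status.SECONDARY:
        patterns = sorted({p.display for p, _ in result.exclusion_hits})
        return "exclusion_demotion:" + ";".join(patterns) if patterns else "exclusion_demotion"
    spine = combination in (ComboId.SPS, ComboId.HD)
    if spine and pred.tie_break_applied:
        return "tie_break_override"
    if not result.matched_cpt:
        return "missing_cpt"
    if not result.matched_icd:
        return "missing_icd"
    return "unresolved"


def misclassification_report(
    predictions: Sequence[CaseClassification],
    gold: Sequence[GoldLabel],
    *,
    panel_restriction: bool = True,
) -> pd.DataFrame:
    """Audit of primary-level false positives/negatives with mechanical causes.

    Each error is tagged with the cause recoverable from the claims data
    alone: ``exclusion_demotion:<patterns>`` (the indication was demoted to
    secondary by the listed exclusion patterns), ``tie_break_override`` (the
    spine age rule swapped stenosis and herniated disc), ``missing_cpt`` /
    ``missing_icd`` (no inclusion code of that kind in the window), else
    ``unresolved`` (would require chart review).
    """
    rows = []
    pairs = _join(predictions, gold)
    for combination in ComboId:
        panel = PANEL_OF_COMBO[combination]
        for pred, ref in pairs:
            if panel_restriction and pred.panel is not panel:
                continue
            pred_pos = pred.status_of(combination) is Status.PRIMARY
            gold_pos = ref.primary_indication == combination.value
            if pred_pos and not gold_pos:
                spine = combination in (ComboId.SPS, ComboId.HD)
                cause = "tie_break_override" if spine and pred.tie_break_applied else "unresolved"
                rows.append((pred.case_id, combination.value, "false_positive", cause))
            elif gold_pos and not pred_pos:
                rows.append(
                    (pred.case_id, combination.value, "false_negative", _fn_cause(pred, combination))
                )
    return pd.DataFrame(rows, columns=["case_id", "combination", "error", "cause"])


# ---------------------------------------------------------------------------
# Model / Results surface


class AlgorithmValidation:
    """Validation study of classifier output against gold-standard labels.

    Parameters
    ----------
    predictions
        Classifier output, one :class:`CaseClassification` per case.
    gold
        Chart-review labels joining 1:1 on ``case_id``.
    panel_restriction
        Evaluate each combination only on its own surgeon panel (default).
    """

    def __init__(
        self,
        predictions: Sequence[CaseClassification],
        gold: Sequence[GoldLabel],
        *,
        panel_restriction: bool = True,
    ) -> None:
        self.predictions = list(predictions)
        self.gold = list(gold)
        self.panel_restriction = panel_restriction
        _join(self.predictions, self.gold)  # fail fast on orphans/duplicates

    def fit(self, alpha: float = 0.05) -> "ValidationResults":
        """Compute confusion counts and metric estimates at both levels."""
        counts: dict[tuple[Level, ComboId], ConfusionCounts] = {}
        estimates: dict[tuple[Level, ComboId, str], MetricEstimate | None] = {}
        for level in Level:
            for combo in ComboId:
                c = confusion(
                    level,
                    combo,
                    self.predictions,
                    self.gold,
                    panel_restriction=self.panel_restriction,
                )
                counts[(level, combo)] = c
                for metric, fn in (("sensitivity", sensitivity), ("specificity", specificity)):
                    try:
                        estimates[(level, combo, metric)] = fn(c, alpha)
                    except UndefinedMetricError:
                        estimates[(level, combo, metric)] = None
        return ValidationResults(self, counts, estimates, alpha)


class ValidationResults:
    """Fitted validation results: counts, estimates, CIs, audit, summary."""

    def __init__(
        self,
        model: AlgorithmValidation,
        counts: Mapping[tuple[Level, ComboId], ConfusionCounts],
        estimates: Mapping[tuple[Level, ComboId, str], MetricEstimate | None],
        alpha: float,
    ) -> None:
        self.model = model
        self.counts = dict(counts)
        self.estimates = dict(estimates)
        self.alpha = alpha

    def confusion(self, level: Level | str, combination: ComboId | str) -> ConfusionCounts:
        return self.counts[(Level(level), ComboId(combination))]

    def estimate(
        self, level: Level | str, combination: ComboId | str, metric: str
    ) -> MetricEstimate | None:
        return self.estimates[(Level(level), ComboId(combination), metric)]

    def misclassification_report(self) -> pd.DataFrame:
        return misclassification_report(
            self.model.predictions,
            self.model.gold,
            panel_restriction=self.model.panel_restriction,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format results table (one row per level × combination × metric)."""
        rows = []
        for (level, combo, metric), est in self.estimates.items():
            c = self.counts[(level, combo)]
            rows.append(
                {
                    "level": level.value,
                    "combination": combo.value,
                    "metric": metric,
                    "estimate": est.point if est else math.nan,
                    "ci_low": est.ci_low if est else math.nan,
                    "ci_high": est.ci_high if est else math.nan,
                    "n": est.n if est else 0,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """JSON-ready nested form (full precision)."""
        out: dict = {"alpha": self.alpha, "panel_restriction": self.model.panel_restriction}
        for level in Level:
            out[level.value] = {}
            for combo in ComboId:
                c = self.counts[(level, combo)]
                entry = {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}
                for metric in ("sensitivity", "specificity"):
                    est = self.estimates[(level, combo, metric)]
                    entry[metric] = (
                        None
                        if est is None
                        else {
                            "point": est.point,
                            "ci_low": est.ci_low,
                            "ci_high": est.ci_high,
                            "n": est.n,
                        }
                    )
                out[level.value][combo.value] = entry
        return out

    def summary(self) -> str:
        """Human-readable summary table (estimates rounded to 2 decimals)."""
        lines = [
            "Algorithm validation against gold-standard review",
            f"cases: {len(self.model.predictions)}   alpha: {self.alpha}   "
            f"panel restriction: {self.model.panel_restriction}",
            "",
            f"{'level':<20}{'combination':<13}{'sensitivity':<21}{'specificity':<21}",
            "-" * 75,
        ]
        for level in Level:
            for combo in ComboId:
                cells = []
                for metric in ("sensitivity", "specificity"):
                    est = self.estimates[(level, combo, metric)]
                    cells.append(str(est) if est else "undefined")
                lines.append(f"{level.value:<20}{combo.value:<13}{cells[0]:<21}{cells[1]:<21}")
        return "\n".join(lines)
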