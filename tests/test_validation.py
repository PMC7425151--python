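"""Confusion counts, exact binomial intervals, predictive values, and kappa."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import orthoclaims as oc
from orthoclaims.validation import (
    ConfusionCounts,
    Level,
    UndefinedMetricError,
    clopper_pearson,
    cohens_kappa,
    confusion,
    predictive_values,
    pv_curve,
    sensitivity,
    specificity,
)

from conftest import clopper_pearson_bisect, make_case

KOA = oc.ComboId.KOA
PRIMARY = Level.PRIMARY_INDICATION


def _counts(tp, fp, fn, tn, level=PRIMARY, combo=KOA):
    return ConfusionCounts(tp, fp, fn, tn, level, combo)


class TestConfusion:
    def _perfect_pair(self, n_pos=4, n_neg=6):
        preds, gold = [], []
        for i in range(n_pos + n_neg):
            positive = i < n_pos
            codes = [("CPT", "27447"), ("ICD10", "M17.11")] if positive else []
            case = make_case(f"C{i}", oc.Panel.HIP_KNEE, 70, codes)
            preds.append(oc.classify_case(case, oc.default_codebook()))
            gold.append(
                oc.GoldLabel(
                    f"C{i}",
                    "knee_replacement" if positive else "other",
                    frozenset({"KOA"} if positive else {"other"}),
                    "KOA" if positive else "other",
                )
            )
        return preds, gold

    def test_perfect_agreement(self):
        preds, gold = self._perfect_pair()
        c = confusion(PRIMARY, KOA, preds, gold)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 6)

    def test_all_other_predictions(self):
        preds, gold = self._perfect_pair()
        blank = [
            oc.classify_case(make_case(p.case_id, oc.Panel.HIP_KNEE, 70, []), oc.default_codebook())
            for p in preds
        ]
        c = confusion(PRIMARY, KOA, blank, gold)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 4, 6)

    def test_counts_partition_cases(self):
        preds, gold = self._perfect_pair()
        for level in Level:
            c = confusion(level, KOA, preds, gold)
            assert c.total == len(preds)

    def test_orphan_case_ids_rejected(self):
        preds, gold = self._perfect_pair()
        with pytest.raises(ValueError, match="unmatched"):
            confusion(PRIMARY, KOA, preds, gold[:-1])

    def test_study_scale_reconstruction(self):
        """Planted error counts at the study's scale flow through correctly."""
        book = oc.default_codebook()
        preds, gold = [], []
        idx = 0

        def add(n, codes, gold_primary):
            nonlocal idx
            for _ in range(n):
                case = make_case(f"C{idx}", oc.Panel.HIP_KNEE, 70, codes)
                preds.append(oc.classify_case(case, book))
                positive = gold_primary == "KOA"
                gold.append(
                    oc.GoldLabel(
                        f"C{idx}",
                        "knee_replacement" if positive else "other",
                        frozenset({gold_primary}),
                        gold_primary,
                    )
                )
                idx += 1

        koa_codes = [("CPT", "27447"), ("ICD10", "M17.11")]
        add(106, koa_codes, "KOA")          # true positives
        add(9, [], "KOA")                   # false negatives: missing codes
        add(2, koa_codes, "other")          # false positives
        add(306, [], "other")               # true negatives
        c = confusion(PRIMARY, KOA, preds, gold)
        assert (c.tp, c.fn, c.fp, c.tn) == (106, 9, 2, 306)
        assert round(sensitivity(c).point, 2) == 0.92


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "tp, fn, expected",
        [(106, 9, 0.92), (37, 16, 0.70), (97, 30, 0.76), (107, 21, 0.84), (0, 5, 0.00)],
    )
    def test_sensitivity_values(self, tp, fn, expected):
        est = sensitivity(_counts(tp, 0, fn, 0))
        assert round(est.point, 2) == expected
        assert est.n == tp + fn

    def test_specificity(self):
        est = specificity(_counts(0, 2, 0, 306))
        assert est.point == pytest.approx(306 / 308)

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(_counts(0, 3, 0, 7))
        with pytest.raises(UndefinedMetricError):
            specificity(_counts(3, 0, 7, 0))

    def test_ci_ordering_invariant(self):
        est = sensitivity(_counts(37, 0, 16, 0))
        assert 0 <= est.ci_low <= est.point <= est.ci_high <= 1


class TestClopperPearson:
    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_published_style_values(self):
        low, high = clopper_pearson(37, 53)
        assert (round(low, 2), round(high, 2)) == (0.56, 0.82)
        assert round(clopper_pearson(106, 115)[0], 2) == 0.86

    def test_domain_violations(self):
        for x, n, alpha in [(-1, 10, 0.05), (11, 10, 0.05), (0, 0, 0.05), (1, 10, 0)]:
            with pytest.raises(ValueError):
                clopper_pearson(x, n, alpha)

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(0, 10), (3, 10), (37, 53), (106, 115), (115, 115)]:
            expected = proportion_confint(x, n, alpha=0.05, method="beta")
            got = clopper_pearson(x, n)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_equals_binomial_tail_bisection_small_n(self):
        """Spot-equivalence with the direct tail-inversion oracle."""
        for x, n in [(0, 1), (1, 1), (2, 7), (5, 20), (30, 60), (59, 60)]:
            assert clopper_pearson(x, n) == pytest.approx(
                clopper_pearson_bisect(x, n), abs=1e-8
            )

    def test_coverage_is_conservative(self):
        """Exact intervals cover the true p in at least 95% of simulations."""
        rng = np.random.default_rng(20180601)
        reps = 5000
        for n in (10, 53, 115):
            for p in (0.1, 0.7, 0.92):
                xs = rng.binomial(n, p, size=reps)
                lows = np.where(xs == 0, 0.0, stats.beta.ppf(0.025, xs, n - xs + 1))
                highs = np.where(xs == n, 1.0, stats.beta.ppf(0.975, xs + 1, n - xs))
                # sanity: the vectorized bounds agree with the implementation
                i = int(rng.integers(reps))
                assert clopper_pearson(int(xs[i]), n) == pytest.approx(
                    (lows[i], highs[i])
                )
                coverage = np.mean((lows <= p) & (p <= highs))
                assert coverage >= 0.95, (n, p, coverage)


class TestPredictiveValues:
    def test_perfect_test(self):
        assert predictive_values(1, 1, 0.5) == (1.0, 1.0)

    def test_boundary_priors(self):
        ppv, npv = predictive_values(0.9, 0.8, 1.0)
        assert ppv == 1.0 and npv == 0.0
        ppv0, npv0 = predictive_values(0.9, 1.0, 0.0)
        assert math.isnan(ppv0) and npv0 == 1.0  # undefined, never 0

    def test_formula_against_monte_carlo(self):
        """Bayes-rule PPV/NPV match frequencies in a simulated population."""
        rng = np.random.default_rng(42)
        se, sp, p, n = 0.92, 0.99, 0.27, 200_000
        truth = rng.random(n) < p
        called = np.where(truth, rng.random(n) < se, rng.random(n) < (1 - sp))
        ppv_mc = truth[called].mean()
        npv_mc = (~truth[~called]).mean()
        ppv, npv = predictive_values(se, sp, p)
        assert ppv == pytest.approx(0.97, abs=0.01)
        se_ppv = math.sqrt(ppv * (1 - ppv) / called.sum())
        se_npv = math.sqrt(npv * (1 - npv) / (~called).sum())
        assert abs(ppv - ppv_mc) <= 3 * se_ppv
        assert abs(npv - npv_mc) <= 3 * se_npv

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            predictive_values(1.2, 0.5, 0.5)

    @given(
        st.floats(0.01, 0.99),
        st.floats(0.01, 0.99),
        st.integers(min_value=2, max_value=50),
    )
    def test_ppv_monotone_npv_antitone(self, se, sp, k):
        grid = [i / k for i in range(k + 1)]
        curve = pv_curve(se, sp, grid)
        assert (curve["ppv"].diff().dropna() >= -1e-12).all()
        assert (curve["npv"].diff().dropna() <= 1e-12).all()

    def test_pv_curve_marks_and_shapes(self):
        curve = pv_curve(0.76, 0.94, [i / 100 for i in range(101)], marks=[0.31])
        assert len(curve) == 102
        assert curve.loc[curve["mark"], "p"].tolist() == [0.31]
        empty = pv_curve(0.9, 0.9, [])
        assert len(empty) == 0

    def test_pv_curve_rejects_unsorted(self):
        with pytest.raises(ValueError):
            pv_curve(0.9, 0.9, [0.5, 0.1])


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([[10, 0], [0, 7]]) == 1.0

    def test_chance_agreement(self):
        assert cohens_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_hand_computed(self):
        # po = 0.9, pe = 0.5 -> kappa = 0.8
        assert cohens_kappa([[45, 5], [5, 45]]) == pytest.approx(0.8)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            cohens_kappa([[1, 2, 3], [4, 5, 6]])

    def test_degenerate_marginals(self):
        # all mass in one diagonal cell: po = pe = 1, perfect agreement wins
        assert cohens_kappa([[10, 0], [0, 0]]) == 1.0
        # total disagreement with opposite marginals: pe = 0, kappa = po = 0
        assert cohens_kappa([[0, 10], [0, 0]]) == pytest.approx(0.0)

    def test_matches_sklearn_on_random_tables(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.integers(0, 4, size=200)
            b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 4, size=200))
            table = np.zeros((4, 4), int)
            np.add.at(table, (a, b), 1)
            assert cohens_kappa(table) == pytest.approx(cohen_kappa_score(a, b))


class TestModelResultsSurface:
    def _fitted(self, seed=5, n=300):
        from orthoclaims.claims_io import filter_eligible, window_events
        from orthoclaims.synth import SimulationConfig, generate_cohort

        ds = generate_cohort(SimulationConfig(n_cases=n, seed=seed))
        book = oc.default_codebook()
        cases, _ = filter_eligible(ds.cases)
        cases = [window_events(c, ds.claims) for c in cases]
        preds = oc.classify_cohort(cases, book)
        return oc.AlgorithmValidation(preds, ds.gold).fit()

    def test_estimates_consistent_with_counts(self):
        results = self._fitted()
        for level in Level:
            for combo in oc.ComboId:
                c = results.confusion(level, combo)
                est = results.estimate(level, combo, "sensitivity")
                if est is not None:
                    assert est.point == pytest.approx(c.tp / (c.tp + c.fn))
                est = results.estimate(level, combo, "specificity")
                if est is not None:
                    assert est.point == pytest.approx(c.tn / (c.tn + c.fp))

    def test_summary_and_frames(self):
        results = self._fitted()
        text = results.summary()
        assert "sensitivity" in text and "primary_indication" in text
        frame = results.to_frame()
        assert len(frame) == 16  # 2 levels x 4 combos x 2 metrics
        d = results.to_dict()
        assert set(d["primary_indication"]) == {"SPS", "HD", "KOA", "HOA"}

    def test_misclassification_causes(self):
        """Planted failure modes surface with the right mechanical tags."""
        book = oc.default_codebook()
        cases = [
            # demoted by an osteonecrosis code despite gold-primary HOA
            make_case("A", oc.Panel.HIP_KNEE, 70,
                      [("CPT", "27130"), ("ICD10", "M16.11"), ("ICD10", "M87.051")]),
            # dual-coded, age >= 50: engine says SPS, gold says HD
            make_case("B", oc.Panel.SPINE, 62,
                      [("CPT", "63047"), ("ICD10", "M48.062"), ("ICD10", "M51.26")]),
            # no procedure code in the window
            make_case("C", oc.Panel.HIP_KNEE, 70, [("ICD10", "M17.11")]),
        ]
        gold = [
            oc.GoldLabel("A", "hip_replacement", frozenset({"HOA"}), "HOA"),
            oc.GoldLabel("B", "spinal_surgery", frozenset({"SPS", "HD"}), "HD"),
            oc.GoldLabel("C", "knee_replacement", frozenset({"KOA"}), "KOA"),
        ]
        preds = oc.classify_cohort(cases, book)
        report = oc.misclassification_report(preds, gold)
        causes = dict(zip(zip(report["case_id"], report["combination"]), report["cause"]))
        assert causes[("A", "HOA")].startswith("exclusion_demotion:") and "M87*" in causes[("A", "HOA")]
        assert causes[("B", "HD")] == "tie_break_override"
        assert causes[("B", "SPS")] == "tie_break_override"  # the matching FP
        assert causes[("C", "KOA")] == "missing_cpt"
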