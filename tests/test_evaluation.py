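"""Diagnostic statistics: confusion matrix, metrics, ROC/AUC, comparisons, logistic fits."""
import numpy as np
import pytest

from sitiscale import (
    ConfusionMatrix,
    ConsistencyError,
    EvaluationError,
    LabeledCohort,
    SingleClassError,
    auc_trapezoid,
    compare_groups,
    confusion_at_threshold,
    diagnostic_metrics,
    evaluate_cohort,
    fit_logistic,
    fixture_table3_cohort,
    rank_auc,
    reproduce_table3,
    roc_curve,
)
from sitiscale.evaluation import round_half_away
from helpers import cohort_from_scores, make_record


class TestConfusion:
    def test_fixture_reproduces_published_matrix(self):
        cm = confusion_at_threshold(fixture_table3_cohort(), threshold=3)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (152, 237, 12, 470)
        assert cm.n_operative == 164 and cm.n_nonoperative == 707

    def test_threshold_zero_makes_everything_positive(self):
        cm = confusion_at_threshold(fixture_table3_cohort(), threshold=0)
        assert cm.fn == 0 and cm.tn == 0

    def test_all_operative_cohort(self):
        cohort = cohort_from_scores([(5, True), (0, True), (3, True)])
        cm = confusion_at_threshold(cohort, threshold=3)
        assert cm.fp == 0 and cm.tn == 0
        assert (cm.tp, cm.fn) == (2, 1)

    def test_empty_cohort_errors(self):
        with pytest.raises(EvaluationError):
            confusion_at_threshold(LabeledCohort())

    def test_cells_partition_assessable_records(self):
        cohort = fixture_table3_cohort(include_excluded=True)
        cm = confusion_at_threshold(cohort, threshold=3)
        assert cm.n == 871  # the 11 excluded records are left out


class TestMetrics:
    def test_ratio_identities_hold_exactly(self):
        cm = ConfusionMatrix(tp=152, fp=237, fn=12, tn=470)
        m = diagnostic_metrics(cm)
        assert m.sensitivity * (cm.tp + cm.fn) == pytest.approx(cm.tp)
        assert m.specificity * (cm.tn + cm.fp) == pytest.approx(cm.tn)
        assert m.ppv * (cm.tp + cm.fp) == pytest.approx(cm.tp)
        assert m.npv * (cm.tn + cm.fn) == pytest.approx(cm.tn)

    def test_zero_denominators_flagged_undefined(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=0, fp=3, fn=0, tn=5))
        assert m.sensitivity is None
        assert m.specificity is not None
        m = diagnostic_metrics(ConfusionMatrix(tp=2, fp=0, fn=1, tn=0))
        assert m.specificity is None  # no nonoperative records
        assert m.npv == 0.0  # defined: one negative call, and it is wrong
        m = diagnostic_metrics(ConfusionMatrix(tp=0, fp=0, fn=2, tn=3))
        assert m.ppv is None  # no positive calls

    @pytest.mark.parametrize(
        "x,expected",
        [(0.345, 0.35), (0.9751, 0.98), (0.926829, 0.93), (0.664781, 0.66), (-0.125, -0.13)],
    )
    def test_rounding_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestROC:
    def test_hand_computed_four_record_cohort(self):
        # nonoperative scores 1, 3; operative scores 2, 5
        cohort = cohort_from_scores([(1, False), (3, False), (2, True), (5, True)])
        pts = roc_curve(cohort)
        assert len(pts) == 13  # thresholds 12..0
        expected = (
            [(0.0, 0.0)] * 7  # t = 12..6
            + [(0.0, 0.5), (0.0, 0.5)]  # t = 5, 4
            + [(0.5, 0.5), (0.5, 1.0), (1.0, 1.0), (1.0, 1.0)]  # t = 3, 2, 1, 0
        )
        assert pts == expected
        # pairwise oracle: wins (2>1, 5>1, 5>3) out of 4 pairs
        assert auc_trapezoid(pts) == pytest.approx(0.75, abs=1e-12)

    def test_endpoints_and_monotonicity(self):
        pts = roc_curve(fixture_table3_cohort())
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        fpr, tpr = np.array(pts).T
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_perfect_separation(self):
        cohort = cohort_from_scores([(11, True)] * 3 + [(0, False)] * 4)
        pts = roc_curve(cohort)
        assert (0.0, 1.0) in pts
        assert auc_trapezoid(pts) == pytest.approx(1.0)

    def test_identical_distributions_give_half(self):
        cohort = cohort_from_scores(
            [(s, True) for s in (0, 2, 5)] + [(s, False) for s in (0, 2, 5)]
        )
        assert auc_trapezoid(roc_curve(cohort)) == pytest.approx(0.5, abs=1e-12)

    def test_single_class_cohort_errors(self):
        with pytest.raises(SingleClassError):
            roc_curve(cohort_from_scores([(3, True), (5, True)]))

    def test_label_swap_maps_auc_to_complement(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 16))
            scores = rng.integers(0, 12, n)
            labels = rng.random(n) < 0.5
            if labels.all() or (~labels).all():
                continue
            pairs = list(zip(scores.tolist(), labels.tolist()))
            auc = auc_trapezoid(roc_curve(cohort_from_scores(pairs)))
            swapped = auc_trapezoid(
                roc_curve(cohort_from_scores([(s, not l) for s, l in pairs]))
            )
            assert auc + swapped == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            scores = rng.integers(0, 12, n)
            labels = rng.random(n) < 0.5
            if labels.all() or (~labels).all():
                continue
            cohort = cohort_from_scores(list(zip(scores.tolist(), labels.tolist())))
            ours = auc_trapezoid(roc_curve(cohort))
            ref = roc_auc_score(labels.astype(int), scores)
            assert ours == pytest.approx(ref, abs=1e-12)
            assert rank_auc(scores, labels) == pytest.approx(ref, abs=1e-12)


class TestCompareGroups:
    def test_identical_numeric_groups(self):
        cohort = LabeledCohort(
            records=[
                make_record(f"a{i}", operative=True, age_years=a)
                for i, a in enumerate((30.0, 40.0, 50.0))
            ]
            + [
                make_record(f"b{i}", operative=False, age_years=a)
                for i, a in enumerate((30.0, 40.0, 50.0))
            ]
        )
        cmp = compare_groups(cohort, "age_years")
        assert cmp.kind == "t"
        assert cmp.statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)

    def test_identical_proportions_give_zero_chi2(self):
        records = []
        i = 0
        for op in (True, False):
            for temporal, count in ((True, 10), (False, 30)):
                for _ in range(count):
                    i += 1
                    records.append(make_record(f"r{i}", temporal=temporal, operative=op))
        cmp = compare_groups(LabeledCohort(records=records), "temporal_pathology")
        assert cmp.kind == "chi2"
        assert cmp.statistic == pytest.approx(0.0, abs=1e-12)

    def test_chi2_matches_hand_computed_fixture(self):
        # 2x2 table: operative 30/20, nonoperative 10/40 by temporal pathology.
        # Pearson without continuity correction: X^2 = 200/252 * ... = 16.666...
        records = []
        i = 0
        for op, yes, no in ((True, 30, 20), (False, 10, 40)):
            for temporal, count in ((True, yes), (False, no)):
                for _ in range(count):
                    i += 1
                    records.append(make_record(f"r{i}", temporal=temporal, operative=op))
        cmp = compare_groups(LabeledCohort(records=records), "temporal_pathology")
        # hand computation: margins 50/50 and 40/60, N=100 -> E = 20/30/20/30
        # X^2 = 100/20 + 100/30 + 100/20 + 100/30 = 16.6666...
        assert cmp.statistic == pytest.approx(50 / 3, abs=1e-9)

    def test_degenerate_table_flagged_without_p(self):
        cohort = LabeledCohort(
            records=[
                make_record("a", temporal=False, operative=True),
                make_record("b", temporal=False, operative=False),
            ]
        )
        cmp = compare_groups(cohort, "temporal_pathology")
        assert cmp.p_value is None and "degenerate" in cmp.note

    def test_siti_total_separates_groups_on_fixture(self):
        cmp = compare_groups(fixture_table3_cohort(), "siti_total")
        assert cmp.group_summary["operative_mean"] > cmp.group_summary["nonoperative_mean"]
        assert cmp.p_value < 1e-6


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        cohort = cohort_from_scores([(3, True)] * 40 + [(3, False)] * 60)
        fit = fit_logistic(cohort, components=())
        assert fit.converged
        est, se = fit.coefficients["intercept"]
        assert est == pytest.approx(np.log(40 / 60), abs=1e-8)
        assert se > 0

    def test_single_binary_component_is_log_odds_ratio(self):
        # temporal pathology: operative 30 yes / 20 no; nonoperative 10 yes / 40 no
        records = []
        i = 0
        for op, yes, no in ((True, 30, 20), (False, 10, 40)):
            for temporal, count in ((True, yes), (False, no)):
                for _ in range(count):
                    i += 1
                    records.append(make_record(f"r{i}", gcs=15, temporal=temporal, operative=op))
        fit = fit_logistic(LabeledCohort(records=records), components=("temporal",))
        est, _ = fit.coefficients["temporal"]
        assert est == pytest.approx(np.log((30 * 40) / (20 * 10)), abs=1e-8)
        assert 0.5 < fit.auc_of_fit <= 1.0

    def test_perfectly_separating_component_flagged(self):
        records = [make_record(f"a{i}", temporal=True, operative=True) for i in range(20)] + [
            make_record(f"b{i}", temporal=False, operative=False) for i in range(20)
        ]
        fit = fit_logistic(LabeledCohort(records=records), components=("temporal",))
        assert not fit.converged
        assert fit.coefficients is None
        assert "separation" in fit.note

    def test_unknown_component_rejected(self):
        with pytest.raises(Exception, match="unknown components"):
            fit_logistic(fixture_table3_cohort(), components=("skull_fracture",))

    def test_full_model_matches_statsmodels_on_synthetic_cohort(self):
        sm = pytest.importorskip("statsmodels.api")
        from sitiscale import CohortSpec, generate_cohort
        from sitiscale.evaluation import COMPONENTS
        import pandas as pd
        from sitiscale.scale import score_frame

        cohort = generate_cohort(CohortSpec(n_total=2000, seed=11))
        fit = fit_logistic(cohort, components=("gcs", "shift", "temporal", "edh"))
        assert fit.converged

        df = pd.DataFrame(
            {
                "gcs_total": [r.presentation.gcs_total for r in cohort],
                "pupils": [r.presentation.pupils for r in cohort],
                "midline_shift_mm": [r.presentation.ct.midline_shift_mm for r in cohort],
                "temporal_pathology": [r.presentation.ct.temporal_pathology for r in cohort],
                "edh_width_mm": [r.presentation.ct.edh_width_mm for r in cohort],
            }
        )
        pts = score_frame(df)
        X = pts[[COMPONENTS[c] for c in ("gcs", "shift", "temporal", "edh")]].to_numpy()
        y = np.array([r.operative for r in cohort], dtype=int)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        ours = np.array([fit.coefficients[k][0] for k in ("intercept", "gcs", "shift", "temporal", "edh")])
        np.testing.assert_allclose(ours, ref.params, atol=1e-6)


class TestReproduceTable3:
    def test_self_consistent_published_matrix(self):
        cm = ConfusionMatrix(tp=152, fp=237, fn=12, tn=470)
        frag = reproduce_table3(cm, nonoperative_total=707)
        assert frag["metrics_rounded"]["sensitivity"] == 0.93
        assert frag["metrics_rounded"]["specificity"] == 0.66
        assert frag["metrics_rounded"]["ppv"] == 0.39
        # raw NPV is 470/482 = 0.97510...; at two decimals this is 0.98
        assert frag["metrics_raw"]["npv"] == pytest.approx(470 / 482, abs=1e-15)
        assert frag["metrics_rounded"]["npv"] == 0.98

    def test_inconsistent_printed_cell_is_flagged(self):
        # a published fp of 327 cannot coexist with 470 true negatives in a
        # nonoperative column of 707: 327 + 470 != 707
        cm = ConfusionMatrix(tp=152, fp=327, fn=12, tn=470)
        with pytest.raises(ConsistencyError, match="707"):
            reproduce_table3(cm, nonoperative_total=707)

    def test_perfect_two_by_two(self):
        frag = reproduce_table3(ConfusionMatrix(tp=1, fp=0, fn=0, tn=1), nonoperative_total=1)
        assert all(v == 1.0 for v in frag["metrics_rounded"].values())


class TestEvaluateCohort:
    def test_report_on_fixture(self):
        report = evaluate_cohort(fixture_table3_cohort(include_excluded=True))
        assert report.cm.n == 871
        assert sum(report.exclusion_tally.values()) == 11
        assert report.metrics.rounded()["sensitivity"] == 0.93
        assert 0.0 < report.auc < 1.0
        d = report.to_dict()
        assert d["confusion"] == {"tp": 152, "fp": 237, "fn": 12, "tn": 470}
        assert d["schema_version"]
        text = report.to_text()
        assert "TP=152" in text and "0.93" in text

    def test_single_class_errors(self):
        with pytest.raises(SingleClassError):
            evaluate_cohort(cohort_from_scores([(3, True), (5, True)]))

    def test_auc_equals_rank_statistic(self):
        report = evaluate_cohort(fixture_table3_cohort())
        from sitiscale.evaluation import _scores_and_labels

        scores, labels, _, _ = _scores_and_labels(fixture_table3_cohort())
        assert report.auc == pytest.approx(rank_auc(scores, labels), abs=1e-12)
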