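import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgssl.evaluate import (ConfusionCounts, auroc, binarize,
                             confusion_metrics, curve_from_scores,
                             example_metrics, label_metrics_report,
                             paired_ttest_auprc, pr_curve_and_auprc,
                             select_operating_point)
from ecgssl.reference_tables import (AF_THRESHOLD_TABLE, ONLINE_CLASS_ROWS,
                                     af_curve)


class TestConfusionArithmetic:
    @pytest.mark.parametrize("row", AF_THRESHOLD_TABLE,
                             ids=[f"thr{r[0]}" for r in AF_THRESHOLD_TABLE])
    def test_af_threshold_rows_reproduce_published_metrics(self, row):
        """Every printed AF threshold row re-derives F1/Sen/Prec/Spe to 3
        decimals from its confusion counts."""
        thr, tp, tn, fp, fn, f1, sen, prec, spe = row
        m = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        assert round(m.f1, 3) == f1
        assert round(m.sensitivity, 3) == sen
        assert round(m.precision, 3) == prec
        assert round(m.specificity, 3) == spe

    @pytest.mark.parametrize("code", list(ONLINE_CLASS_ROWS))
    def test_online_class_rows_reproduce_published_metrics(self, code):
        tp, tn, fp, fn, sen, spe, f1 = ONLINE_CLASS_ROWS[code]
        m = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        assert round(m.sensitivity, 3) == sen
        assert round(m.specificity, 3) == spe
        assert round(m.f1, 3) == f1

    def test_degenerate_denominators_flagged_not_zeroed(self):
        m = confusion_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(m.sensitivity)
        assert np.isnan(m.precision)
        assert np.isnan(m.f1)
        assert m.specificity == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestBinarize:
    def test_score_equal_to_threshold_is_positive(self):
        pred, _ = binarize(np.array([[0.5]]), np.array([0.5]))
        assert pred[0, 0] == 1

    def test_extreme_thresholds(self):
        scores = np.random.default_rng(0).random((20, 3))
        labels = np.random.default_rng(1).integers(0, 2, (20, 3))
        _, counts = binarize(scores, np.zeros(3), labels)
        assert all(c.fn == 0 and c.tn == 0 for c in counts)
        _, counts = binarize(scores, np.full(3, 1.1), labels)
        assert all(c.tp == 0 and c.fp == 0 for c in counts)

    def test_threshold_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 3)), np.zeros(2))

    def test_lowering_threshold_never_decreases_tp_or_fp(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        rows = curve_from_scores(scores, labels,
                                 thresholds=np.linspace(0, 1, 21))
        tps = [c.tp for _, c in rows]
        fps = [c.fp for _, c in rows]
        assert tps == sorted(tps, reverse=True)
        assert fps == sorted(fps, reverse=True)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0])) == 1.0

    def test_worked_example(self):
        val = auroc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert val == pytest.approx(0.75)

    def test_single_class_flagged(self):
        assert np.isnan(auroc(np.array([0.1, 0.9]), np.array([1, 1])))

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0])),
                    min_size=2, max_size=8))
    def test_matches_exhaustive_pair_counting(self, pairs):
        """Oracle: Mann-Whitney pair counting with half credit for ties."""
        labels = np.array([p[0] for p in pairs])
        scores = np.array([p[1] for p in pairs])
        if labels.min() == labels.max():
            assert np.isnan(auroc(scores, labels))
            return
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auroc(scores, labels) == pytest.approx(
            wins / (len(pos) * len(neg)))

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        if labels.min() != labels.max():
            assert auroc(scores, labels) == pytest.approx(
                1.0 - auroc(scores, 1 - labels))


class TestAveragePrecision:
    def test_perfect_ranking(self):
        _, _, _, ap = pr_curve_and_auprc(np.array([0.9, 0.8, 0.2]),
                                         np.array([1, 1, 0]))
        assert ap == 1.0

    def test_hand_computed_step_sum(self):
        _, _, _, ap = pr_curve_and_auprc(np.array([0.1, 0.4, 0.35, 0.8]),
                                         np.array([0, 0, 1, 1]))
        assert ap == pytest.approx(0.8333, abs=1e-4)

    def test_identical_scores_give_prevalence(self):
        labels = np.array([1, 0, 0, 0, 1])
        _, _, _, ap = pr_curve_and_auprc(np.full(5, 0.7), labels)
        assert ap == pytest.approx(labels.mean())

    def test_no_positives_flagged(self):
        _, _, _, ap = pr_curve_and_auprc(np.array([0.1, 0.2]),
                                         np.array([0, 0]))
        assert np.isnan(ap)


class TestExampleMetrics:
    def test_perfect_prediction(self):
        y = np.array([[1, 0, 1], [0, 1, 0]])
        out = example_metrics(y, y)
        for key in ("sensitivity", "specificity", "f1", "accuracy"):
            assert out[key] == 1.0

    def test_direct_counting_example(self):
        out = example_metrics(np.array([[1, 1, 0, 0]]),
                              np.array([[1, 0, 1, 0]]))
        assert (out["mean_tp"], out["mean_tn"],
                out["mean_fp"], out["mean_fn"]) == (1, 1, 1, 1)
        for key in ("sensitivity", "specificity", "f1", "accuracy"):
            assert out[key] == pytest.approx(0.5)

    def test_undefined_records_skipped_not_zeroed(self):
        y_true = np.array([[0, 0], [1, 0]])   # record 0 has no positives
        y_pred = np.array([[0, 0], [1, 0]])
        out = example_metrics(y_true, y_pred)
        assert out["sensitivity"] == 1.0
        assert out["skipped"]["sensitivity"] == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            example_metrics(np.zeros((2, 3)), np.zeros((2, 4)))


class TestOperatingPoints:
    def test_break_even_selects_published_threshold(self):
        op = select_operating_point(af_curve(), "break_even")
        assert op.threshold == 0.528
        assert op.metrics.precision == pytest.approx(op.metrics.sensitivity,
                                                     abs=5e-4)

    def test_optimal_f1_selects_published_threshold(self):
        op = select_operating_point(af_curve(), "optimal_f1")
        assert op.threshold == 0.603
        assert round(op.metrics.f1, 3) == 0.847

    def test_sensitivity_floor_matches_fine_tuned_point(self):
        """Sen >= 0.9 with maximal precision lands on the 0.300 row."""
        op = select_operating_point(af_curve(), "sensitivity_floor",
                                    s_min=0.9)
        assert op.threshold == 0.300
        assert round(op.metrics.sensitivity, 3) == 0.900
        assert op.feasible

    def test_infeasible_floor_flagged_with_closest(self):
        op = select_operating_point(af_curve(), "sensitivity_floor",
                                    s_min=1.5)
        assert not op.feasible
        assert op.metrics.sensitivity == 1.0    # the 0.004 row

    def test_perfect_classifier_break_even_at_one(self):
        rows = curve_from_scores(np.array([0.9, 0.8, 0.1, 0.2]),
                                 np.array([1, 1, 0, 0]))
        op = select_operating_point(rows, "break_even")
        assert op.metrics.precision == 1.0
        assert op.metrics.sensitivity == 1.0

    def test_empty_curve_and_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            select_operating_point([], "break_even")
        with pytest.raises(ValueError):
            select_operating_point(af_curve(), "best_vibes")


class TestLabelReport:
    def test_macro_skips_undefined_classes(self):
        scores = np.array([[0.9, 0.4], [0.2, 0.6], [0.7, 0.5]])
        labels = np.array([[1, 0], [0, 0], [1, 0]])  # class 1 never positive
        report = label_metrics_report(scores, labels)
        assert np.isnan(report.auprc[1])
        assert report.skipped["auprc"] == 1
        assert not np.isnan(report.macro["auprc"])


class TestPairedTtest:
    def test_identical_vectors_degenerate(self):
        t, p, degen = paired_ttest_auprc(np.array([0.5, 0.6, 0.7]),
                                         np.array([0.5, 0.6, 0.7]))
        assert (t, p, degen) == (0.0, 1.0, True)

    def test_textbook_example(self):
        a = np.array([0.5, 0.6, 0.7])
        b = a - np.array([0.1, 0.2, 0.3])
        t, p, degen = paired_ttest_auprc(a, b)
        assert not degen
        assert t == pytest.approx(3.4641, abs=1e-3)
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(6), rng.random(6)
        t_ab, p_ab, _ = paired_ttest_auprc(a, b)
        t_ba, p_ba, _ = paired_ttest_auprc(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest_auprc(np.array([0.1]), np.array([0.2]))
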