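"""Evaluation metrics against independent oracles: brute-force counting for
the classification report, the pairwise-probability definition for AUC, and
onset subtraction for detection lag."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import breathnet as bn
from breathnet.channels import CLASSES


def counting_oracle(y_true, y_pred, classes=CLASSES):
    """Explicit per-class TP/FP/FN counting, independent of sklearn."""
    out = {}
    for c in classes:
        tp = sum(t == c and p == c for t, p in zip(y_true, y_pred))
        fp = sum(t != c and p == c for t, p in zip(y_true, y_pred))
        fn = sum(t == c and p != c for t, p in zip(y_true, y_pred))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = (prec, rec, f1, tp + fn)
    return out


def pairwise_auc_oracle(scores, truth):
    """P(random positive outscores random negative), ties counting 1/2."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestF1FromPR:
    @pytest.mark.parametrize(
        "p, r, expected",
        [
            (0.89, 0.85, 0.87),  # central apnea detection row
            (0.90, 0.95, 0.92),  # normal breathing row
            (0.52, 0.50, 0.51),  # obstructive apnea row
            (0.61, 0.54, 0.57),  # sighing row
        ],
    )
    def test_harmonic_mean_of_published_style_rows(self, p, r, expected):
        assert round(bn.f1_from_pr(p, r), 2) == expected

    @given(st.floats(0.001, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_equal_precision_recall_is_identity(self, x):
        assert bn.f1_from_pr(x, x) == pytest.approx(x)

    def test_double_zero_convention(self):
        assert bn.f1_from_pr(0.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bn.f1_from_pr(1.2, 0.5)


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = ["normal", "csa", "cough", "osa", "sigh", "yawn"] * 3
        report = bn.classification_report(y, y)
        assert all(m.f1 == 1.0 for m in report.per_class.values())
        assert np.array_equal(report.confusion, np.diag([3] * 6))

    def test_three_label_toy_hand_count(self):
        report = bn.classification_report(
            ["normal", "normal", "csa"], ["normal", "csa", "csa"]
        )
        assert report.per_class["csa"].precision == 0.5
        assert report.per_class["csa"].recall == 1.0
        assert report.per_class["normal"].support == 2

    def test_supports_sum_to_total(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(CLASSES, 500)
        y_pred = rng.choice(CLASSES, 500)
        report = bn.classification_report(y_true, y_pred)
        assert report.total_support == 500

    def test_matches_counting_oracle_on_random_sequences(self):
        """Exact agreement with brute-force counting on 1,000 random pairs."""
        rng = np.random.default_rng(1)
        for trial in range(1000):
            n = int(rng.integers(2, 40))
            y_true = rng.choice(CLASSES, n)
            y_pred = rng.choice(CLASSES, n)
            report = bn.classification_report(y_true, y_pred)
            oracle = counting_oracle(y_true, y_pred)
            for c in CLASSES:
                m = report.per_class[c]
                assert (m.precision, m.recall, m.f1, m.support) == pytest.approx(
                    oracle[c]
                ), f"trial {trial} class {c}"

    def test_confusion_rows_normalize_to_100(self):
        rng = np.random.default_rng(2)
        y_true = rng.choice(CLASSES, 300)
        y_pred = rng.choice(CLASSES, 300)
        report = bn.classification_report(y_true, y_pred)
        sums = report.confusion_percent.sum(axis=1)
        present = report.confusion.sum(axis=1) > 0
        assert np.allclose(sums[present], 100.0, atol=0.01)

    def test_support_equals_confusion_row_sums(self):
        rng = np.random.default_rng(3)
        y_true = rng.choice(CLASSES, 200)
        y_pred = rng.choice(CLASSES, 200)
        report = bn.classification_report(y_true, y_pred)
        for i, c in enumerate(CLASSES):
            assert report.per_class[c].support == report.confusion[i].sum()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bn.classification_report(["normal"], ["normal", "csa"])

    def test_absent_class_flagged(self):
        report = bn.classification_report(["normal"] * 5, ["normal"] * 5)
        assert "csa" in report.zero_division_classes


class TestROC:
    def test_perfect_separation(self):
        res = bn.roc_curve_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_worked_example(self):
        res = bn.roc_curve_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(4)
        scores = rng.random(60)
        truth = rng.integers(0, 2, 60)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        a = bn.roc_curve_auc(scores, truth).auc
        b = bn.roc_curve_auc(scores, 1 - truth).auc
        assert a + b == pytest.approx(1.0)

    def test_matches_pairwise_oracle(self):
        """Trapezoidal AUC equals the pairwise-probability definition to 1e-9,
        including under heavy score ties."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 80))
            scores = np.round(rng.random(n), 2)  # ties likely
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                truth[0] = 1 - truth[0]
            res = bn.roc_curve_auc(scores, truth)
            assert res.auc == pytest.approx(
                pairwise_auc_oracle(scores, truth), abs=1e-9
            )

    def test_tpr_fpr_monotone(self):
        rng = np.random.default_rng(6)
        scores, truth = rng.random(100), rng.integers(0, 2, 100)
        res = bn.roc_curve_auc(scores, truth)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            bn.roc_curve_auc([0.1, 0.9], [1, 1])


class TestDetectionLag:
    def test_one_second_late_detection(self):
        report = bn.detection_lag([("csa", 4, 14)], [("csa", 5, 15)])
        assert report.lags == [1]

    def test_identical_spans_zero_lag(self):
        report = bn.detection_lag([("cough", 3, 5)], [("cough", 3, 5)])
        assert report.lags == [0]

    def test_early_detection_negative_lag(self):
        report = bn.detection_lag([("csa", 4, 14)], [("csa", 2, 12)])
        assert report.lags == [-2]

    def test_largest_overlap_wins(self):
        report = bn.detection_lag(
            [("osa", 10, 20)], [("osa", 8, 12), ("osa", 13, 20)]
        )
        assert report.matched[0].predicted_span == (13, 20)
        assert report.lags == [3]

    def test_unmatched_and_class_mismatch(self):
        report = bn.detection_lag([("sigh", 2, 6)], [("yawn", 2, 6)])
        assert not report.matched
        assert report.unmatched == [("sigh", (2, 6))]

    def test_labels_to_spans_roundtrip(self):
        labels = ["normal"] * 4 + ["csa"] * 10 + ["normal"] * 16
        assert bn.labels_to_spans(labels) == [("csa", 4, 14)]
        labels[20:22] = ["cough", "cough"]
        assert bn.labels_to_spans(labels) == [("csa", 4, 14), ("cough", 20, 22)]
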