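"""Confusion counts, diagnostic ratios, ROC/AUC and the one-vs-rest report."""

import numpy as np
import pytest

from wavecnn import (
    ConfusionCounts,
    accuracy,
    confusion_counts,
    multiclass_report,
    roc_auc,
    sensitivity,
    specificity,
)
from wavecnn.exceptions import InputError, UndefinedMetricError


def pairwise_concordance(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(score+ > score-), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_all_positive_all_correct(self):
        c = confusion_counts(["P"] * 5, ["P"] * 5, "P")
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 0, 0)

    def test_enumerated_two_by_two(self):
        c = confusion_counts(["P", "P", "N", "N"], ["P", "N", "P", "N"], "P")
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_matches_per_item_tally_oracle(self, rng):
        labels = rng.choice(["P", "N"], size=200)
        preds = rng.choice(["P", "N"], size=200)
        c = confusion_counts(labels, preds, "P")
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for l, p in zip(labels, preds):
            key = ("t" if l == p else "f") + ("p" if p == "P" else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"],
        )
        assert c.total == 200

    def test_length_mismatch_and_unknown_class_rejected(self):
        with pytest.raises(InputError):
            confusion_counts([1, 0], [1], 1)
        with pytest.raises(InputError):
            confusion_counts([1, 0], [1, 0], 2)


class TestRatios:
    def test_reference_arithmetic(self):
        c = ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        assert accuracy(c) == pytest.approx(0.7)
        assert sensitivity(c) == pytest.approx(0.6)
        assert specificity(c) == pytest.approx(0.8)

    def test_perfect_classifier(self):
        c = ConfusionCounts(tp=10, fp=0, tn=10, fn=0)
        assert accuracy(c) == sensitivity(c) == specificity(c) == 1.0

    def test_zero_denominator_raises_undefined_metric(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(tp=0, fp=2, tn=3, fn=0))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(tp=2, fp=0, tn=0, fn=1))

    def test_accuracy_is_prevalence_weighted_combination(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            prevalence = (c.tp + c.fn) / c.total
            assert accuracy(c) == pytest.approx(
                prevalence * sensitivity(c) + (1 - prevalence) * specificity(c)
            )


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_trapezoid_equals_pairwise_concordance(self, rng):
        for _ in range(5):
            scores = np.round(rng.random(50), 2)  # rounding forces ties
            labels = rng.integers(0, 2, size=50)
            if labels.sum() in (0, 50):
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pairwise_concordance(scores, labels), abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        curve, _ = roc_auc(rng.random(30), rng.integers(0, 2, 30) | (np.arange(30) == 0))
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_invariance_under_strictly_increasing_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        _, auc = roc_auc(scores, labels)
        _, auc2 = roc_auc(np.exp(3 * scores) + 5, labels)
        assert auc2 == pytest.approx(auc, abs=1e-12)

    def test_label_swap_maps_auc_to_complement(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        _, auc = roc_auc(scores, labels)
        _, auc_swapped = roc_auc(-scores, 1 - labels)
        assert auc_swapped == pytest.approx(auc, abs=1e-12)

    def test_sensitivity_specificity_swap_under_label_swap(self, rng):
        labels = rng.choice([0, 1], size=60)
        preds = rng.choice([0, 1], size=60)
        labels[:2], preds[:2] = [0, 1], [1, 0]
        c = confusion_counts(labels, preds, 1)
        c_swapped = confusion_counts(1 - labels, 1 - preds, 1)
        assert sensitivity(c) == pytest.approx(specificity(c_swapped))
        assert specificity(c) == pytest.approx(sensitivity(c_swapped))

    def test_single_class_labels_rejected(self):
        with pytest.raises(InputError):
            roc_auc([0.1, 0.2], [1, 1])


class TestMulticlassReport:
    @staticmethod
    def _softmax_rows(rng, n, k):
        z = rng.random((n, k))
        return z / z.sum(axis=1, keepdims=True)

    def test_perfect_predictions(self):
        labels = np.array(["a", "b", "c", "d"] * 5)
        classes = ["a", "b", "c", "d"]
        scores = np.full((20, 4), 0.1)
        for i, l in enumerate(labels):
            scores[i, classes.index(l)] = 0.7
        report = multiclass_report(labels, scores, classes)
        assert report["overall_accuracy"] == 1.0
        for cls in classes:
            assert report["per_class"][cls]["sensitivity"] == 1.0

    def test_two_class_report_consistent_with_binary_operations(self, rng):
        labels = rng.choice(["neg", "pos"], size=60)
        labels[:2] = ["neg", "pos"]
        scores = self._softmax_rows(rng, 60, 2)
        report = multiclass_report(labels, scores, ["neg", "pos"])
        preds = np.where(scores[:, 1] > scores[:, 0], "pos", "neg")
        c = confusion_counts(labels, preds, "pos")
        assert report["per_class"]["pos"]["sensitivity"] == pytest.approx(sensitivity(c))
        assert report["per_class"]["pos"]["specificity"] == pytest.approx(specificity(c))
        _, auc = roc_auc(scores[:, 1], (labels == "pos").astype(int))
        assert report["per_class"]["pos"]["auc"] == pytest.approx(auc)

    def test_macro_values_equal_mean_of_per_class_oracle(self, rng):
        classes = list("abcd")
        labels = rng.choice(classes, size=100)
        for i, c in enumerate(classes):  # ensure every class occurs
            labels[i] = c
        scores = self._softmax_rows(rng, 100, 4)
        report = multiclass_report(labels, scores, classes)
        preds = np.asarray(classes, dtype=object)[scores.argmax(axis=1)]
        per = []
        for k, cls in enumerate(classes):
            c = confusion_counts(labels, preds, cls)
            _, auc = roc_auc(scores[:, k], (labels == cls).astype(int))
            per.append((sensitivity(c), specificity(c), auc))
        per = np.array(per)
        assert report["macro"]["sensitivity"] == pytest.approx(per[:, 0].mean())
        assert report["macro"]["specificity"] == pytest.approx(per[:, 1].mean())
        assert report["macro"]["auc"] == pytest.approx(per[:, 2].mean())

    def test_rows_not_summing_to_one_rejected(self):
        with pytest.raises(InputError):
            multiclass_report(["a", "b"], np.array([[0.9, 0.3], [0.5, 0.5]]), ["a", "b"])

    def test_absent_class_flagged_undefined(self, rng):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        scores = self._softmax_rows(rng, 10, 3)
        report = multiclass_report(labels, scores, ["a", "b", "c"])
        undefined_names = {cls for cls, _ in report["undefined"]}
        assert "c" in undefined_names
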