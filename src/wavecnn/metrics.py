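"""Classification metrics: confusion counts, accuracy, sensitivity,
specificity, ROC/AUC, and a one-vs-rest multi-class report.

Definitions follow the standard diagnostic-test convention:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)        (true positive rate)
    specificity = TN / (TN + FP)        (true negative rate)

AUC is the trapezoidal area under the ROC curve, which equals the
Mann-Whitney concordance probability P(score+ > score-) with ties counted
one half.  Multi-class scores are reduced one-vs-rest; macro averages are
unweighted means over classes and micro averages pool the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import InputError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: object = 1

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray


def confusion_counts(labels, predictions, positive_class) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise InputError(
            f"labels and predictions differ in length: {labels.shape} vs {predictions.shape}"
        )
    classes = set(labels.tolist()) | set(predictions.tolist())
    if positive_class not in classes:
        raise InputError(f"positive class {positive_class!r} not among observed classes")
    pos_label = labels == positive_class
    pos_pred = predictions == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_label & pos_pred)),
        fp=int(np.sum(~pos_label & pos_pred)),
        tn=int(np.sum(~pos_label & ~pos_pred)),
        fn=int(np.sum(pos_label & ~pos_pred)),
        positive_class=positive_class,
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def roc_auc(scores, labels) -> tuple[RocCurve, float]:
    """ROC curve over all distinct score thresholds and its trapezoidal area.

    ``labels`` is binary (1 = positive); tied scores are grouped at a single
    threshold, so tied positive-negative pairs contribute 1/2 to the area.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise InputError("scores and labels differ in length")
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or n_pos == len(labels):
        raise InputError("ROC requires at least one positive and one negative label")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr), auc


def multiclass_report(labels, scores_matrix, class_set, tol: float = 1e-6) -> dict:
    """One-vs-rest evaluation of softmax scores.

    Predictions are argmax rows of ``scores_matrix`` (whose rows must sum to
    one).  Per-class sensitivity/specificity/accuracy/AUC are computed
    one-vs-rest; classes with undefined values are flagged and excluded from
    the macro means.  Micro averages pool the one-vs-rest counts.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores_matrix, dtype=float)
    class_set = list(class_set)
    if scores.ndim != 2 or scores.shape[1] != len(class_set):
        raise InputError("scores matrix must be (n_samples, n_classes)")
    if scores.shape[0] != len(labels):
        raise InputError("labels and scores differ in length")
    row_sums = scores.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > tol):
        raise InputError("score rows must sum to 1 (softmax outputs)")

    preds = np.asarray(class_set, dtype=object)[scores.argmax(axis=1)]
    overall_accuracy = float(np.mean(preds == labels))

    per_class: dict = {}
    undefined: list = []
    pooled = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for k, cls in enumerate(class_set):
        c = confusion_counts(labels, preds, cls) if cls in set(labels) or cls in set(
            preds
        ) else ConfusionCounts(0, 0, len(labels), 0, cls)
        entry: dict = {"counts": c}
        for name, fn in (("accuracy", accuracy), ("sensitivity", sensitivity),
                         ("specificity", specificity)):
            try:
                entry[name] = fn(c)
            except UndefinedMetricError:
                entry[name] = float("nan")
                undefined.append((cls, name))
        try:
            _, entry["auc"] = roc_auc(scores[:, k], (labels == cls).astype(int))
        except InputError:
            entry["auc"] = float("nan")
            undefined.append((cls, "auc"))
        for key in pooled:
            pooled[key] += getattr(c, key)
        per_class[cls] = entry

    def _macro(name):
        vals = [per_class[cls][name] for cls in class_set]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    micro_counts = ConfusionCounts(
        pooled["tp"], pooled["fp"], pooled["tn"], pooled["fn"], positive_class="pooled"
    )
    report = {
        "reduction": "one-vs-rest (macro = unweighted class mean; micro = pooled counts)",
        "overall_accuracy": overall_accuracy,
        "per_class": per_class,
        "macro": {name: _macro(name) for name in ("accuracy", "sensitivity",
                                                  "specificity", "auc")},
        "micro": {
            "accuracy": accuracy(micro_counts),
            "sensitivity": sensitivity(micro_counts),
            "specificity": specificity(micro_counts),
        },
        "undefined": undefined,
    }
    return report
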