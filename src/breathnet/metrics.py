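"""Evaluation: per-class precision/recall/F1, confusion matrices, ROC/AUC,
and onset-lag analysis for per-second event detection.

Precision, recall and support are computed with scikit-learn; F1 is the
harmonic mean 2PR/(P+R) with the convention that it is 0 when both
precision and recall are 0 (zero-denominator classes are flagged in the
report). Confusion matrices are reported both as raw counts and as
row-normalized percentages (per true class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs
from sklearn.metrics import roc_curve as _sk_roc_curve

from .channels import CLASSES


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0 and recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    """Per-class metrics with macro/weighted averages and confusion matrices."""

    per_class: dict[str, ClassMetrics]
    confusion: np.ndarray
    confusion_percent: np.ndarray
    classes: tuple[str, ...] = CLASSES
    zero_division_classes: list[str] = field(default_factory=list)

    @property
    def macro_f1(self) -> float:
        return float(np.mean([m.f1 for m in self.per_class.values()]))

    @property
    def macro_precision(self) -> float:
        return float(np.mean([m.precision for m in self.per_class.values()]))

    @property
    def macro_recall(self) -> float:
        return float(np.mean([m.recall for m in self.per_class.values()]))

    @property
    def weighted_f1(self) -> float:
        supports = np.array([m.support for m in self.per_class.values()], dtype=float)
        f1s = np.array([m.f1 for m in self.per_class.values()])
        return float(np.average(f1s, weights=supports)) if supports.sum() else 0.0

    @property
    def total_support(self) -> int:
        return int(sum(m.support for m in self.per_class.values()))

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "support": m.support,
                }
                for c, m in self.per_class.items()
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted_f1": self.weighted_f1,
            "confusion": self.confusion.tolist(),
            "confusion_percent": self.confusion_percent.tolist(),
            "classes": list(self.classes),
            "zero_division_classes": self.zero_division_classes,
        }

    def to_table(self) -> str:
        """Aligned text table: Precision Recall F1-Score Support per class."""
        lines = [f"{'':10s} {'Precision':>9s} {'Recall':>7s} {'F1-Score':>8s} {'Support':>8s}"]
        for c, m in self.per_class.items():
            lines.append(
                f"{c:10s} {m.precision:9.2f} {m.recall:7.2f} {m.f1:8.2f} {m.support:8d}"
            )
        lines.append(
            f"{'macro avg':10s} {self.macro_precision:9.2f} "
            f"{self.macro_recall:7.2f} {self.macro_f1:8.2f} {self.total_support:8d}"
        )
        return "\n".join(lines)


def classification_report(
    y_true, y_pred, classes: tuple[str, ...] = CLASSES
) -> EvalReport:
    """Per-class precision/recall/F1/support plus confusion matrices.

    ``y_true`` and ``y_pred`` are equal-length label sequences drawn from
    ``classes``. F1 uses :func:`f1_from_pr`; support is the count of true
    labels per class. Row-normalized confusion percentages sum to 100 for
    every class with non-zero support.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        bad = set(np.unique(arr)) - set(classes)
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    prec, rec, _, supp = _sk_prfs(
        y_true, y_pred, labels=list(classes), zero_division=0
    )
    conf = _sk_confusion(y_true, y_pred, labels=list(classes))
    row_sums = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * conf / row_sums, 0.0)
    per_class = {}
    flagged = []
    for i, c in enumerate(classes):
        p, r = float(prec[i]), float(rec[i])
        if (p == 0 and r == 0) or conf[:, i].sum() == 0 or supp[i] == 0:
            if supp[i] == 0 or conf[:, i].sum() == 0:
                flagged.append(c)
        per_class[c] = ClassMetrics(p, r, f1_from_pr(p, r), int(supp[i]))
    return EvalReport(
        per_class=per_class,
        confusion=conf,
        confusion_percent=pct,
        classes=tuple(classes),
        zero_division_classes=flagged,
    )


@dataclass
class ROCResult:
    """ROC curve points and the area under the curve."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve_auc(scores, truth) -> ROCResult:
    """ROC curve and AUC for binary scores.

    The AUC equals the probability that a random positive outscores a random
    negative, counting ties as 1/2. Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if set(np.unique(truth)) - {0, 1}:
        raise ValueError("truth must be binary (0/1)")
    if truth.min() == truth.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(truth, scores)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


@dataclass
class MatchedEvent:
    label: str
    true_span: tuple[int, int]
    predicted_span: tuple[int, int]
    lag_s: int


@dataclass
class LagReport:
    """Signed onset lags (predicted onset - true onset) for matched events."""

    matched: list[MatchedEvent]
    unmatched: list[tuple[str, tuple[int, int]]]

    @property
    def lags(self) -> list[int]:
        return [m.lag_s for m in self.matched]

    @property
    def mean_lag(self) -> float:
        return float(np.mean(self.lags)) if self.matched else float("nan")


def labels_to_spans(labels) -> list[tuple[str, int, int]]:
    """Collapse a per-second label sequence into non-normal runs
    ``(label, start, end)`` with half-open second intervals."""
    spans = []
    start = None
    current = None
    for i, lab in enumerate(list(labels) + ["normal"]):
        if lab != current:
            if current is not None and current != "normal":
                spans.append((current, start, i))
            current, start = lab, i
    return spans


def detection_lag(true_spans, predicted_spans) -> LagReport:
    """Match true events to same-class predicted runs; report onset lags.

    Each true span ``(label, start, end)`` is matched to the predicted run
    of the same class with the largest temporal overlap (earliest onset
    breaks ties); unmatched true events are reported separately. The lag is
    ``predicted start - true start`` in seconds (positive = late detection).
    """
    matched, unmatched = [], []
    for label, ts, te in true_spans:
        best, best_overlap = None, 0
        for plabel, ps, pe in predicted_spans:
            if plabel != label:
                continue
            overlap = max(0, min(te, pe) - max(ts, ps))
            if overlap > best_overlap or (
                overlap == best_overlap and overlap > 0 and best and ps < best[0]
            ):
                best, best_overlap = (ps, pe), overlap
        if best is None or best_overlap == 0:
            unmatched.append((label, (ts, te)))
        else:
            matched.append(
                MatchedEvent(label, (ts, te), best, lag_s=best[0] - ts)
            )
    return LagReport(matched=matched, unmatched=unmatched)
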