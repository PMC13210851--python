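"""Classification metric suite with interval estimates.

Per class (one-vs-rest): precision, recall, specificity, F1. Aggregates:
accuracy, support-weighted F1, minimum recall, unweighted mean F1, class
balance (max recall minus min recall, in percentage points), average false
positive rate (mean over classes of 1 - specificity), and class leakage —
the largest off-diagonal row-normalised confusion entries, the classifier's
worst mistakes. Interval estimators: Wilson score for a proportion,
percentile bootstrap over resampled (true, predicted) pairs, and Student-t
intervals over cross-validation folds. Undefined ratios (zero denominator)
are reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .conditions import CLASS_ORDER

__all__ = [
    "ConfusionMatrix",
    "ClasswiseMetrics",
    "AggregateReport",
    "IntervalEstimate",
    "FoldSummary",
    "EvaluationReport",
    "confusion_matrix",
    "classwise_metrics",
    "aggregate_metrics",
    "class_leakage",
    "wilson_interval",
    "bootstrap_interval",
    "summarise_folds",
    "t_interval",
    "evaluate_predictions",
]


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class, canonical class order."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def confusion_matrix(true_labels, predicted_labels,
                     classes: tuple[str, ...] = CLASS_ORDER) -> ConfusionMatrix:
    """Count (true, predicted) pairs; labels may be names or class indices."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    k = len(classes)
    idx = {name: i for i, name in enumerate(classes)}

    def to_idx(arr):
        if arr.dtype.kind in "iu":
            if len(arr) and (arr.min() < 0 or arr.max() >= k):
                raise ValueError("class index out of range")
            return arr.astype(np.int64)
        out = np.empty(len(arr), dtype=np.int64)
        for j, v in enumerate(arr):
            if str(v) not in idx:
                raise ValueError(f"unknown label {v!r}")
            out[j] = idx[str(v)]
        return out

    t = to_idx(true_labels)
    p = to_idx(predicted_labels)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, classes)


@dataclass
class ClasswiseMetrics:
    """One-vs-rest precision/recall/specificity/F1 per class (fractions)."""

    classes: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(num, dtype=float))
    np.divide(num, den, out=out, where=np.asarray(den) > 0)
    return out


def classwise_metrics(cm: ConfusionMatrix) -> ClasswiseMetrics:
    c = cm.counts.astype(float)
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = c.sum() - tp - fn - fp
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return ClasswiseMetrics(cm.classes, precision, recall, specificity, f1)


@dataclass
class AggregateReport:
    """Aggregate indicators over the six classes (fractions unless noted)."""

    accuracy: float
    weighted_f1: float
    min_recall: float
    avg_f1: float
    class_balance_pp: float  # 100 * (max recall - min recall)
    avg_fpr: float  # mean over classes of 1 - specificity
    leakage: list[tuple[str, str, int]] = field(default_factory=list)


def class_leakage(cm: ConfusionMatrix, top_k: int = 3
                  ) -> list[tuple[str, str, int]]:
    """Worst off-diagonal row-normalised confusions, as whole-number
    percentages, sorted descending; ties break by (row, column) class
    order."""
    c = cm.counts.astype(float)
    rows = c.sum(axis=1, keepdims=True)
    frac = np.divide(c, rows, out=np.zeros_like(c), where=rows > 0)
    entries = []
    k = len(cm.classes)
    for i in range(k):
        for j in range(k):
            if i == j or frac[i, j] <= 0:
                continue
            entries.append((cm.classes[i], cm.classes[j],
                            int(round(100 * frac[i, j])), i, j))
    entries.sort(key=lambda e: (-e[2], e[3], e[4]))
    return [(a, b, pct) for a, b, pct, _, _ in entries[:top_k] if pct > 0]


def aggregate_metrics(cm: ConfusionMatrix, top_k_leakage: int = 3
                      ) -> AggregateReport:
    cw = classwise_metrics(cm)
    total = cm.total
    accuracy = float(np.trace(cm.counts)) / total if total else 0.0
    support = cm.supports.astype(float)
    weighted_f1 = (float((cw.f1 * support).sum() / support.sum())
                   if support.sum() else 0.0)
    return AggregateReport(
        accuracy=accuracy,
        weighted_f1=weighted_f1,
        min_recall=float(cw.recall.min()),
        avg_f1=float(cw.f1.mean()),
        class_balance_pp=100.0 * float(cw.recall.max() - cw.recall.min()),
        avg_fpr=float((1.0 - cw.specificity).mean()),
        leakage=class_leakage(cm, top_k_leakage),
    )


@dataclass
class IntervalEstimate:
    """A point estimate with CI offsets in percentage points."""

    point: float  # fraction
    lower_offset_pp: float  # <= 0
    upper_offset_pp: float  # >= 0
    method: str
    confidence: float = 0.95
    n: int | None = None

    @property
    def lower(self) -> float:
        return self.point + self.lower_offset_pp / 100.0

    @property
    def upper(self) -> float:
        return self.point + self.upper_offset_pp / 100.0


def wilson_interval(p_hat: float, n: int, confidence: float = 0.95
                    ) -> IntervalEstimate:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must be in [0, 1]")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    denom = 1 + z * z / n
    centre = (p_hat + z * z / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z * z / (4 * n * n)) / denom
    lo, hi = max(centre - half, 0.0), min(centre + half, 1.0)
    return IntervalEstimate(point=p_hat, lower_offset_pp=100 * (lo - p_hat),
                            upper_offset_pp=100 * (hi - p_hat),
                            method="wilson", confidence=confidence, n=n)


def bootstrap_interval(true_labels, predicted_labels, metric_fn,
                       B: int = 1000, seed: int = 0,
                       confidence: float = 0.95) -> IntervalEstimate:
    """Percentile bootstrap CI of ``metric_fn(true, pred)`` over B resamples
    of the (true, predicted) pairs with replacement."""
    if B < 2:
        raise ValueError("B must be >= 2")
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) == 0:
        raise ValueError("empty label vectors")
    rng = np.random.default_rng(seed)
    point = float(metric_fn(t, p))
    n = len(t)
    vals = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        vals[b] = metric_fn(t[idx], p[idx])
    alpha = 1 - confidence
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return IntervalEstimate(point=point,
                            lower_offset_pp=100 * (min(lo, point) - point),
                            upper_offset_pp=100 * (max(hi, point) - point),
                            method="bootstrap", confidence=confidence, n=B)


def t_interval(values, confidence: float = 0.95
               ) -> tuple[float, float, float]:
    """(mean, sample std, t-based CI half-width) of fold-wise values."""
    v = np.asarray(values, dtype=float)
    k = len(v)
    if k < 2:
        raise ValueError("need at least 2 folds")
    mean = float(v.mean())
    std = float(v.std(ddof=1))
    half = float(stats.t.ppf(0.5 + confidence / 2.0, k - 1) * std / np.sqrt(k))
    return mean, std, half


@dataclass
class FoldSummary:
    """Per-metric mean, sample std and Student-t CI half-width over folds."""

    metrics: dict[str, dict]
    k: int
    confidence: float = 0.95


def summarise_folds(per_fold_metrics: dict[str, list[float]],
                    confidence: float = 0.95) -> FoldSummary:
    k = None
    out = {}
    for name, vals in per_fold_metrics.items():
        if k is None:
            k = len(vals)
        elif len(vals) != k:
            raise ValueError("all metrics must have the same fold count")
        mean, std, half = t_interval(vals, confidence)
        out[name] = {"values": list(map(float, vals)), "mean": mean,
                     "std": std, "ci_half_width": half}
    if k is None or k < 2:
        raise ValueError("need at least 2 folds")
    return FoldSummary(metrics=out, k=k, confidence=confidence)


@dataclass
class EvaluationReport:
    """Everything computed for one model on one test set."""

    cm: ConfusionMatrix
    classwise: ClasswiseMetrics
    aggregates: AggregateReport
    accuracy_ci: IntervalEstimate | None = None
    bootstrap_cis: dict[str, IntervalEstimate] = field(default_factory=dict)

    def to_dict(self) -> dict:
        agg = self.aggregates
        d = {
            "confusion_matrix": self.cm.counts.tolist(),
            "classes": list(self.cm.classes),
            "accuracy": agg.accuracy,
            "weighted_f1": agg.weighted_f1,
            "min_recall": agg.min_recall,
            "avg_f1": agg.avg_f1,
            "class_balance_pp": agg.class_balance_pp,
            "avg_fpr": agg.avg_fpr,
            "leakage": [list(e) for e in agg.leakage],
            "classwise": {
                "precision": self.classwise.precision.tolist(),
                "recall": self.classwise.recall.tolist(),
                "specificity": self.classwise.specificity.tolist(),
                "f1": self.classwise.f1.tolist(),
            },
        }
        if self.accuracy_ci is not None:
            d["accuracy_ci_pp"] = [self.accuracy_ci.lower_offset_pp,
                                   self.accuracy_ci.upper_offset_pp]
        for name, ci in self.bootstrap_cis.items():
            d[f"{name}_ci_pp"] = [ci.lower_offset_pp, ci.upper_offset_pp]
        return d


def evaluate_predictions(true_labels, predicted_labels, seed: int = 0,
                         bootstrap_B: int = 1000,
                         classes: tuple[str, ...] = CLASS_ORDER
                         ) -> EvaluationReport:
    """Full report: confusion matrix, class-wise and aggregate metrics,
    Wilson CI on accuracy and bootstrap CIs on the aggregate indicators."""
    cm = confusion_matrix(true_labels, predicted_labels, classes)
    cw = classwise_metrics(cm)
    agg = aggregate_metrics(cm)
    acc_ci = wilson_interval(agg.accuracy, cm.total) if cm.total else None

    def metric(fn):
        return lambda t, p: fn(aggregate_metrics(confusion_matrix(t, p, classes)))

    boot = {}
    if cm.total:
        for name, fn in {
            "min_recall": lambda a: a.min_recall,
            "avg_f1": lambda a: a.avg_f1,
            "class_balance_pp": lambda a: a.class_balance_pp / 100.0,
            "avg_fpr": lambda a: a.avg_fpr,
            "weighted_f1": lambda a: a.weighted_f1,
        }.items():
            boot[name] = bootstrap_interval(true_labels, predicted_labels,
                                            metric(fn), B=bootstrap_B, seed=seed)
    return EvaluationReport(cm=cm, classwise=cw, aggregates=agg,
                            accuracy_ci=acc_ci, bootstrap_cis=boot)
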