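"""Stratified cross-validation, holdout evaluation, and the metric suite.

Reported metrics are accuracy, class-weighted precision/recall/F-measure,
the ROC curve with trapezoidal AUC, and the precision-recall curve with
step-integral AUPRC.  Cross-validated curves and the pooled confusion matrix
are built from pooled out-of-fold scores (deterministic for a given seed)
rather than per-fold averaging; the AUC computed this way equals the
Mann-Whitney U statistic normalized by n_pos * n_neg.

The learning-curve experiment subsamples a fixed number of training
instances per class, repeats cross-validation over seeds, and reports the
mean and standard deviation of accuracy per size — the classifier-improves-
with-more-miRNAs phenomenon as a measurable property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

from .exceptions import DomainError
from .model import TrainedClassifier, fit_baseline
from .seqio import NEGATIVE_LABEL, POSITIVE_LABEL, FeatureTable

__all__ = [
    "EvaluationReport",
    "stratified_folds",
    "cross_validate",
    "roc_curve",
    "pr_curve",
    "learning_curve",
    "evaluate_holdout",
]


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Metrics, curves and confusion matrices from one evaluation run.

    The pooled confusion matrix is laid out rows = true class, columns =
    predicted class, in (negative, positive) order.
    """

    classifier: str
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    auc: float | None
    auprc: float | None
    confusion: np.ndarray
    roc_points: tuple[np.ndarray, np.ndarray] | None
    pr_points: tuple[np.ndarray, np.ndarray] | None
    n_instances: int
    k: int | None = None
    seed: int | None = None
    fold_assignment: np.ndarray | None = None
    per_fold: list[dict] = field(default_factory=list)
    scores: np.ndarray | None = None
    true_labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "n_instances": self.n_instances,
            "k": self.k,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "auprc": self.auprc,
            "confusion": self.confusion.astype(int).tolist(),
            "per_fold": self.per_fold,
            "roc_points": None
            if self.roc_points is None
            else [self.roc_points[0].tolist(), self.roc_points[1].tolist()],
            "pr_points": None
            if self.pr_points is None
            else [self.pr_points[0].tolist(), self.pr_points[1].tolist()],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# folds and curves
# ---------------------------------------------------------------------------


def stratified_folds(labels: Sequence, k: int, seed: int = 1) -> np.ndarray:
    """Assign each instance to one of ``k`` stratified folds.

    Per-class counts across folds differ by at most one; the assignment is a
    deterministic function of ``seed``.  A class with fewer than ``k``
    members is a stratification error.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise DomainError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = [str(c) for c, n in zip(classes, counts) if n < k]
    if small:
        raise DomainError(
            f"class(es) {small} have fewer than k={k} members; cannot stratify"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    y = np.asarray([1 if l == POSITIVE_LABEL else 0 for l in labels])
    if y.min() == y.max():
        raise DomainError("both classes must be present")
    return y


def roc_curve(scores: Sequence[float], labels: Sequence):
    """ROC points over all distinct score thresholds plus trapezoidal AUC.

    Tied scores are grouped at a single threshold, so all-equal scores give
    the chance diagonal (AUC 0.5).  The AUC equals the Mann-Whitney U
    statistic normalized by ``n_pos * n_neg``.
    """
    y = _check_two_classes(np.asarray(labels))
    fpr, tpr, _ = skmetrics.roc_curve(y, scores, drop_intermediate=False)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def pr_curve(scores: Sequence[float], labels: Sequence):
    """Precision-recall points plus step-integral AUPRC.

    No linear interpolation between points (which would overestimate the
    area); all-equal scores give AUPRC equal to the positive prevalence.
    """
    y = _check_two_classes(np.asarray(labels))
    precision, recall, _ = skmetrics.precision_recall_curve(y, scores)
    auprc = float(skmetrics.average_precision_score(y, scores))
    return recall, precision, auprc


def _confusion(true: np.ndarray, pred: np.ndarray) -> np.ndarray:
    return skmetrics.confusion_matrix(
        true, pred, labels=[NEGATIVE_LABEL, POSITIVE_LABEL]
    )


def _weighted_prf(true: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    p, r, f, _ = skmetrics.precision_recall_fscore_support(
        true, pred, average="weighted", zero_division=0
    )
    return float(p), float(r), float(f)


def _report_from_scores(
    classifier: str,
    true: np.ndarray,
    scores: np.ndarray,
    n: int,
    **extra,
) -> EvaluationReport:
    pred = np.asarray(
        [POSITIVE_LABEL if s >= 0.5 else NEGATIVE_LABEL for s in scores], dtype=object
    )
    conf = _confusion(true, pred)
    accuracy = float(np.trace(conf) / conf.sum())
    precision, recall, f_measure = _weighted_prf(true, pred)
    if len(set(true)) == 2:
        fpr, tpr, auc = roc_curve(scores, true)
        rec, prec, auprc = pr_curve(scores, true)
        roc_points, pr_points = (fpr, tpr), (rec, prec)
    else:
        auc = auprc = None
        roc_points = pr_points = None
    return EvaluationReport(
        classifier=classifier,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        auc=auc,
        auprc=auprc,
        confusion=conf,
        roc_points=roc_points,
        pr_points=pr_points,
        n_instances=n,
        scores=scores,
        true_labels=true,
        **extra,
    )


# ---------------------------------------------------------------------------
# cross-validation, holdout, learning curve
# ---------------------------------------------------------------------------


def _subtable(table: FeatureTable, idx: np.ndarray, labeled: bool = True) -> FeatureTable:
    return FeatureTable(
        ids=[table.ids[i] for i in idx],
        attributes=list(table.attributes),
        values=table.values[idx],
        labels=table.labels[idx] if labeled and table.labels is not None else None,
    )


def cross_validate(
    table: FeatureTable,
    classifier: str = "bayesnet",
    k: int = 5,
    seed: int = 1,
    alpha: float = 0.5,
    **classifier_kwargs,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of one classifier kind.

    Each fold's model is trained on the other k-1 folds and scores its
    held-out instances; the out-of-fold scores are pooled for the confusion
    matrix, metrics and curves.
    """
    labels = table.y
    assignment = stratified_folds(labels, k, seed)
    scores = np.zeros(table.n_instances)
    per_fold: list[dict] = []
    for fold in range(k):
        test_idx = np.nonzero(assignment == fold)[0]
        train_idx = np.nonzero(assignment != fold)[0]
        model = fit_baseline(
            classifier, _subtable(table, train_idx), seed=seed, alpha=alpha,
            **classifier_kwargs,
        )
        result = model.predict(_subtable(table, test_idx, labeled=False))
        scores[test_idx] = result.prob_positive
        fold_conf = _confusion(labels[test_idx], np.asarray(result.labels, dtype=object))
        per_fold.append(
            {
                "fold": fold,
                "n_test": int(len(test_idx)),
                "confusion": fold_conf.astype(int).tolist(),
                "accuracy": float(np.trace(fold_conf) / fold_conf.sum()),
            }
        )
    return _report_from_scores(
        classifier,
        labels,
        scores,
        table.n_instances,
        k=k,
        seed=seed,
        fold_assignment=assignment,
        per_fold=per_fold,
    )


def evaluate_holdout(model: TrainedClassifier, table: FeatureTable) -> EvaluationReport:
    """Score a labeled holdout table in a single pass (no folding)."""
    if table.n_instances == 0:
        raise DomainError("holdout table is empty")
    labels = table.y
    result = model.predict(_subtable(table, np.arange(table.n_instances), labeled=False))
    return _report_from_scores(
        model.kind, labels, result.prob_positive, table.n_instances
    )


@dataclass
class LearningCurvePoint:
    size: int
    mean_accuracy: float
    sd_accuracy: float
    accuracies: list[float]


def learning_curve(
    table: FeatureTable,
    classifier: str = "bayesnet",
    sizes: Sequence[int] = (20, 40),
    seeds: Sequence[int] = tuple(range(10)),
    k: int = 5,
    alpha: float = 0.5,
) -> dict[int, LearningCurvePoint]:
    """Cross-validated accuracy as a function of per-class training count.

    For each size and seed, ``size`` instances per class are subsampled
    (without replacement, preserving original row order so the full size
    reproduces plain cross-validation exactly) and evaluated with
    ``cross_validate``.
    """
    labels = table.y
    classes, counts = np.unique(labels, return_counts=True)
    max_size = int(counts.min())
    for size in sizes:
        if size > max_size:
            raise DomainError(
                f"requested {size} per class but smallest class has {max_size}"
            )
        if size < k:
            raise DomainError(f"size {size} is smaller than k={k}")
    out: dict[int, LearningCurvePoint] = {}
    for size in sizes:
        accs: list[float] = []
        for seed in seeds:
            rng = np.random.default_rng(seed)
            keep: list[int] = []
            for c in classes:
                idx = np.nonzero(labels == c)[0]
                keep.extend(rng.choice(idx, size=size, replace=False))
            keep_idx = np.asarray(sorted(keep))
            report = cross_validate(
                _subtable(table, keep_idx), classifier, k=k, seed=seed, alpha=alpha
            )
            accs.append(report.accuracy)
        arr = np.asarray(accs)
        out[size] = LearningCurvePoint(
            size=size,
            mean_accuracy=float(arr.mean()),
            sd_accuracy=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            accuracies=accs,
        )
    return out
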