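"""Confusion-matrix metrics, AUC, and stratified k-fold cross-validation.

Percentage metrics follow the usual definitions on TP/TN/FP/FN counts;
any metric whose denominator is zero is reported as ``None`` (undefined)
rather than coerced to 0 or 100, and undefined entries are excluded from
cross-fold means with a logged count.  AUC is the rank-based probability
that a random positive outscores a random negative, ties counted half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from firehawk.augmentation import LabeledVectorSet, smote_balance
from firehawk.classifier import ClassifierSpec, Hyperparameters, train_classifier

logger = logging.getLogger(__name__)


class InputError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Percentage metrics in [0, 100] (or None when undefined) plus AUC in [0, 1]."""

    precision: float | None = None
    specificity: float | None = None
    sensitivity: float | None = None
    accuracy: float | None = None
    f1: float | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
        }


def confusion_counts(truth: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for binary vectors (positive class = 1)."""
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.shape != predictions.shape or truth.ndim != 1 or truth.size < 1:
        raise InputError("truth and predictions must be equal-length non-empty vectors")
    for arr in (truth, predictions):
        if not np.isin(arr, (0, 1)).all():
            raise InputError("labels must be binary (0/1)")
    truth = truth.astype(int)
    predictions = predictions.astype(int)
    return ConfusionCounts(
        tp=int(np.sum((truth == 1) & (predictions == 1))),
        tn=int(np.sum((truth == 0) & (predictions == 0))),
        fp=int(np.sum((truth == 0) & (predictions == 1))),
        fn=int(np.sum((truth == 1) & (predictions == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Percentage precision/specificity/sensitivity/accuracy/F1 from counts."""
    if counts.total == 0:
        raise InputError("cannot compute metrics from empty counts")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    specificity = _ratio(counts.tn, counts.tn + counts.fp)
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn)
    accuracy = _ratio(counts.tp + counts.tn, counts.total)
    if precision is not None and sensitivity is not None and precision + sensitivity > 0:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    else:
        f1 = None
    return MetricsReport(
        precision=precision,
        specificity=specificity,
        sensitivity=sensitivity,
        accuracy=accuracy,
        f1=f1,
    )


def auc_score(truth: np.ndarray, scores: np.ndarray) -> float | None:
    """Rank-based AUC with half-tie handling; None when only one class present."""
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise InputError("truth and scores must have equal length")
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    rank_sum_pos = float(np.sum(ranks[truth == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def stratified_kfold(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """k disjoint, exhaustive folds with per-class counts differing by <= 1.

    Each class's shuffled members are dealt in near-equal chunks; the
    oversized chunks go to the currently smallest folds, keeping total fold
    sizes as even as possible.
    """
    labels = np.asarray(labels).astype(int)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < k):
        raise ConfigurationError("every class must have at least k members")
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in classes:
        rows = rng.permutation(np.flatnonzero(labels == cls))
        base, extra = divmod(rows.size, k)
        loads = np.array([len(f) for f in folds])
        # stable order: smallest folds first get the +1 chunks
        recipients = np.argsort(loads, kind="stable")
        sizes = np.full(k, base)
        sizes[recipients[:extra]] += 1
        start = 0
        for fold_id in range(k):
            folds[fold_id].extend(rows[start : start + sizes[fold_id]].tolist())
            start += sizes[fold_id]
    return [np.sort(np.array(f, dtype=int)) for f in folds]


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """What happens inside each training fold."""

    hyper: Hyperparameters
    spec: ClassifierSpec
    smote_k: int | None = 5  # None disables balancing


@dataclass
class CrossValResult:
    folds: list[MetricsReport]
    mean: MetricsReport
    undefined_counts: dict[str, int] = field(default_factory=dict)


def _mean_report(folds: list[MetricsReport]) -> tuple[MetricsReport, dict[str, int]]:
    mean = MetricsReport()
    undefined: dict[str, int] = {}
    for name in ("precision", "specificity", "sensitivity", "accuracy", "f1", "auc"):
        vals = [getattr(r, name) for r in folds]
        defined = [v for v in vals if v is not None]
        undefined[name] = len(vals) - len(defined)
        if undefined[name]:
            logger.info("metric %s undefined in %d fold(s); excluded from mean", name, undefined[name])
        setattr(mean, name, float(np.mean(defined)) if defined else None)
    return mean, undefined


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> CrossValResult:
    """Stratified k-fold evaluation with all fitting inside training folds.

    SMOTE (when enabled) sees only the training-fold rows, so no test
    sample ever takes part in neighbor search, interpolation, or training.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    folds = stratified_kfold(y, k, rng)
    reports: list[MetricsReport] = []
    all_idx = np.arange(y.size)
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        if np.intersect1d(train_idx, test_idx).size:
            raise AssertionError("leakage guard: train/test folds overlap")
        train_set = LabeledVectorSet(X[train_idx], y[train_idx])
        if config.smote_k is not None and np.unique(y[train_idx]).size == 2:
            train_set = smote_balance(train_set, config.smote_k, rng)
            if train_set.synthetic[: train_idx.size].any():
                raise AssertionError("leakage guard: a real training row was flagged synthetic")
        model = train_classifier(config.spec, train_set.vectors, train_set.labels, config.hyper, rng)
        preds = model.predict(X[test_idx])
        report = classification_metrics(confusion_counts(y[test_idx], preds))
        scores = model.predict_proba(X[test_idx])[:, 1]
        report.auc = auc_score(y[test_idx], scores)
        reports.append(report)
    mean, undefined = _mean_report(reports)
    return CrossValResult(folds=reports, mean=mean, undefined_counts=undefined)
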