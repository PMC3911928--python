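"""Confusion matrices, correctness, Youden's J-index, CV and paired t-tests.

Youden's J-index is the unweighted mean of per-class recalls (balanced
accuracy): on unbalanced data it weighs rare labels as heavily as common
ones, so a constant classifier scores 0.5 regardless of the prevalence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .bayes import Dataset, NaiveBayesClassifier

__all__ = [
    "ConfusionMatrix",
    "EvaluationResult",
    "ComparisonReport",
    "confusion_matrix",
    "correctness",
    "j_index",
    "j_score",
    "cross_validate",
    "paired_t_test",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i][j] = number of cases with real label i classified as j."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("one row/column per label required")
        if (counts < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred, labels: Sequence | None = None) -> ConfusionMatrix:
    """Count real-vs-predicted labels; label order defaults to sorted unique."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty inputs")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred), key=repr)
    else:
        labels = list(labels)
        known = set(labels)
        for v in y_true + y_pred:
            if v not in known:
                raise ValueError(f"unknown label {v!r}")
    counts = _sk_confusion(y_true, y_pred, labels=labels)
    return ConfusionMatrix(tuple(labels), counts)


def correctness(cm: ConfusionMatrix) -> float:
    """Plain accuracy: trace of the matrix over its total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def j_index(cm: ConfusionMatrix) -> float:
    """Youden's J: average per-class recall over classes present in y_true.

    Classes absent from the true labels are excluded from the average with a
    warning (so tiny evaluation folds remain scorable).
    """
    row_totals = cm.counts.sum(axis=1)
    present = row_totals > 0
    if not present.any():
        raise ValueError("empty confusion matrix")
    if not present.all():
        warnings.warn(
            f"classes {[cm.labels[i] for i in np.nonzero(~present)[0]]} absent "
            "from the true labels; excluded from the J-index average"
        )
    recalls = np.diag(cm.counts)[present] / row_totals[present]
    return float(recalls.mean())


def j_score(model: NaiveBayesClassifier, data: Dataset) -> float:
    """Convenience: J-index of a classifier's predictions on a dataset."""
    preds = model.predict_frame(data.X)
    return j_index(confusion_matrix(data.y, preds, labels=model.class_labels))


@dataclass
class EvaluationResult:
    """Per-repeat-per-fold J-index values plus their mean and spread."""

    values: np.ndarray
    n_folds: int
    n_repeats: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_folds * self.n_repeats:
            raise ValueError("expected one value per repeat per fold")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def n_evaluations(self) -> int:
        return len(self.values)


def cross_validate(
    builder: Callable[[Dataset], NaiveBayesClassifier],
    data: Dataset,
    k: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> EvaluationResult:
    """Repeated stratified k-fold CV of a classifier-building procedure.

    Per repeat, a fresh seeded stratified split; ``builder`` is fit on the
    union of k-1 folds and the held-out fold's J-index is recorded.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = data.y.value_counts()
    if (counts < k).any():
        raise ValueError(
            f"class too small to stratify into {k} folds: {counts.to_dict()}"
        )
    values = []
    for r in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for train_idx, test_idx in splitter.split(data.X, data.y):
            model = builder(data.subset_rows(train_idx))
            values.append(j_score(model, data.subset_rows(test_idx)))
    return EvaluationResult(np.asarray(values), n_folds=k, n_repeats=repeats)


def paired_t_test(a: Sequence[float], b: Sequence[float], tail: str = "two") -> float:
    """Paired t-test on fold-matched scores; one-tail tests mean(a) > mean(b).

    Zero variance of the differences is degenerate for the t statistic:
    p = 1 when the means agree, p -> 0 otherwise (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    diffs = a - b
    if np.allclose(diffs, diffs[0]):
        if np.isclose(diffs[0], 0.0):
            return 1.0
        log.info("zero-variance paired differences with nonzero mean; p -> 0")
        if tail == "two" or diffs[0] > 0:
            return 0.0
        return 1.0
    alternative = "greater" if tail == "one" else "two-sided"
    return float(stats.ttest_rel(a, b, alternative=alternative).pvalue)


@dataclass
class ComparisonReport:
    """Per-method CV results plus hypothesis-test p-values against a reference."""

    method_names: list[str]
    results: dict[str, EvaluationResult]
    p_values: dict[str, float] = field(default_factory=dict)
    tails: dict[str, str] = field(default_factory=dict)
    reference: str = ""

    def __post_init__(self) -> None:
        for name, p in self.p_values.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value for {name!r} outside [0, 1]")

    def to_frame(self):
        import pandas as pd

        rows = {}
        for name in self.method_names:
            res = self.results[name]
            rows[name] = {
                "mean_j": res.mean,
                "sd_j": res.sd,
                "n": res.n_evaluations,
                "p_value": self.p_values.get(name, float("nan")),
                "tail": self.tails.get(name, ""),
            }
        return pd.DataFrame(rows).T

    def to_markdown(self) -> str:
        frame = self.to_frame()
        lines = [f"Comparison against reference method `{self.reference}`", ""]
        header = "| method | mean J | sd | n | p-value | tail |"
        lines += [header, "|" + "---|" * 6]
        for name, row in frame.iterrows():
            p = "" if np.isnan(row["p_value"]) else f"{row['p_value']:.4g}"
            lines.append(
                f"| {name} | {row['mean_j']:.4f} | {row['sd_j']:.4f} | "
                f"{int(row['n'])} | {p} | {row['tail']} |"
            )
        return "\n".join(lines)
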