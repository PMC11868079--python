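"""Leave-one-out cross-validation, confusion counts and metrics.

LOOCV is deterministic: each pattern is held out once, the model is
refit on the remainder, and the held-out prediction recorded.  All
data-dependent preprocessing (missing-value imputation by column mean)
is recomputed on each training fold and applied to the held-out pattern,
so no information leaks from the test pattern into learning.

Hyperparameter handling per fold:

* fixed :class:`Hyperparameters` — same (att, bound) every fold;
* :class:`~spheremml.tune.DEConfig` with ``mode="per_fold"`` — DE retuned
  inside every fold (the honest, slower protocol);
* ``mode="global"`` — DE tuned once on the full data, then fixed for all
  folds.  This reuses the held-out patterns during tuning and is
  therefore optimistic; it is provided as a fast approximation only.

Class 1 is the positive class for the confusion layout and F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import learn
from .classify import classify
from .dataset import DegenerateTrainingError, LabeledDataset, UndefinedMetricError
from .tune import DEConfig, evolve


@dataclass(frozen=True)
class Hyperparameters:
    """Fixed (att, bound) pair, bypassing self-adjustment."""

    att: int
    bound: int
    att_is_percent: bool = False


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion counts with class 1 as positive."""

    tp: int
    fn: int
    tn: int
    fp: int


@dataclass(frozen=True)
class FoldRecord:
    fold_index: int
    true_class: int
    predicted_class: int
    att: int
    bound: int
    c1_in: bool


@dataclass
class EvaluationReport:
    confusion: ConfusionCounts
    balanced_accuracy: float
    f1: float
    per_fold: list[FoldRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.confusion.tp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
            },
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "per_fold": [
                {
                    "fold_index": r.fold_index,
                    "true_class": r.true_class,
                    "predicted_class": r.predicted_class,
                    "att": r.att,
                    "bound": r.bound,
                    "c1_in": r.c1_in,
                }
                for r in self.per_fold
            ],
        }


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity; robust to class imbalance."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError("balanced accuracy needs both classes present")
    return (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp)) / 2.0


def f1_score(c: ConfusionCounts) -> float:
    """F1 of the positive class (class 1); 0 when tp = 0 with fp+fn > 0."""
    if c.tp + c.fp + c.fn == 0:
        raise UndefinedMetricError("F1 undefined with no positives anywhere")
    if c.tp == 0:
        return 0.0
    return 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)


def _impute_fold(
    train_values: np.ndarray, test_pattern: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Column-mean imputation computed on the training fold only."""
    if not (np.isnan(train_values).any() or np.isnan(test_pattern).any()):
        return train_values, test_pattern
    col_means = np.nanmean(
        np.where(np.isnan(train_values), np.nan, train_values), axis=0
    )
    col_means = np.where(np.isnan(col_means), 0.0, col_means)  # all-missing column
    train_filled = np.where(np.isnan(train_values), col_means, train_values)
    test_filled = np.where(np.isnan(test_pattern), col_means, test_pattern)
    return train_filled, test_filled


def loocv(
    data: LabeledDataset,
    tuning: Hyperparameters | DEConfig,
    mode: str = "per_fold",
) -> EvaluationReport:
    """Deterministic leave-one-out evaluation.

    Requires at least 3 patterns and at least 2 per class, so every
    training fold retains both classes.
    """
    if mode not in ("per_fold", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    n = data.n_patterns
    if n < 3 or data.n1 < 2 or data.n2 < 2:
        raise DegenerateTrainingError(
            f"LOOCV needs >= 3 patterns and >= 2 per class (n1={data.n1}, n2={data.n2})"
        )

    fixed: Hyperparameters | None = tuning if isinstance(tuning, Hyperparameters) else None
    if isinstance(tuning, DEConfig) and mode == "global":
        full = data
        if full.has_missing:
            values, _ = _impute_fold(full.values, full.values[0])
            full = LabeledDataset(values, full.labels, full.attribute_names,
                                  dict(full.class_names))
        best, _, _ = evolve(full, tuning)
        fixed = Hyperparameters(best.att, best.bound, tuning.att_is_percent)

    records: list[FoldRecord] = []
    tp = fn = tn = fp = 0
    for i in range(n):
        rows = np.arange(n) != i
        train_values, test_pattern = _impute_fold(data.values[rows], data.values[i])
        train = LabeledDataset(
            train_values, data.labels[rows], data.attribute_names, dict(data.class_names)
        )
        if train.n1 == 0 or train.n2 == 0:
            raise DegenerateTrainingError(f"training fold {i} lost a class")
        if fixed is not None:
            model = learn(train, fixed.att, fixed.bound, att_is_percent=fixed.att_is_percent)
        else:
            # per-fold retuning; derive a distinct deterministic seed per fold
            fold_config = replace(tuning, seed=int((tuning.seed * 100003 + i) % 2**31))
            _, model, _ = evolve(train, fold_config)
        predicted, _ = classify(model, test_pattern)
        true = int(data.labels[i])
        records.append(
            FoldRecord(i, true, predicted, model.att, model.bound, model.c1_in)
        )
        if true == 1:
            tp += predicted == 1
            fn += predicted == 2
        else:
            tn += predicted == 2
            fp += predicted == 1

    confusion = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
    return EvaluationReport(
        confusion=confusion,
        balanced_accuracy=balanced_accuracy(confusion),
        f1=f1_score(confusion),
        per_fold=records,
    )
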