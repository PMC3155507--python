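"""Evaluation measures and the 7-fold sample-level cross-validation protocol.

Q_total, Q_predicted and Q_observed are percentages over the pooled
confusion matrix; MCC is the Matthews correlation coefficient; AUC is the
area under the ROC curve.  Cross-validation folds are drawn at the sample
(window) level: equal-size random folds, each sample predicted exactly
once, with both layers of the model refit on the training folds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .features import SampleSet
from .model import (
    TrainingConfig,
    predict,
    predict_single_svm,
    train_single_svm,
    train_two_layer,
)


@dataclass
class ConfusionMatrix:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[bool], y_pred: Sequence[bool]
    ) -> "ConfusionMatrix":
        t = np.asarray(y_true, dtype=bool)
        p = np.asarray(y_pred, dtype=bool)
        if t.shape != p.shape:
            raise ValueError("label arrays must have the same length")
        return cls(
            TP=int((t & p).sum()),
            FP=int((~t & p).sum()),
            TN=int((~t & ~p).sum()),
            FN=int((t & ~p).sum()),
        )

    def to_dict(self) -> dict:
        return {"TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN}


def q_total(cm: ConfusionMatrix) -> float:
    """Overall accuracy: 100 * (TP + TN) / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (cm.TP + cm.TN) / cm.total


def q_predicted(cm: ConfusionMatrix) -> float:
    """Precision: 100 * TP / (TP + FP); 0 with a warning when nothing was predicted positive."""
    if cm.TP + cm.FP == 0:
        warnings.warn("no positive predictions; Q_predicted defined as 0")
        return 0.0
    return 100.0 * cm.TP / (cm.TP + cm.FP)


def q_observed(cm: ConfusionMatrix) -> float:
    """Sensitivity: 100 * TP / (TP + FN)."""
    if cm.TP + cm.FN == 0:
        raise ValueError("no observed positives; evaluation set invalid")
    return 100.0 * cm.TP / (cm.TP + cm.FN)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; any zero denominator factor yields 0."""
    denom = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    if denom == 0:
        return 0.0
    return (cm.TP * cm.TN - cm.FP * cm.FN) / math.sqrt(denom)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve (midrank tie handling)."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC/AUC requires both classes")
    return float(roc_auc_score(y.astype(int), np.asarray(scores, dtype=float)))


@dataclass
class CVResult:
    """Pooled cross-validation outcome: fold map, per-sample scores, measures."""

    fold_assignments: np.ndarray
    scores: np.ndarray
    predicted: np.ndarray
    y_true: np.ndarray
    cm: ConfusionMatrix
    q_total: float
    q_predicted: float
    q_observed: float
    mcc: float
    auc: float

    def to_dict(self, include_roc: bool = True) -> dict:
        out = {
            "n_samples": int(len(self.y_true)),
            "k_folds": int(self.fold_assignments.max() + 1),
            "confusion_matrix": self.cm.to_dict(),
            "Q_total": self.q_total,
            "Q_predicted": self.q_predicted,
            "Q_observed": self.q_observed,
            "MCC": self.mcc,
            "AUC": self.auc,
            "fold_sizes": np.bincount(self.fold_assignments).tolist(),
        }
        if include_roc:
            fpr, tpr, thr = roc_curve(self.y_true.astype(int), self.scores)
            out["roc_curve"] = {
                "fpr": fpr.tolist(),
                "tpr": tpr.tolist(),
                "thresholds": [float(t) for t in thr],
            }
        return out


def make_folds(n_samples: int, k: int, seed: int) -> np.ndarray:
    """Random equal-size sample-level folds; the remainder spreads one per fold.

    Returns an array mapping sample index -> fold index.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n_samples < k:
        raise ValueError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    assignments = np.empty(n_samples, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = fold
    return assignments


def cross_validate(
    samples: SampleSet,
    k: int = 7,
    config: TrainingConfig | None = None,
    seed: int = 0,
    model_kind: str = "two_layer",
    threshold: float = 0.5,
) -> CVResult:
    """k-fold sample-level cross-validation of the stacked (or single) model.

    For each fold, both layers are refit on the remaining k-1 folds — the
    held-out samples are never involved in the construction of either layer
    — and each sample is predicted exactly once.  Per-fold training seeds
    are derived from the master seed for reproducibility.
    """
    if model_kind not in ("two_layer", "single"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    if config is None:
        config = TrainingConfig(seed=seed)
    n = len(samples)
    folds = make_folds(n, k, seed)
    scores = np.zeros(n)
    predicted = np.zeros(n, dtype=bool)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=k)
    for fold in range(k):
        test = folds == fold
        train = ~test
        y_train = samples.y[train]
        if y_train.all() or not y_train.any():
            raise ValueError(f"training split for fold {fold} contains a single class")
        fold_config = TrainingConfig(**{**config.to_dict(), "seed": int(fold_seeds[fold])})
        train_set = SampleSet(
            X=samples.X[train],
            y=y_train,
            chain_ids=[c for c, m in zip(samples.chain_ids, train) if m],
            starts=samples.starts[train],
            scheme=samples.scheme,
        )
        test_set = SampleSet(
            X=samples.X[test],
            y=samples.y[test],
            chain_ids=[c for c, m in zip(samples.chain_ids, test) if m],
            starts=samples.starts[test],
            scheme=samples.scheme,
        )
        if model_kind == "two_layer":
            model = train_two_layer(train_set, fold_config)
            labels, s = predict(model, test_set, threshold=threshold)
        else:
            clf = train_single_svm(train_set, fold_config)
            labels, s = predict_single_svm(clf, test_set, threshold=threshold)
        scores[test] = s
        predicted[test] = labels
    cm = ConfusionMatrix.from_predictions(samples.y, predicted)
    return CVResult(
        fold_assignments=folds,
        scores=scores,
        predicted=predicted,
        y_true=samples.y.copy(),
        cm=cm,
        q_total=q_total(cm),
        q_predicted=q_predicted(cm),
        q_observed=q_observed(cm),
        mcc=mcc(cm),
        auc=roc_auc(scores, samples.y),
    )
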