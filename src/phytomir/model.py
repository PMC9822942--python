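"""The random-forest interaction scorer.

A deliberately small forest of 13 trees scores each candidate duplex with a
confidence equal to the fraction of trees voting "target". Thirteen trees
give a coarse but well-calibrated-enough confidence grid (multiples of 1/13)
and train in milliseconds at desk scale; only the tree count is pinned, all
other hyperparameters follow standard random-forest defaults (unlimited
depth, sqrt(11) features per split, bootstrap resampling).

An operating threshold on the confidence is chosen by stratified k-fold
cross-validation: the smallest threshold whose cross-validated mean precision
reaches a target (1.0 by default), reported with mean +/- sd of recall and
precision across folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES, LabeledExample, examples_to_matrix
from .io_formats import DataError

DEFAULT_N_TREES = 13
DEFAULT_CV_FOLDS = 5

_FORMAT_VERSION = 1


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    n_trees: int = DEFAULT_N_TREES
    feature_order: tuple = tuple(FEATURE_NAMES)
    seed: int = 0

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": _FORMAT_VERSION,
                "forest": self.forest,
                "n_trees": self.n_trees,
                "feature_order": tuple(self.feature_order),
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise DataError(f"unsupported model file version in {path}")
        return cls(
            forest=payload["forest"],
            n_trees=payload["n_trees"],
            feature_order=payload["feature_order"],
            seed=payload["seed"],
        )


def _as_matrix(examples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(examples, tuple) and len(examples) == 2:
        X, y = examples
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    return examples_to_matrix(examples)


def train(
    examples: Sequence[LabeledExample] | tuple,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> TrainedModel:
    """Fit the forest on labelled examples (or an ``(X, y)`` pair)."""
    X, y = _as_matrix(examples)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise DataError(
            f"feature matrix must have {len(FEATURE_NAMES)} columns, got {X.shape}"
        )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("degenerate training set: a single class present")
    if counts.min() < 2:
        raise DataError("degenerate training set: fewer than 2 examples in a class")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedModel(forest=forest, n_trees=n_trees, seed=seed)


def predict(model: TrainedModel, examples) -> np.ndarray:
    """Confidence per example: the fraction of trees voting the positive class."""
    if isinstance(examples, np.ndarray):
        X = np.asarray(examples, dtype=float)
    else:
        X, _ = _as_matrix(examples)
    if X.ndim != 2 or X.shape[1] != len(model.feature_order):
        raise DataError(
            f"expected {len(model.feature_order)} features, got shape {X.shape}"
        )
    pos_index = int(np.nonzero(model.forest.classes_ == 1)[0][0])
    votes = np.zeros(X.shape[0])
    for tree in model.forest.estimators_:
        votes += tree.predict(X) == model.forest.classes_[pos_index]
    return votes / len(model.forest.estimators_)


@dataclass
class ThresholdReport:
    threshold: float
    cv_recall_mean: float
    cv_recall_sd: float
    cv_precision_mean: float
    cv_precision_sd: float
    k: int
    precision_target: float
    target_reached: bool


def _fold_indices(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    n = len(labels)
    if k == n:  # leave-one-out: singleton folds in index order
        return [np.array([i]) for i in range(n)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(n), labels)]


def _fold_metrics(scores, labels, t):
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else 1.0  # vacuous: no positive calls
    recall = tp / (tp + fn) if tp + fn > 0 else None  # fold without positives
    return precision, recall


def select_threshold_cv(
    examples: Optional[Sequence[LabeledExample]] = None,
    *,
    scores: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
    k: int = DEFAULT_CV_FOLDS,
    precision_target: float = 1.0,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> ThresholdReport:
    """Choose an operating confidence threshold by k-fold cross-validation.

    Either ``examples`` (a forest is trained per fold and scores out-of-fold
    examples) or precomputed ``scores``/``labels`` (folds only partition the
    evaluation) must be given. Candidate thresholds are the distinct observed
    out-of-fold scores; the smallest one whose mean precision across folds
    reaches ``precision_target`` is selected. Folds with no positive calls
    count precision 1.0 (vacuously precise); folds without positive examples
    are excluded from the recall mean. If no threshold reaches the target the
    maximum observed score is returned with ``target_reached=False``.
    """
    if examples is not None:
        X, y = examples_to_matrix(examples)
    elif scores is not None and labels is not None:
        y = np.asarray(labels, dtype=int)
        scores = np.asarray(scores, dtype=float)
    else:
        raise DataError("select_threshold_cv needs examples or scores+labels")
    if len(np.unique(y)) < 2:
        raise DataError("degenerate input: a single class present")

    folds = _fold_indices(y, k, seed)
    fold_scores: list[np.ndarray] = []
    fold_labels: list[np.ndarray] = []
    for test_idx in folds:
        if examples is not None:
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            m = train((X[train_idx], y[train_idx]), n_trees=n_trees, seed=seed)
            fold_scores.append(predict(m, X[test_idx]))
        else:
            fold_scores.append(scores[test_idx])
        fold_labels.append(y[test_idx])

    grid = np.unique(np.concatenate(fold_scores))
    chosen = None
    for t in grid:
        precisions = []
        for fs, fl in zip(fold_scores, fold_labels):
            p, _ = _fold_metrics(fs, fl, t)
            precisions.append(p)
        if np.mean(precisions) >= precision_target:
            chosen = float(t)
            break
    target_reached = chosen is not None
    if chosen is None:
        chosen = float(grid[-1])

    precisions, recalls = [], []
    for fs, fl in zip(fold_scores, fold_labels):
        p, r = _fold_metrics(fs, fl, chosen)
        precisions.append(p)
        if r is not None:
            recalls.append(r)
    return ThresholdReport(
        threshold=chosen,
        cv_recall_mean=float(np.mean(recalls)) if recalls else float("nan"),
        cv_recall_sd=float(np.std(recalls)) if recalls else float("nan"),
        cv_precision_mean=float(np.mean(precisions)),
        cv_precision_sd=float(np.std(precisions)),
        k=k,
        precision_target=precision_target,
        target_reached=target_reached,
    )
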