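"""Classifier evaluation: precision-recall curves, threshold metrics, densities.

PR-AUC is computed by step-wise (rectangular) integration over recall —
precision is not interpolated between operating points, which would be
optimistic in PR space. Examples are called positive when their score is
greater than or equal to the threshold (closed rule), so a threshold of 0
degenerates cleanly to recall 1. Tied scores flip together when the
threshold crosses them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import DataError


@dataclass(frozen=True)
class MetricsAtThreshold:
    threshold: float
    recall: float
    precision: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class PRCurve:
    #: (recall, precision) operating points, ascending recall
    points: tuple
    auc: float

    @property
    def recalls(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def precisions(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise DataError("empty score/label input")
    if scores.shape != labels.shape:
        raise DataError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise DataError("labels must be binary 0/1")
    return scores, labels


def metrics_at_threshold(
    scores, labels, threshold: float = 0.5
) -> MetricsAtThreshold:
    """Confusion counts and recall/precision/accuracy at a score threshold."""
    scores, labels = _validate(scores, labels)
    if not np.any(labels == 1):
        raise DataError("no positive examples: recall is undefined")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    recall = tp / (tp + fn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    return MetricsAtThreshold(
        threshold=threshold,
        recall=recall,
        precision=precision,
        accuracy=accuracy,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def pr_curve(scores, labels) -> PRCurve:
    """Precision-recall curve over every distinct score threshold.

    The area is the step-wise sum ``Σ (R_k − R_{k−1}) · P_k`` over operating
    points in order of decreasing threshold (increasing recall), i.e. average
    precision without interpolation.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or n_pos == labels.size:
        raise DataError("pr_curve requires both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group tied scores: cumulative counts at the last index of each tie block
    distinct_idx = np.nonzero(np.diff(s))[0]
    block_ends = np.concatenate([distinct_idx, [s.size - 1]])
    tp_cum = np.cumsum(y)[block_ends]
    n_called = block_ends + 1
    fp_cum = n_called - tp_cum
    recalls = tp_cum / n_pos
    precisions = tp_cum / n_called
    prev_r = np.concatenate([[0.0], recalls[:-1]])
    auc = float(np.sum((recalls - prev_r) * precisions))
    points = tuple(zip(recalls.tolist(), precisions.tolist()))
    return PRCurve(points=points, auc=auc)


@dataclass(frozen=True)
class ScoreDensity:
    """Per-class normalised score histograms over [0, 1] (masses sum to 1)."""

    bin_edges: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    positive_empty: bool
    negative_empty: bool


def score_density(scores, labels, bins: int = 20) -> ScoreDensity:
    """Histogram the scores of each class over [0, 1], normalised to unit mass."""
    scores, labels = _validate(scores, labels)
    if bins < 2:
        raise DataError("bins must be >= 2")
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = {}
    flags = {}
    for cls, name in ((1, "positive"), (0, "negative")):
        vals = scores[labels == cls]
        if vals.size == 0:
            out[name] = np.zeros(bins)
            flags[name] = True
        else:
            hist, _ = np.histogram(vals, bins=edges)
            out[name] = hist / hist.sum()
            flags[name] = False
    return ScoreDensity(
        bin_edges=edges,
        positive=out["positive"],
        negative=out["negative"],
        positive_empty=flags["positive"],
        negative_empty=flags["negative"],
    )


def overlap_coefficient(density: ScoreDensity) -> float:
    """Histogram overlap between the class score distributions (0 = separated)."""
    return float(np.minimum(density.positive, density.negative).sum())
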