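"""Precision-recall machinery and the prevalence-adjusted AUCPR metric.

Across a grid of effective thresholds the positive-class prevalence changes,
and with it the floor of the precision-recall curve: predicting everything
positive already achieves precision equal to prevalence at recall one
(P_R=1).  Plain AUCPR therefore rewards permissive thresholds.  The adjusted
metric

    AUCPR_adj = AUCPR - P_R=1

removes that floor, so a model with no discriminatory ability scores 0 at
any prevalence and a perfect ranker scores 1 - prevalence.  AUCPR is the
step integral sum_i (r_i - r_{i-1}) * p_i over the curve points in
descending-margin order (no trapezoidal interpolation, which is known to be
optimistic for PR curves).  For cross-model comparison, AUCPR_adj values of
one evaluation stage are min-max normalized to 0-100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .classifiers import classify


class MetricError(ValueError):
    """Base class for evaluation failures."""


class UndefinedMetricError(MetricError):
    """Metric undefined for this label composition (e.g. no positives)."""


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def contingency_table(y_true, y_pred) -> ContingencyTable:
    """Counts of the four outcome cells of binary predictions."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if y.shape != p.shape or y.size == 0:
        raise MetricError("y_true and y_pred must be equal-length and non-empty")
    return ContingencyTable(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


@dataclass(frozen=True)
class PRCurve:
    """Ordered (recall, precision) points with the margins that produced them.

    Points are in descending-margin order, so recalls are non-decreasing.
    ``margins[i]`` is the score threshold s_i: the point arises from
    classifying positive every record with score >= s_i, i.e. from any
    confidence margin in [s_{i+1}, s_i).  The first point is the zero-
    positive endpoint (recall 0, precision 1 by convention); the last is the
    all-positive endpoint (recall 1, precision = prevalence).
    """

    margins: np.ndarray
    recalls: np.ndarray
    precisions: np.ndarray
    n_pos: int
    n_neg: int

    def point_at_margin(self, margin: float) -> tuple[float, float]:
        """(recall, precision) of the binary call ``score > margin``."""
        above = np.flatnonzero(self.margins > margin)
        i = above[-1] if above.size else 0
        return float(self.recalls[i]), float(self.precisions[i])


def precision_recall_curve(y_true, scores) -> PRCurve:
    """One curve point per distinct score (descending), plus the endpoints."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise MetricError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(y.size - n_pos)
    if n_pos == 0:
        raise UndefinedMetricError("recall is undefined without positive labels")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # last index of each run of equal scores
    boundaries = np.flatnonzero(np.diff(s_sorted) != 0)
    boundaries = np.append(boundaries, s_sorted.size - 1)
    tp = np.cumsum(y_sorted)[boundaries]
    fp = np.cumsum(1 - y_sorted)[boundaries]
    margins = np.concatenate([[np.inf], s_sorted[boundaries]])
    recalls = np.concatenate([[0.0], tp / n_pos])
    precisions = np.concatenate([[1.0], tp / (tp + fp)])
    return PRCurve(
        margins=margins, recalls=recalls, precisions=precisions, n_pos=n_pos, n_neg=n_neg
    )


def aucpr(curve: PRCurve) -> float:
    """Step integral of precision over recall (see module docstring)."""
    prev = np.concatenate([[0.0], curve.recalls[:-1]])
    return float(np.sum((curve.recalls - prev) * curve.precisions))


def p_at_full_recall(y_true) -> float:
    """Precision of the all-positive prediction: the positive-class prevalence."""
    y = np.asarray(y_true, dtype=int)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise UndefinedMetricError("P_R=1 is undefined without positive labels")
    return n_pos / y.size


def aucpr_adj(curve: PRCurve, y_true) -> float:
    """AUCPR minus P_R=1; negative for worse-than-baseline rankers."""
    return aucpr(curve) - p_at_full_recall(y_true)


def roc_auc(y_true, scores) -> float:
    """Probability a random positive outranks a random negative, ties half."""
    y = np.asarray(y_true, dtype=int)
    if np.unique(y).size < 2:
        raise UndefinedMetricError("ROC AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def normalize_scores(values) -> np.ndarray:
    """Min-max scale a collection to [0, 100]; constant input maps to all-0.

    Applied once per evaluation stage (e.g. all cross-validation results
    together, all holdout results together), never across stages.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise MetricError("cannot normalize an empty collection")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo) * 100.0


RECALL_GRID = np.linspace(0.0, 1.0, 101)


def average_pr_curves(curves) -> PRCurve:
    """Vertical average: per-curve step precision on a shared recall grid.

    The precision of a curve at grid recall r is the precision of its first
    point with recall >= r (step interpolation); the averaged curve's recalls
    are exactly the shared grid.
    """
    curves = list(curves)
    if not curves:
        raise MetricError("average_pr_curves requires at least one curve")
    grid = RECALL_GRID
    stack = np.empty((len(curves), grid.size))
    for row, c in enumerate(curves):
        idx = np.searchsorted(c.recalls, grid, side="left")
        idx = np.minimum(idx, c.recalls.size - 1)
        stack[row] = c.precisions[idx]
    return PRCurve(
        margins=np.full(grid.size, np.nan),
        recalls=grid.copy(),
        precisions=stack.mean(axis=0),
        n_pos=int(sum(c.n_pos for c in curves)),
        n_neg=int(sum(c.n_neg for c in curves)),
    )


@dataclass
class ModelEvaluation:
    """All evaluation artifacts of one model on one record set."""

    curve: PRCurve
    aucpr: float
    p_r1: float
    aucpr_adj: float
    roc_auc: float
    table: ContingencyTable
    normalized_adj: float | None = None

    def to_dict(self) -> dict:
        d = {
            "aucpr": self.aucpr,
            "p_r1": self.p_r1,
            "aucpr_adj": self.aucpr_adj,
            "roc_auc": self.roc_auc,
            "normalized_adj": self.normalized_adj,
        }
        d.update(self.table.as_dict())
        return d


def evaluate_predictions(y_true, scores, margin: float = 0.5) -> ModelEvaluation:
    """Curve, AUCPR, P_R=1, AUCPR_adj, ROC AUC and the margin contingency table."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    curve = precision_recall_curve(y, s)
    return ModelEvaluation(
        curve=curve,
        aucpr=aucpr(curve),
        p_r1=p_at_full_recall(y),
        aucpr_adj=aucpr_adj(curve, y),
        roc_auc=roc_auc(y, s),
        table=contingency_table(y, classify(s, margin)),
    )


def curve_frame(curve: PRCurve):
    """Curve as a (margin, recall, precision) table for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {"margin": curve.margins, "recall": curve.recalls, "precision": curve.precisions}
    )
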