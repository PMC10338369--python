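"""Threshold grids, trichotomous labeling, stratified splits and K-fold plans.

Efficacy distributions of small siRNA screens offer no natural cutoff, and
replicate noise makes records on either side of any single threshold
indistinguishable.  The trichotomous scheme therefore uses two cutoffs: an
*effective* threshold h1 (efficacy <= h1 -> EFFECTIVE), an *ineffective*
threshold h2 (efficacy > h2 -> INEFFECTIVE), and everything in between is
UNDEFINED and excluded from model development.  Candidate thresholds are the
interior equal-count (decile) boundaries of the observed efficacies, and
every ordered pair h1 <= h2 drawn from that grid is evaluated - n(n+1)/2
pairs, i.e. 45 for the default nine thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np


class PartitionError(ValueError):
    """Base class for partitioning failures."""


class DegeneracyError(PartitionError):
    """Equal-count thresholds collide (too few distinct efficacies)."""


class OrderingError(PartitionError):
    """Threshold list is not strictly increasing."""


class StratificationError(PartitionError):
    """A class is empty or too small to stratify."""


class ParameterError(PartitionError):
    """Invalid K or fraction."""


class ClassLabel(Enum):
    EFFECTIVE = "E"
    INEFFECTIVE = "I"
    UNDEFINED = "U"


@dataclass(frozen=True)
class ThresholdPair:
    """Effective (h1) / ineffective (h2) efficacy cutoffs, h1 <= h2, in percent."""

    h1: float
    h2: float

    def __post_init__(self):
        if not (math.isfinite(self.h1) and math.isfinite(self.h2)):
            raise PartitionError("thresholds must be finite")
        if self.h1 > self.h2:
            raise PartitionError(f"h1 must be <= h2, got ({self.h1}, {self.h2})")

    @property
    def label(self) -> str:
        """Display label with integer-rounded percents, e.g. ``"22/53"``."""
        return f"{round(self.h1)}/{round(self.h2)}"


def select_equal_count_thresholds(efficacies, n_groups: int = 10) -> np.ndarray:
    """Interior equal-count (quantile) boundaries of the efficacy distribution.

    Threshold k is the largest observed value v such that at most k*n/n_groups
    values are <= v (lower empirical quantile), keeping thresholds at observed
    data values.  Returns ``n_groups - 1`` strictly increasing thresholds.
    """
    vals = np.sort(np.asarray(efficacies, dtype=float))
    n = vals.size
    if n_groups < 2:
        raise ParameterError("n_groups must be >= 2")
    if n < n_groups:
        raise DegeneracyError(f"need at least {n_groups} values, got {n}")
    ranks = [int(math.floor(k * n / n_groups)) for k in range(1, n_groups)]
    thresholds = vals[[r - 1 for r in ranks]]
    dup = np.flatnonzero(np.diff(thresholds) <= 0)
    if dup.size:
        raise DegeneracyError(
            f"too few distinct efficacies: boundary value {thresholds[dup[0] + 1]!r} "
            "is duplicated"
        )
    return thresholds


def enumerate_threshold_pairs(thresholds) -> list[ThresholdPair]:
    """All (h1, h2) with h1 <= h2 drawn from a strictly increasing grid.

    Ordered by h1 ascending then h2 ascending; count is n(n+1)/2.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or thr.size == 0:
        raise OrderingError("thresholds must be a non-empty 1-d sequence")
    if np.any(np.diff(thr) <= 0):
        raise OrderingError("thresholds must be strictly increasing")
    return [
        ThresholdPair(float(thr[i]), float(thr[j]))
        for i in range(thr.size)
        for j in range(i, thr.size)
    ]


def assign_classes(records, pair: ThresholdPair) -> list[ClassLabel]:
    """Trichotomous labels for records (or bare efficacies) under a pair.

    efficacy <= h1 -> EFFECTIVE; efficacy > h2 -> INEFFECTIVE; otherwise
    UNDEFINED.  When h1 = h2 no record is UNDEFINED.
    """
    eff = _efficacies(records)
    out = []
    for e in eff:
        if e <= pair.h1:
            out.append(ClassLabel.EFFECTIVE)
        elif e > pair.h2:
            out.append(ClassLabel.INEFFECTIVE)
        else:
            out.append(ClassLabel.UNDEFINED)
    return out


def partition_indices(efficacies, pair: ThresholdPair):
    """Index arrays (effective, ineffective, undefined) under a pair."""
    eff = np.asarray(_efficacies(efficacies), dtype=float)
    e_idx = np.flatnonzero(eff <= pair.h1)
    i_idx = np.flatnonzero(eff > pair.h2)
    u_idx = np.flatnonzero((eff > pair.h1) & (eff <= pair.h2))
    return e_idx, i_idx, u_idx


def _efficacies(records):
    if len(records) and hasattr(records[0], "efficacy_pct"):
        return [r.efficacy_pct for r in records]
    return list(records)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint training/holdout index sets over the labeled (E u I) records."""

    training_idx: np.ndarray
    holdout_idx: np.ndarray
    seed: int
    train_fraction: float

    def __post_init__(self):
        object.__setattr__(self, "training_idx", np.sort(np.asarray(self.training_idx)))
        object.__setattr__(self, "holdout_idx", np.sort(np.asarray(self.holdout_idx)))


def stratified_holdout_split(labels, train_fraction: float = 0.75, seed: int = 0) -> DatasetSplit:
    """Seeded stratified training/holdout split of binary-labeled records.

    ``labels`` is a binary array (1 = effective); UNDEFINED records must
    already be excluded.  The training set holds round(train_fraction * n)
    records, allocated per class by largest remainder so per-class
    proportions are preserved within one record.
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError(f"train_fraction must be in (0, 1), got {train_fraction}")
    classes = [1, 0]
    class_idx = {c: np.flatnonzero(y == c) for c in classes}
    for c in classes:
        if class_idx[c].size < 2:
            raise StratificationError(
                f"class {c} has {class_idx[c].size} record(s); need at least 2 per class"
            )
    n_train = int(math.floor(train_fraction * n + 0.5))
    exact = {c: train_fraction * class_idx[c].size for c in classes}
    base = {c: int(math.floor(exact[c])) for c in classes}
    remainder = n_train - sum(base.values())
    by_frac = sorted(classes, key=lambda c: (-(exact[c] - base[c]), c))
    for c in by_frac[:remainder]:
        base[c] += 1
    rng = np.random.default_rng(seed)
    train_parts, hold_parts = [], []
    for c in classes:
        perm = rng.permutation(class_idx[c])
        train_parts.append(perm[: base[c]])
        hold_parts.append(perm[base[c] :])
    return DatasetSplit(
        training_idx=np.concatenate(train_parts),
        holdout_idx=np.concatenate(hold_parts),
        seed=seed,
        train_fraction=train_fraction,
    )


@dataclass(frozen=True)
class KFoldPlan:
    """K disjoint, class-balanced, near-equal folds over the training records."""

    folds: tuple
    k: int
    seed: int


def make_kfold_plan(labels, k: int = 10, seed: int = 0) -> KFoldPlan:
    """Seeded class-balanced K-fold partition of binary-labeled training records.

    Each class is shuffled and split independently into K near-equal chunks;
    the larger chunks of one class are paired with the smaller chunks of the
    other so overall fold sizes also differ by at most one.
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of training records ({n})")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise StratificationError("both classes must be present for a balanced K-fold plan")
    rng = np.random.default_rng(seed)
    pos_chunks = np.array_split(rng.permutation(pos), k)  # sizes non-increasing
    neg_chunks = np.array_split(rng.permutation(neg), k)[::-1]  # sizes non-decreasing
    folds = tuple(
        np.sort(np.concatenate([pc, nc])) for pc, nc in zip(pos_chunks, neg_chunks)
    )
    return KFoldPlan(folds=folds, k=k, seed=seed)
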