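"""The two model families: a small random forest and a frequency-difference
linear classifier, behind one train/score contract.

The forest (200 trees, depth 3, >= 1 sample per leaf) is deliberately
shallow: with only a few dozen effective/ineffective training examples per
threshold pair, deeper trees overfit, while depth 3 still captures pairwise
position-base conjunctions.  The linear classifier scores a sequence by the
per-position difference between base frequencies among effective and among
ineffective training records, the classical first-generation siRNA design
rule.  Both emit a confidence score in [0, 1]; a margin (default 0.5) turns
the score into a binary call, with ties classified negative - conservative
for siRNA design, where false positives are the costly error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .records import BASES, N_FEATURES, TARGET_SITE_LENGTH, vector_to_matrix


class TrainingError(ValueError):
    """Training input is unusable (e.g. a single class)."""


class ModelStateError(RuntimeError):
    """Operation requires a trained model."""


class FamilyError(TypeError):
    """Operation applies to a different model family."""


class MarginError(ValueError):
    """Confidence margin outside [0, 1]."""


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (defaults are the framework's fixed choice)."""

    n_trees: int = 200
    max_depth: int = 3
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_trees, self.max_depth, self.min_samples_leaf) < 1:
            raise ValueError("n_trees, max_depth and min_samples_leaf must all be positive")

    def with_seed(self, seed: int) -> "ForestConfig":
        return replace(self, seed=int(seed))


def _check_training_input(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise TrainingError(f"X must be (n, {N_FEATURES}), got {X.shape}")
    if X.shape[0] != y.size or y.size < 2:
        raise TrainingError("need |X| = |y| >= 2")
    if np.unique(y).size < 2:
        raise TrainingError("both classes must be present in y")
    return X, y


@dataclass
class TrainedClassifier:
    """Base class: an opaque fitted state plus training metadata."""

    family: str
    meta: dict = field(default_factory=dict)

    def predict_confidence(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class RandomForestModel(TrainedClassifier):
    config: ForestConfig = field(default_factory=ForestConfig)
    _forest: RandomForestClassifier | None = None

    def predict_confidence(self, X) -> np.ndarray:
        if self._forest is None:
            raise ModelStateError("forest has not been trained")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        proba = self._forest.predict_proba(X)
        pos_col = int(np.flatnonzero(self._forest.classes_ == 1)[0])
        return proba[:, pos_col]


@dataclass
class LinearFreqDiffModel(TrainedClassifier):
    """Frequency-difference weights plus the training-score range.

    ``weights[p, b]`` = frequency of base b at position t(p+1) among EFFECTIVE
    training records minus the frequency among INEFFECTIVE ones; the raw score
    of a sequence is the sum over positions of the weight of its observed
    base.  Raw scores are mapped to [0, 1] by min-max over the training-set
    scores (clipped for out-of-range probes) so the linear model exposes the
    same confidence contract as the forest.
    """

    weights: np.ndarray | None = None
    score_min: float = 0.0
    score_max: float = 0.0

    def raw_scores(self, X) -> np.ndarray:
        if self.weights is None:
            raise ModelStateError("linear model has not been trained")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights.reshape(N_FEATURES)

    def predict_confidence(self, X) -> np.ndarray:
        raw = self.raw_scores(X)
        span = self.score_max - self.score_min
        if span <= 0:
            # Degenerate training scores carry no ranking information.
            return np.full(raw.shape, 0.5)
        return np.clip((raw - self.score_min) / span, 0.0, 1.0)


def train_random_forest(X, y, config: ForestConfig | None = None) -> RandomForestModel:
    """Fit the random forest; identical seed and data give identical behavior."""
    config = config or ForestConfig()
    X, y = _check_training_input(X, y)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        random_state=config.seed,
    )
    forest.fit(X, y)
    return RandomForestModel(
        family="forest",
        meta={"n_train": int(y.size), "seed": config.seed},
        config=config,
        _forest=forest,
    )


def train_linear_freqdiff(X, y) -> LinearFreqDiffModel:
    """Fit the frequency-difference linear classifier."""
    X, y = _check_training_input(X, y)
    freq_eff = vector_to_matrix(X[y == 1].mean(axis=0))
    freq_ineff = vector_to_matrix(X[y == 0].mean(axis=0))
    weights = freq_eff - freq_ineff
    model = LinearFreqDiffModel(
        family="linear", meta={"n_train": int(y.size)}, weights=weights
    )
    raw = model.raw_scores(X)
    model.score_min = float(raw.min())
    model.score_max = float(raw.max())
    return model


def predict_confidence(model: TrainedClassifier, X) -> np.ndarray:
    """Confidence in [0, 1] that each encoded sequence is EFFECTIVE."""
    return model.predict_confidence(X)


def classify(scores, margin: float = 0.5) -> np.ndarray:
    """Binary calls from confidence scores: positive iff score > margin.

    A score exactly at the margin is classified negative.
    """
    if not 0.0 <= margin <= 1.0:
        raise MarginError(f"margin must be within [0, 1], got {margin}")
    return (np.asarray(scores, dtype=float) > margin).astype(int)


def save_model(model: TrainedClassifier, path) -> None:
    """Persist a trained classifier as a self-describing joblib archive."""
    payload = {
        "format": "sirnaforest-model",
        "version": 1,
        "family": model.family,
        "meta_json": json.dumps(model.meta, default=str, sort_keys=True),
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedClassifier:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "sirnaforest-model":
        raise ValueError(f"{path}: not a sirnaforest model archive")
    return payload["model"]


def linear_weights_frame(model: LinearFreqDiffModel):
    """The linear weights as a labeled 20 x 4 table (t1..t20 by A,U,C,G)."""
    import pandas as pd

    if model.family != "linear":
        raise FamilyError("weights table is defined for the linear family only")
    return pd.DataFrame(
        model.weights,
        index=[f"t{i}" for i in range(1, TARGET_SITE_LENGTH + 1)],
        columns=list(BASES),
    )
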