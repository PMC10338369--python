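"""Model-agnostic proxy feature weights and the AU-GC thermodynamic trend.

Game-theoretic attribution is expensive for 80 one-hot features; the proxy
method instead needs only the model's classification outputs.  Records are
binned into TP/TN/FP/FN at the confidence margin, the one-hot vectors of
each group are averaged, the false-positive and false-negative averages are
negated (they represent incorrect predictions), the four group vectors are
summed, and the sum is reshaped to a 20 x 4 position-by-base matrix.
Weights are then scaled to [-100, 100] and entries with |w| < 20 are zeroed
to suppress low-weight noise.  A positive weight marks a base favored in
distinguishing effective siRNAs; magnitude marks importance.

Group signs: each group's average represents the class it belongs to -
positive for the effective class, negative for the ineffective class - and
the averages of the incorrect groups (FP, FN) are negated on top of that.
The net signs are therefore TP +, FN +, TN -, FP -, which makes a positive
weight mean "favored among effective siRNAs" and lets the proxy matrix of a
linear model approximate its directly extracted weights.  The
``convention="correctness"`` sensitivity variant instead negates only the
incorrect groups (TP +, TN +, FP -, FN -); it measures how correctly and
incorrectly classified records differ in composition, and carries no class
direction (conditioning on the prediction cancels it), so it is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import FamilyError, LinearFreqDiffModel, TrainedClassifier, classify, predict_confidence
from .records import BASES, TARGET_SITE_LENGTH, vector_to_matrix

#: Normalized entries with magnitude below this are set to zero.
ZERO_BAND = 20.0

GROUP_NAMES = ("TP", "TN", "FP", "FN")


@dataclass(frozen=True)
class WeightMatrix:
    """20 positions x 4 bases (A, U, C, G) of signed importance weights."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (TARGET_SITE_LENGTH, len(BASES)):
            raise ValueError(f"weight matrix must be 20 x 4, got {arr.shape}")
        object.__setattr__(self, "values", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[f"t{i}" for i in range(1, TARGET_SITE_LENGTH + 1)],
            columns=list(BASES),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="position")

    @classmethod
    def from_tsv(cls, path, normalized: bool = False) -> "WeightMatrix":
        df = pd.read_csv(path, sep="\t", index_col="position")
        return cls(values=df[list(BASES)].to_numpy(dtype=float), normalized=normalized)


def classification_groups(
    model: TrainedClassifier, X, y_true, margin: float = 0.5
) -> dict[str, np.ndarray]:
    """Partition record indices into TP/TN/FP/FN at the given margin."""
    y = np.asarray(y_true, dtype=int)
    pred = classify(predict_confidence(model, X), margin)
    return {
        "TP": np.flatnonzero((y == 1) & (pred == 1)),
        "TN": np.flatnonzero((y == 0) & (pred == 0)),
        "FP": np.flatnonzero((y == 0) & (pred == 1)),
        "FN": np.flatnonzero((y == 1) & (pred == 0)),
    }


#: group -> sign, per convention (see module docstring)
SIGN_CONVENTIONS = {
    "class": {"TP": 1.0, "FN": 1.0, "TN": -1.0, "FP": -1.0},
    "correctness": {"TP": 1.0, "TN": 1.0, "FP": -1.0, "FN": -1.0},
}


def proxy_feature_weights(groups: dict, X, convention: str = "class") -> WeightMatrix:
    """Raw proxy weights: signed sum of the four group-mean feature vectors.

    Each empty group contributes the zero vector (the unique neutral element
    of the sum); group means are unweighted by group size.  ``convention``
    selects the group signs - ``"class"`` (default) or ``"correctness"``
    (sensitivity variant); see the module docstring.
    """
    X = np.asarray(X, dtype=float)
    if convention not in SIGN_CONVENTIONS:
        raise ValueError(f"unknown sign convention {convention!r}")
    signs = SIGN_CONVENTIONS[convention]
    if all(len(np.asarray(groups.get(g, []))) == 0 for g in GROUP_NAMES):
        raise ValueError("all four classification groups are empty")
    vec = np.zeros(X.shape[1], dtype=float)
    for g in GROUP_NAMES:
        idx = np.asarray(groups.get(g, []), dtype=int)
        if idx.size:
            vec += signs[g] * X[idx].mean(axis=0)
    return WeightMatrix(values=vector_to_matrix(vec), normalized=False)


def normalize_weight_matrix(w: WeightMatrix, zero_band: float = ZERO_BAND) -> WeightMatrix:
    """Scale to max |entry| = 100 (sign-preserving) and zero the |w| < zero_band band.

    An all-zero matrix is returned unchanged; the operation is idempotent.
    """
    values = np.asarray(w.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("weight matrix contains non-finite entries")
    peak = np.abs(values).max()
    if peak == 0:
        return WeightMatrix(values=values.copy(), normalized=True)
    scaled = values * (100.0 / peak)
    scaled[np.abs(scaled) < zero_band] = 0.0
    return WeightMatrix(values=scaled, normalized=True)


def direct_linear_weights(model: TrainedClassifier) -> WeightMatrix:
    """Normalized weight matrix read directly off a linear model's coefficients."""
    if not isinstance(model, LinearFreqDiffModel) or model.family != "linear":
        raise FamilyError("direct weight extraction applies to the linear family only")
    return normalize_weight_matrix(WeightMatrix(values=model.weights.copy()))


def au_gc_trend(w: WeightMatrix) -> np.ndarray:
    """Per-position (A + U) - (G + C) weight sums: a duplex-stability proxy.

    AU-rich (weakly paired) positions get positive trend; GC-rich (tightly
    paired) positions negative.
    """
    v = w.values
    a, u, c, g = (v[:, BASES.index(b)] for b in ("A", "U", "C", "G"))
    return (a + u) - (g + c)


def trend_frame(trend: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"position": [f"t{i}" for i in range(1, TARGET_SITE_LENGTH + 1)], "trend": trend}
    )


def plot_weight_matrix(w: WeightMatrix, ax=None, cmap: str = "coolwarm"):
    """Heat map of a weight matrix (bases on the y axis, positions on x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.4))
    vmax = max(np.abs(w.values).max(), 1e-9)
    im = ax.imshow(w.values.T, cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(len(BASES)), BASES)
    ax.set_xticks(range(TARGET_SITE_LENGTH), [f"t{i}" for i in range(1, 21)], fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="weight")
    return ax


__all__ = [
    "WeightMatrix",
    "classification_groups",
    "proxy_feature_weights",
    "normalize_weight_matrix",
    "direct_linear_weights",
    "au_gc_trend",
    "trend_frame",
    "plot_weight_matrix",
    "ZERO_BAND",
]
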