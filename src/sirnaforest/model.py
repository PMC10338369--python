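"""Model/Results entry points, in the spirit of statsmodels.

:class:`SiRNAEfficacyModel` binds a dataset to one threshold pair and one
model family; ``fit()`` runs the full assessment protocol (stratified split,
balanced K-fold cross-validation, final training, holdout evaluation) and
returns a :class:`SiRNAEfficacyResults` carrying the classifier, both
evaluations, attribution matrices and a text ``summary()``.
:class:`ThresholdSweep` does the same across the whole threshold grid.
"""

from __future__ import annotations

import numpy as np

from . import attribution as _attr
from .classifiers import predict_confidence
from .evaluation import ModelEvaluation
from .io import records_from_dataframe
from .partitioning import ThresholdPair
from .pipeline import (
    PairResult,
    SweepConfig,
    SweepError,
    SweepResult,
    run_threshold_sweep,
    scan_transcript,
    select_candidates,
    shuffle_labels_control,
)
from .records import encode_sequences


class FitError(RuntimeError):
    """The requested pair is degenerate on this dataset."""


class SiRNAEfficacyModel:
    """A trichotomous-threshold efficacy classifier bound to a dataset.

    Parameters
    ----------
    records : list of SiRNARecord
    threshold_pair : ThresholdPair or (h1, h2)
        Effective/ineffective efficacy cutoffs in percent, h1 <= h2.  Must
        be drawn from the dataset's equal-count threshold grid.
    family : {"forest", "linear"}
    """

    def __init__(self, records, threshold_pair, family: str = "forest", *,
                 n_groups: int = 10, train_fraction: float = 0.75, k: int = 10,
                 margin: float = 0.5, forest_config=None):
        if not isinstance(threshold_pair, ThresholdPair):
            threshold_pair = ThresholdPair(*threshold_pair)
        self.records = list(records)
        self.threshold_pair = threshold_pair
        self.family = family
        kwargs = {} if forest_config is None else {"forest": forest_config}
        self.config = SweepConfig(
            families=(family,),
            n_groups=n_groups,
            train_fraction=train_fraction,
            k=k,
            margin=margin,
            pairs=((threshold_pair.h1, threshold_pair.h2),),
            **kwargs,
        )

    @classmethod
    def from_dataframe(cls, df, threshold_pair, family: str = "forest", **kwargs):
        """Build from a table with id/gene/target_site/efficacy_pct columns."""
        return cls(records_from_dataframe(df), threshold_pair, family, **kwargs)

    def fit(self, seed: int = 0) -> "SiRNAEfficacyResults":
        try:
            sweep = run_threshold_sweep(self.records, self.config, seed)
        except SweepError as exc:
            raise FitError(str(exc)) from exc
        res = sweep.results[self.family][0]
        if res.degenerate:
            raise FitError(
                f"pair {self.threshold_pair.label} is degenerate on this dataset: {res.reason}"
            )
        return SiRNAEfficacyResults(self, res, seed)


class SiRNAEfficacyResults:
    """Fitted classifier plus its cross-validation and holdout evaluations."""

    def __init__(self, model: SiRNAEfficacyModel, pair_result: PairResult, seed: int):
        self.model = model
        self._res = pair_result
        self.seed = seed
        self.classifier = pair_result.model
        self.cv: ModelEvaluation = pair_result.cv
        self.holdout: ModelEvaluation = pair_result.holdout
        self._records_sorted = sorted(model.records, key=lambda r: r.id)

    # -- prediction ------------------------------------------------------
    def predict(self, sequences) -> np.ndarray:
        """Confidence in [0, 1] that each 20-nt sequence is effective."""
        return predict_confidence(self.classifier, encode_sequences(sequences))

    def scan(self, transcript, margin: float | None = None):
        return scan_transcript(
            transcript, self.classifier, self.model.config.margin if margin is None else margin
        )

    def design(self, transcripts, n: int = 10):
        """Scan transcripts and pick the top predicted-effective/-ineffective sets."""
        candidates = []
        for tx in transcripts:
            candidates.extend(self.scan(tx))
        return select_candidates(candidates, n)

    # -- attribution -----------------------------------------------------
    def _eval_matrix(self, on: str):
        labeled = self._res.labeled_idx
        eff = np.array([r.efficacy_pct for r in self._records_sorted])
        y = (eff[labeled] <= self.model.threshold_pair.h1).astype(int)
        X = encode_sequences([self._records_sorted[i].target_site for i in labeled])
        if on == "training":
            sel = self._res.training_idx
        elif on == "holdout":
            sel = self._res.holdout_idx
        elif on == "all":
            sel = np.arange(labeled.size)
        else:
            raise ValueError("on must be 'training', 'holdout' or 'all'")
        return X[sel], y[sel]

    def proxy_weights(self, normalized: bool = True, on: str = "training",
                      convention: str = "class") -> _attr.WeightMatrix:
        """Proxy-extracted position-base weight matrix.

        ``on`` selects the evaluation records: the training set by default
        (the records used in model development), or "holdout"/"all";
        ``convention`` picks the group-sign scheme (see attribution module).
        """
        X, y = self._eval_matrix(on)
        groups = _attr.classification_groups(
            self.classifier, X, y, self.model.config.margin
        )
        w = _attr.proxy_feature_weights(groups, X, convention=convention)
        return _attr.normalize_weight_matrix(w) if normalized else w

    def direct_weights(self) -> _attr.WeightMatrix:
        """Directly extracted (normalized) weights; linear family only."""
        return _attr.direct_linear_weights(self.classifier)

    def au_gc_trend(self, normalized: bool = True, on: str = "training") -> np.ndarray:
        return _attr.au_gc_trend(self.proxy_weights(normalized=normalized, on=on))

    # -- controls --------------------------------------------------------
    def shuffle_control(self, shuffle_seed: int | None = None):
        """Re-evaluate on the holdout set with efficacies permuted vs sequences."""
        return shuffle_labels_control(
            self.model.records,
            self.model.threshold_pair,
            self.model.config,
            seed=self.seed,
            shuffle_seed=shuffle_seed,
            family=self.model.family,
        )

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        r = self._res
        t = self.holdout.table
        lines = [
            "siRNA efficacy classification results",
            "=" * 53,
            f"family:            {self.model.family}",
            f"threshold pair:    {self.model.threshold_pair.label} "
            f"(h1={self.model.threshold_pair.h1:.6g}, h2={self.model.threshold_pair.h2:.6g})",
            f"class sizes:       E={r.n_effective}  I={r.n_ineffective}  U={r.n_undefined}",
            f"train/holdout:     {r.training_idx.size}/{r.holdout_idx.size} "
            f"(fraction {self.model.config.train_fraction}, K={self.model.config.k}, "
            f"seed {self.seed})",
            "-" * 53,
            f"{'':18}{'CV (avg)':>12}{'holdout':>12}",
            f"{'AUCPR':18}{self.cv.aucpr:>12.4f}{self.holdout.aucpr:>12.4f}",
            f"{'P_R=1':18}{self.cv.p_r1:>12.4f}{self.holdout.p_r1:>12.4f}",
            f"{'AUCPR_adj':18}{self.cv.aucpr_adj:>12.4f}{self.holdout.aucpr_adj:>12.4f}",
            f"{'ROC AUC':18}{self.cv.roc_auc:>12.4f}{self.holdout.roc_auc:>12.4f}",
            "-" * 53,
            f"holdout contingency at margin {self.model.config.margin}: "
            f"TP={t.tp} FP={t.fp} TN={t.tn} FN={t.fn}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SiRNAEfficacyResults {self.model.family} pair="
            f"{self.model.threshold_pair.label} holdout_aucpr_adj="
            f"{self.holdout.aucpr_adj:.4f}>"
        )


class ThresholdSweep:
    """The full grid evaluation: every h1 <= h2 pair, per model family."""

    def __init__(self, records, families=("forest",), *, n_groups: int = 10,
                 train_fraction: float = 0.75, k: int = 10, margin: float = 0.5,
                 forest_config=None, pairs=None):
        self.records = list(records)
        kwargs = {} if forest_config is None else {"forest": forest_config}
        self.config = SweepConfig(
            families=tuple(families),
            n_groups=n_groups,
            train_fraction=train_fraction,
            k=k,
            margin=margin,
            pairs=pairs,
            **kwargs,
        )

    @classmethod
    def from_dataframe(cls, df, families=("forest",), **kwargs):
        return cls(records_from_dataframe(df), families, **kwargs)

    def fit(self, seed: int = 0) -> "SweepResults":
        return SweepResults(self, run_threshold_sweep(self.records, self.config, seed))


class SweepResults:
    """Wrapper over the raw sweep with tabular and best-pair accessors."""

    def __init__(self, model: ThresholdSweep, raw: SweepResult):
        self.model = model
        self.raw = raw
        self.thresholds = raw.thresholds

    def to_frame(self):
        return self.raw.to_frame()

    def best_pair(self, family: str | None = None, stage: str = "holdout") -> PairResult:
        family = family or self.model.config.families[0]
        live = [r for r in self.raw.results[family] if not r.degenerate]
        if not live:
            raise SweepError("no non-degenerate pair in sweep")
        return max(live, key=lambda r: getattr(r, stage).aucpr_adj)

    def summary(self) -> str:
        df = self.to_frame()
        cols = [
            "family", "pair", "n_effective", "n_ineffective", "n_undefined",
            "cv_aucpr_adj", "cv_normalized_adj", "holdout_aucpr_adj",
            "holdout_normalized_adj", "degenerate",
        ]
        cols = [c for c in cols if c in df.columns]
        return df[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}")
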