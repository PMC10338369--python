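"""Orchestration: the full threshold-pair sweep, the label-shuffle control
and the transcript-scanning design application.

For every threshold pair the pipeline labels the records, splits the
effective/ineffective subset 75/25 with stratification, runs class-balanced
K-fold cross-validation (vertically averaging the K precision-recall
curves), trains a final model on the whole training set and evaluates it on
the holdout set.  AUCPR_adj values are then min-max normalized to 0-100
within the cross-validation stage and within the holdout stage separately.
Pairs that leave a split or a fold without both classes are marked
degenerate and skipped with a logged reason rather than aborting the sweep:
stringent pairs on small datasets legitimately produce tiny classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifiers import (
    ForestConfig,
    TrainedClassifier,
    classify,
    predict_confidence,
    train_linear_freqdiff,
    train_random_forest,
)
from .evaluation import (
    ContingencyTable,
    ModelEvaluation,
    aucpr,
    average_pr_curves,
    contingency_table,
    curve_frame,
    evaluate_predictions,
    normalize_scores,
    precision_recall_curve,
    roc_auc,
)
from .partitioning import (
    ThresholdPair,
    enumerate_threshold_pairs,
    make_kfold_plan,
    partition_indices,
    select_equal_count_thresholds,
    stratified_holdout_split,
)
from .records import TARGET_SITE_LENGTH, Transcript, encode_sequences

logger = logging.getLogger("sirnaforest")

FAMILIES = ("forest", "linear")


class SweepError(ValueError):
    """The dataset supports no valid threshold pair."""


@dataclass(frozen=True)
class SweepConfig:
    """Knobs of the sweep; defaults are the framework's standard protocol."""

    families: tuple = ("forest",)
    n_groups: int = 10
    train_fraction: float = 0.75
    k: int = 10
    margin: float = 0.5
    forest: ForestConfig = field(default_factory=ForestConfig)
    pairs: tuple | None = None  # optional (h1, h2) restriction of the grid

    def __post_init__(self):
        bad = [f for f in self.families if f not in FAMILIES]
        if bad:
            raise ValueError(f"unknown model families {bad}; expected subset of {FAMILIES}")


@dataclass
class PairResult:
    """Everything the sweep learned about one threshold pair (one family)."""

    pair: ThresholdPair
    family: str
    n_effective: int
    n_ineffective: int
    n_undefined: int
    degenerate: bool = False
    reason: str | None = None
    cv: ModelEvaluation | None = None
    holdout: ModelEvaluation | None = None
    model: TrainedClassifier | None = None
    labeled_idx: np.ndarray | None = None  # indices into the (sorted) record list
    training_idx: np.ndarray | None = None  # positions within labeled_idx
    holdout_idx: np.ndarray | None = None


@dataclass
class SweepResult:
    """Per-pair evaluations across the full grid, per model family."""

    thresholds: np.ndarray
    results: dict
    config: SweepConfig
    seed: int

    def pairs(self) -> list[ThresholdPair]:
        first = next(iter(self.results.values()))
        return [r.pair for r in first]

    def get(self, family: str, pair: ThresholdPair) -> PairResult:
        for r in self.results[family]:
            if r.pair == pair:
                return r
        raise KeyError(f"pair {pair} not in sweep")

    def to_frame(self):
        import pandas as pd

        rows = []
        for family, results in self.results.items():
            for r in results:
                row = {
                    "family": family,
                    "h1": r.pair.h1,
                    "h2": r.pair.h2,
                    "pair": r.pair.label,
                    "n_effective": r.n_effective,
                    "n_ineffective": r.n_ineffective,
                    "n_undefined": r.n_undefined,
                    "degenerate": r.degenerate,
                    "reason": r.reason,
                }
                for stage in ("cv", "holdout"):
                    ev = getattr(r, stage)
                    if ev is not None:
                        row[f"{stage}_aucpr"] = ev.aucpr
                        row[f"{stage}_p_r1"] = ev.p_r1
                        row[f"{stage}_aucpr_adj"] = ev.aucpr_adj
                        row[f"{stage}_roc_auc"] = ev.roc_auc
                        row[f"{stage}_normalized_adj"] = ev.normalized_adj
                rows.append(row)
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        """Deterministic JSON-ready summary (used for reproducibility checks)."""
        out = {
            "seed": self.seed,
            "thresholds": [float(t) for t in self.thresholds],
            "k": self.config.k,
            "train_fraction": self.config.train_fraction,
            "results": {},
        }
        for family, results in self.results.items():
            out["results"][family] = []
            for r in results:
                entry = {
                    "h1": r.pair.h1,
                    "h2": r.pair.h2,
                    "n_effective": r.n_effective,
                    "n_ineffective": r.n_ineffective,
                    "n_undefined": r.n_undefined,
                    "degenerate": r.degenerate,
                    "reason": r.reason,
                }
                for stage in ("cv", "holdout"):
                    ev = getattr(r, stage)
                    entry[stage] = None if ev is None else ev.to_dict()
                out["results"][family].append(entry)
        return out

    def save(self, out_dir) -> None:
        """Write summary JSON plus per-pair curve TSVs."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "sweep_summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary_dict(), fh, indent=1, sort_keys=True)
        for family, results in self.results.items():
            for r in results:
                if r.degenerate:
                    continue
                tag = f"{family}_{round(r.pair.h1)}_{round(r.pair.h2)}"
                curve_frame(r.cv.curve).to_csv(out_dir / f"curve_cv_{tag}.tsv", sep="\t", index=False)
                curve_frame(r.holdout.curve).to_csv(
                    out_dir / f"curve_holdout_{tag}.tsv", sep="\t", index=False
                )


def _derive_seeds(seed: int, family_index: int, pair_index: int) -> dict:
    ss = np.random.SeedSequence(int(seed), spawn_key=(family_index, pair_index))
    vals = ss.generate_state(3).astype(np.int64) % (2**31)
    return {"split": int(vals[0]), "kfold": int(vals[1]), "model": int(vals[2])}


def _train(family: str, X, y, seed: int, config: SweepConfig) -> TrainedClassifier:
    if family == "forest":
        return train_random_forest(X, y, config.forest.with_seed(seed))
    return train_linear_freqdiff(X, y)


def _evaluate_pair(
    X_all, efficacies, pair, family, config, seed, family_index, pair_index
) -> PairResult:
    e_idx, i_idx, u_idx = partition_indices(efficacies, pair)
    base = PairResult(
        pair=pair,
        family=family,
        n_effective=int(e_idx.size),
        n_ineffective=int(i_idx.size),
        n_undefined=int(u_idx.size),
    )
    k = config.k
    if e_idx.size < 2 or i_idx.size < 2:
        base.degenerate, base.reason = True, "fewer than two records in a class"
        return base
    labeled = np.sort(np.concatenate([e_idx, i_idx]))
    y = (np.asarray(efficacies)[labeled] <= pair.h1).astype(int)
    seeds = _derive_seeds(seed, family_index, pair_index)
    split = stratified_holdout_split(y, config.train_fraction, seeds["split"])
    y_train, y_hold = y[split.training_idx], y[split.holdout_idx]
    if np.unique(y_hold).size < 2:
        base.degenerate, base.reason = True, "holdout set lacks a class"
        return base
    if min(np.sum(y_train == 1), np.sum(y_train == 0)) < k:
        base.degenerate, base.reason = (
            True,
            f"a training class is smaller than k={k}; folds would lack a class",
        )
        return base

    X = X_all[labeled]
    X_train = X[split.training_idx]
    plan = make_kfold_plan(y_train, k, seeds["kfold"])
    curves, prevalences, rocs = [], [], []
    pooled = ContingencyTable(0, 0, 0, 0)
    for fold in plan.folds:
        mask = np.ones(y_train.size, dtype=bool)
        mask[fold] = False
        clf = _train(family, X_train[mask], y_train[mask], seeds["model"], config)
        conf = predict_confidence(clf, X_train[fold])
        y_fold = y_train[fold]
        curves.append(precision_recall_curve(y_fold, conf))
        prevalences.append(float(np.mean(y_fold)))
        rocs.append(roc_auc(y_fold, conf))
        pooled = pooled + contingency_table(y_fold, classify(conf, config.margin))
    cv_curve = average_pr_curves(curves)
    cv_aucpr = aucpr(cv_curve)
    cv_p_r1 = float(np.mean(prevalences))
    base.cv = ModelEvaluation(
        curve=cv_curve,
        aucpr=cv_aucpr,
        p_r1=cv_p_r1,
        aucpr_adj=cv_aucpr - cv_p_r1,
        roc_auc=float(np.mean(rocs)),
        table=pooled,
    )

    final = _train(family, X_train, y_train, seeds["model"], config)
    conf_hold = predict_confidence(final, X[split.holdout_idx])
    base.holdout = evaluate_predictions(y_hold, conf_hold, config.margin)
    base.model = final
    base.labeled_idx = labeled
    base.training_idx = split.training_idx
    base.holdout_idx = split.holdout_idx
    return base


def run_threshold_sweep(records, config: SweepConfig | None = None, seed: int = 0) -> SweepResult:
    """Evaluate every enumerated threshold pair for every requested family.

    Records are canonically pre-sorted by id, so results are independent of
    input row order; all randomness is derived from ``seed``.
    """
    config = config or SweepConfig()
    records = sorted(records, key=lambda r: r.id)
    if len(records) < config.n_groups:
        raise SweepError(f"dataset of {len(records)} records is too small to sweep")
    efficacies = np.array([r.efficacy_pct for r in records])
    X_all = encode_sequences([r.target_site for r in records])
    thresholds = select_equal_count_thresholds(efficacies, config.n_groups)
    pairs = enumerate_threshold_pairs(thresholds)
    if config.pairs is not None:
        wanted = [tuple(p) for p in config.pairs]
        pairs = [
            p
            for p in pairs
            if any(np.isclose(p.h1, w[0]) and np.isclose(p.h2, w[1]) for w in wanted)
        ]
        if not pairs:
            raise SweepError("no enumerated pair matches the requested restriction")

    results: dict[str, list[PairResult]] = {}
    for fi, family in enumerate(config.families):
        family_results = []
        for pi, pair in enumerate(pairs):
            res = _evaluate_pair(X_all, efficacies, pair, family, config, seed, fi, pi)
            if res.degenerate:
                logger.info("pair %s (%s) skipped: %s", pair.label, family, res.reason)
            family_results.append(res)
        for stage in ("cv", "holdout"):
            live = [r for r in family_results if not r.degenerate]
            if live:
                norm = normalize_scores([getattr(r, stage).aucpr_adj for r in live])
                for r, v in zip(live, norm):
                    getattr(r, stage).normalized_adj = float(v)
        results[family] = family_results
    if all(r.degenerate for fam in results.values() for r in fam):
        raise SweepError("every threshold pair was degenerate; dataset too small")
    return SweepResult(thresholds=thresholds, results=results, config=config, seed=seed)


@dataclass
class ShuffleControlResult:
    """Holdout evaluation before and after permuting efficacies against sequences."""

    original: ModelEvaluation
    shuffled: ModelEvaluation
    permutation: np.ndarray


def shuffle_labels_control(
    records,
    pair: ThresholdPair,
    config: SweepConfig | None = None,
    seed: int = 0,
    shuffle_seed: int | None = None,
    family: str | None = None,
) -> ShuffleControlResult:
    """Permute holdout efficacies against sequences and re-evaluate the model.

    The permutation preserves the efficacy multiset; because every holdout
    record is already effective or ineffective under ``pair``, re-assigning
    classes from the permuted efficacies is exactly a permutation of the
    binary labels.  A model fitting real sequence signal should degrade.
    """
    config = config or SweepConfig()
    family = family or config.families[0]
    restricted = SweepConfig(
        families=(family,),
        n_groups=config.n_groups,
        train_fraction=config.train_fraction,
        k=config.k,
        margin=config.margin,
        forest=config.forest,
        pairs=((pair.h1, pair.h2),),
    )
    sweep = run_threshold_sweep(records, restricted, seed)
    res = sweep.results[family][0]
    if res.degenerate:
        raise SweepError(f"pair {pair.label} is degenerate: {res.reason}")
    records_sorted = sorted(records, key=lambda r: r.id)
    eff = np.array([r.efficacy_pct for r in records_sorted])
    labeled = res.labeled_idx
    y = (eff[labeled] <= pair.h1).astype(int)
    y_hold = y[res.holdout_idx]
    X_hold = encode_sequences(
        [records_sorted[labeled[i]].target_site for i in res.holdout_idx]
    )
    if shuffle_seed is None:
        shuffle_seed = _derive_seeds(seed, 7, 0)["split"]
    perm = np.random.default_rng(shuffle_seed).permutation(y_hold.size)
    conf = predict_confidence(res.model, X_hold)
    return ShuffleControlResult(
        original=res.holdout,
        shuffled=evaluate_predictions(y_hold[perm], conf, config.margin),
        permutation=perm,
    )


@dataclass(frozen=True)
class DesignCandidate:
    """One 20-nt window of a transcript, scored by a trained classifier."""

    transcript_id: str
    start: int  # 1-based, inclusive
    end: int
    target_site: str
    score: float
    predicted_effective: bool

    def __post_init__(self):
        if self.end - self.start + 1 != TARGET_SITE_LENGTH:
            raise ValueError("candidate window must span exactly 20 nt")


def scan_transcript(
    tx: Transcript, model: TrainedClassifier, margin: float = 0.5
) -> list[DesignCandidate]:
    """Score every 20-nt sliding window (stride 1) of a transcript.

    Windows are emitted 5'->3' and mapped into the t1..t20 register in the
    orientation the training data used; a transcript of length L yields
    L - 19 candidates tiling starts 1..L-19.
    """
    seq = tx.sequence
    n_windows = len(seq) - TARGET_SITE_LENGTH + 1
    windows = [seq[i : i + TARGET_SITE_LENGTH] for i in range(n_windows)]
    conf = predict_confidence(model, encode_sequences(windows))
    calls = classify(conf, margin)
    return [
        DesignCandidate(
            transcript_id=tx.id,
            start=i + 1,
            end=i + TARGET_SITE_LENGTH,
            target_site=windows[i],
            score=float(conf[i]),
            predicted_effective=bool(calls[i]),
        )
        for i in range(n_windows)
    ]


def select_candidates(candidates, n: int = 10):
    """Top predicted-effective (highest score) and predicted-ineffective
    (lowest score) candidates; ties broken by ascending window start.

    Returns ``(top_effective, top_ineffective)``; if a group holds fewer than
    ``n`` candidates all of them are returned and a warning is logged.
    """
    effective = sorted(
        (c for c in candidates if c.predicted_effective),
        key=lambda c: (-c.score, c.start, c.transcript_id),
    )
    ineffective = sorted(
        (c for c in candidates if not c.predicted_effective),
        key=lambda c: (c.score, c.start, c.transcript_id),
    )
    for name, group in (("effective", effective), ("ineffective", ineffective)):
        if len(group) < n:
            logger.warning(
                "only %d predicted-%s candidates available (requested %d)",
                len(group), name, n,
            )
    return effective[:n], ineffective[:n]


def design_candidates_frame(candidates):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "start": c.start,
                "end": c.end,
                "target_site": c.target_site,
                "score": c.score,
                "predicted": "effective" if c.predicted_effective else "ineffective",
            }
            for c in candidates
        ]
    )


def subsample_records(records, n: int, seed: int = 0):
    """Seeded sampling without replacement (the downsized-dataset protocol)."""
    if n > len(records):
        raise ValueError(f"cannot subsample {n} from {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(records), size=n, replace=False))
    return [records[i] for i in idx]
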