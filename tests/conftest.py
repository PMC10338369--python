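"""Shared fixtures and independent brute-force oracles for the test suite."""

import numpy as np
import pytest

import sirnaforest as sf


def brute_force_pr_metrics(y, s):
    """Independent PR oracle: enumerate every distinct margin explicitly.

    For each distinct score (descending) classify positive everything at or
    above it, accumulate (recall, precision) points, and integrate the step
    curve as sum (r_i - r_{i-1}) * p_i from recall 0.
    """
    y = [int(v) for v in y]
    s = [float(v) for v in s]
    n_pos = sum(y)
    points = []
    for t in sorted(set(s), reverse=True):
        tp = sum(1 for yi, si in zip(y, s) if si >= t and yi == 1)
        fp = sum(1 for yi, si in zip(y, s) if si >= t and yi == 0)
        points.append((tp / n_pos, tp / (tp + fp)))
    area, prev_r = 0.0, 0.0
    for r, p in points:
        area += (r - prev_r) * p
        prev_r = r
    prevalence = n_pos / len(y)
    return {"aucpr": area, "p_r1": prevalence, "aucpr_adj": area - prevalence}


def brute_force_roc_auc(y, s):
    """Concordant-pair count over all positive/negative pairs, ties half."""
    pos = [si for si, yi in zip(s, y) if yi == 1]
    neg = [si for si, yi in zip(s, y) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


@pytest.fixture
def pr_oracle():
    return brute_force_pr_metrics


@pytest.fixture
def roc_oracle():
    return brute_force_roc_auc


@pytest.fixture(scope="session")
def small_dataset():
    """120 planted-signal records over 6 genes; quick enough for sweeps."""
    records, planted = sf.generate_dataset(
        sf.SyntheticConfig(n_records=120, n_genes=6, seed=7)
    )
    return records, planted


@pytest.fixture(scope="session")
def small_thresholds(small_dataset):
    records, _ = small_dataset
    return sf.select_equal_count_thresholds([r.efficacy_pct for r in records])


def random_sequences(rng, n):
    bases = np.array(list("AUCG"))
    return ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(n)]


@pytest.fixture
def seq_factory():
    return random_sequences
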