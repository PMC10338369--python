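"""Domain records and one-hot encoding for siRNA target sites.

An siRNA guide strand (g1..g20) silences a gene by directing RISC to the
complementary 20-nt mRNA target site (t1..t20); RISC cleaves the target
between t10 and t11.  Throughout this package the target-site sequence is
the sole feature source: each position is encoded as a 4-bit indicator in
the fixed base order A, U, C, G, yielding 80 position-base features per
sequence.  Efficacy is percent reporter expression remaining after
treatment, so *lower* values mean *more* effective silencing.

Input sequences may use the DNA alphabet (T is silently mapped to U):
published external siRNA sets are commonly written with DNA overhang
conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TARGET_SITE_LENGTH = 20
BASES = ("A", "U", "C", "G")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_FEATURES = TARGET_SITE_LENGTH * len(BASES)  # 80

#: Printed efficacies are rounded, so a stored mean may disagree with the
#: replicate mean by up to half a percentage point.
REPLICATE_MEAN_TOL = 0.5


class SequenceError(ValueError):
    """Base class for sequence validation failures."""


class SequenceLengthError(SequenceError):
    """Sequence has the wrong length."""


class AlphabetError(SequenceError):
    """Sequence contains characters outside {A, C, G, U, T}."""


class ShapeError(ValueError):
    """Array argument has the wrong shape."""


def _normalize(raw: str) -> str:
    if not isinstance(raw, str) or not raw:
        raise AlphabetError("sequence must be a non-empty string")
    return raw.strip().upper().replace("T", "U")


def normalize_rna(raw: str) -> str:
    """Uppercase a sequence and map T to U, validating the RNA alphabet."""
    seq = _normalize(raw)
    bad = sorted(set(seq) - set(BASES))
    if bad:
        raise AlphabetError(f"invalid characters {bad!r}; expected A/C/G/U (or T)")
    return seq


def validate_target_site(raw: str) -> str:
    """Validate a 20-nt target-site sequence.

    Returns the uppercased RNA sequence (T mapped to U).  Raises
    :class:`SequenceLengthError` if the length is not exactly 20 and
    :class:`AlphabetError` for characters outside the siRNA alphabet.
    """
    seq = _normalize(raw)
    if len(seq) != TARGET_SITE_LENGTH:
        raise SequenceLengthError(
            f"target site must be exactly {TARGET_SITE_LENGTH} nt, got {len(seq)}"
        )
    return normalize_rna(seq)


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a validated 20-nt sequence as an 80-long 0/1 feature vector.

    Position blocks of four are appended in sequence order with
    A -> [1,0,0,0], U -> [0,1,0,0], C -> [0,0,1,0], G -> [0,0,0,1].
    """
    seq = validate_target_site(seq)
    vec = np.zeros(N_FEATURES, dtype=float)
    for pos, base in enumerate(seq):
        vec[4 * pos + BASE_INDEX[base]] = 1.0
    return vec


def encode_sequences(seqs) -> np.ndarray:
    """Stack :func:`one_hot_encode` over an iterable of sequences."""
    return np.array([one_hot_encode(s) for s in seqs], dtype=float)


def vector_to_matrix(vec) -> np.ndarray:
    """Reshape an 80-long feature vector into a 20 x 4 position-by-base matrix.

    Row ``p`` holds the A, U, C, G weights of position t(p+1).  The inverse of
    block flattening, it applies equally to averaged (non-binary) vectors.
    """
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (N_FEATURES,):
        raise ShapeError(f"expected a flat vector of length {N_FEATURES}, got shape {arr.shape}")
    return arr.reshape(TARGET_SITE_LENGTH, len(BASES))


def matrix_to_vector(mat) -> np.ndarray:
    """Flatten a 20 x 4 position-by-base matrix back into an 80-long vector."""
    arr = np.asarray(mat, dtype=float)
    if arr.shape != (TARGET_SITE_LENGTH, len(BASES)):
        raise ShapeError(
            f"expected a {TARGET_SITE_LENGTH} x {len(BASES)} matrix, got shape {arr.shape}"
        )
    return arr.reshape(N_FEATURES)


def decode_one_hot(vec) -> str:
    """Spell the sequence encoded by a one-hot feature vector (argmax per row)."""
    mat = vector_to_matrix(vec)
    return "".join(BASES[i] for i in mat.argmax(axis=1))


@dataclass(frozen=True)
class SiRNARecord:
    """One siRNA compound: identity, 20-nt target site and measured efficacy.

    ``efficacy_pct`` is percent reporter expression remaining; when replicate
    measurements are present their mean must agree with ``efficacy_pct``
    within :data:`REPLICATE_MEAN_TOL` percentage points.
    """

    id: str
    gene: str
    target_site: str
    efficacy_pct: float
    replicates: tuple | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "target_site", validate_target_site(self.target_site))
        eff = float(self.efficacy_pct)
        if not math.isfinite(eff) or eff < 0:
            raise ValueError(f"efficacy_pct must be finite and >= 0, got {self.efficacy_pct!r}")
        object.__setattr__(self, "efficacy_pct", eff)
        if self.replicates is not None:
            reps = tuple(float(r) for r in self.replicates)
            if not reps:
                object.__setattr__(self, "replicates", None)
                return
            if any(not math.isfinite(r) for r in reps):
                raise ValueError(f"record {self.id}: non-finite replicate value")
            if abs(float(np.mean(reps)) - eff) > REPLICATE_MEAN_TOL:
                raise ValueError(
                    f"record {self.id}: replicate mean {np.mean(reps):.3f} disagrees with "
                    f"efficacy_pct {eff:.3f} beyond {REPLICATE_MEAN_TOL}"
                )
            object.__setattr__(self, "replicates", reps)

    @property
    def feature_vector(self) -> np.ndarray:
        return one_hot_encode(self.target_site)


@dataclass(frozen=True)
class Transcript:
    """A target mRNA sequence; must be at least 20 nt so it can be scanned."""

    id: str
    sequence: str = field(repr=False)

    def __post_init__(self):
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        seq = normalize_rna(self.sequence)
        if len(seq) < TARGET_SITE_LENGTH:
            raise SequenceLengthError(
                f"transcript {self.id!r} is {len(seq)} nt; scanning requires >= "
                f"{TARGET_SITE_LENGTH}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)
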