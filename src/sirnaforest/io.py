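"""Readers and writers for the delimited dataset table and FASTA transcripts.

The dataset table is UTF-8 delimited text (comma or tab, auto-detected)
with required header columns ``id``, ``gene``, ``target_site``,
``efficacy_pct`` and optional ``replicate_*`` columns.  Transcripts are
plain FASTA; T and U are both accepted and normalized to RNA.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import SequenceLengthError, SiRNARecord, Transcript

REQUIRED_COLUMNS = ("id", "gene", "target_site", "efficacy_pct")


class DatasetError(ValueError):
    """Base class for dataset table problems."""


class SchemaError(DatasetError):
    """The table is missing required columns."""


class RowError(DatasetError):
    """One or more rows failed validation; the message lists them."""


class DuplicateIdError(DatasetError):
    """Two rows share an id."""


class TranscriptError(ValueError):
    """No usable transcript records were found."""


def _detect_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_dataset(path) -> list[SiRNARecord]:
    """Read the siRNA dataset table, validating every row.

    Row order is preserved; duplicate ids and any invalid sequence or
    efficacy raise an error naming the offending rows.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={"id": str, "gene": str, "target_site": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    rep_cols = sorted(c for c in df.columns if c.startswith("replicate"))

    seen: set[str] = set()
    records: list[SiRNARecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rid = getattr(row, "id")
        if rid in seen:
            raise DuplicateIdError(f"{path.name}: duplicate id {rid!r}")
        seen.add(rid)
        reps = None
        if rep_cols:
            vals = [getattr(row, c) for c in rep_cols]
            vals = [float(v) for v in vals if pd.notna(v)]
            reps = tuple(vals) if vals else None
        try:
            records.append(
                SiRNARecord(
                    id=rid,
                    gene=getattr(row, "gene"),
                    target_site=getattr(row, "target_site"),
                    efficacy_pct=float(getattr(row, "efficacy_pct")),
                    replicates=reps,
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {i} (id={rid!r}): {exc}")
    if problems:
        raise RowError(f"{path.name}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    return records


def write_dataset(records, path, delimiter: str = ",") -> None:
    """Write records to a delimited table readable by :func:`read_dataset`."""
    max_reps = max((len(r.replicates) for r in records if r.replicates), default=0)
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "gene": r.gene,
            "target_site": r.target_site,
            "efficacy_pct": r.efficacy_pct,
        }
        for k in range(max_reps):
            row[f"replicate_{k + 1}"] = (
                r.replicates[k] if r.replicates and k < len(r.replicates) else np.nan
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def records_from_dataframe(df: pd.DataFrame) -> list[SiRNARecord]:
    """Build validated records from an in-memory table with the standard columns."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dataframe is missing required column(s) {missing}")
    rep_cols = sorted(c for c in df.columns if c.startswith("replicate"))
    records = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        rid = str(getattr(row, "id"))
        if rid in seen:
            raise DuplicateIdError(f"duplicate id {rid!r}")
        seen.add(rid)
        reps = None
        if rep_cols:
            vals = [float(getattr(row, c)) for c in rep_cols if pd.notna(getattr(row, c))]
            reps = tuple(vals) if vals else None
        records.append(
            SiRNARecord(
                id=rid,
                gene=str(getattr(row, "gene")),
                target_site=str(getattr(row, "target_site")),
                efficacy_pct=float(getattr(row, "efficacy_pct")),
                replicates=reps,
            )
        )
    return records


def dataset_to_dataframe(records) -> pd.DataFrame:
    """Inverse of :func:`records_from_dataframe` (replicates as replicate_k columns)."""
    max_reps = max((len(r.replicates) for r in records if r.replicates), default=0)
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "gene": r.gene,
            "target_site": r.target_site,
            "efficacy_pct": r.efficacy_pct,
        }
        for k in range(max_reps):
            row[f"replicate_{k + 1}"] = (
                r.replicates[k] if r.replicates and k < len(r.replicates) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def read_transcripts(path) -> list[Transcript]:
    """Read FASTA transcripts, normalizing to the RNA alphabet.

    Records shorter than 20 nt are excluded with a warning (they cannot be
    scanned); if every record fails, a :class:`TranscriptError` is raised.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        try:
            transcripts.append(Transcript(id=rec.id, sequence=str(rec.seq)))
        except SequenceLengthError as exc:
            warnings.warn(f"{path.name}: skipping transcript {rec.id!r}: {exc}", stacklevel=2)
    if n_seen and not transcripts:
        raise TranscriptError(f"{path.name}: no transcript of length >= 20 found")
    return transcripts
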