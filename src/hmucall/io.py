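"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tables are TSV with declared headers
(diffable between pipeline stages); BED is 0-based half-open.  All writers
round-trip losslessly through the matching reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .overlap import IntervalSet
from .pileup import SIGNAL_COLUMNS
from .simdata import COUNTS_COLUMNS

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "bed_to_intervalset",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_signals_tsv",
    "write_signals_tsv",
    "t_positions",
]

BED_COLUMNS = ["ref", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    """Malformed input file; the message carries the file and line/record."""


def read_fasta(path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def read_fastq(path) -> list[SeqRecord]:
    """Strict 4-line FASTQ; parse failures report the offending line."""
    records = []
    it = SeqIO.parse(str(path), "fastq")
    while True:
        try:
            rec = next(it)
        except StopIteration:
            break
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed FASTQ near line {4 * len(records) + 1}: {exc}"
            ) from exc
        records.append(rec)
    return records


def write_fastq(reads: Iterable, path, prefix: str = "read", quality: int = 40) -> None:
    """Write reads (strings or SeqRecords) as 4-line FASTQ, constant quality."""
    records = []
    for i, r in enumerate(reads):
        if isinstance(r, SeqRecord):
            rec = r
            if "phred_quality" not in rec.letter_annotations:
                rec.letter_annotations["phred_quality"] = [quality] * len(rec)
        else:
            rec = SeqRecord(Seq(str(r)), id=f"{prefix}_{i+1}", description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(rec)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_bed(path) -> pd.DataFrame:
    """BED3+ as a DataFrame; coordinates 0-based half-open, validated per line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            ref = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            if start < 0 or end <= start:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) (need 0 <= start < end)"
                )
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((ref, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def bed_to_intervalset(bed: pd.DataFrame, ref: str, length: int) -> IntervalSet:
    sub = bed[bed["ref"] == ref]
    return IntervalSet(ref, list(zip(sub["start"], sub["end"])), length)


def _read_table(path, columns: Sequence[str], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: {kind} table missing column(s) {missing}")
    return df[list(columns)]


def read_counts_tsv(path) -> pd.DataFrame:
    return _read_table(path, COUNTS_COLUMNS, "count")


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df[COUNTS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_signals_tsv(path) -> pd.DataFrame:
    return _read_table(path, SIGNAL_COLUMNS, "signal")


def write_signals_tsv(df: pd.DataFrame, path) -> None:
    df[SIGNAL_COLUMNS].to_csv(path, sep="\t", index=False)


def t_positions(seq: str) -> np.ndarray:
    """0-based positions of T in a sequence (candidate positions for calls)."""
    arr = np.frombuffer(str(seq).upper().encode("ascii"), dtype="S1")
    return np.flatnonzero(arr == b"T")
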