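"""File I/O: FASTA/FASTQ via Biopython, truth tables and TSVs via pandas.

All writers are deterministic (fixed column order, fixed float format) so
that identical inputs always produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TRUTH_VERSION = "satquant-truth-v1"
FLOAT_FORMAT = "%.10g"

# Constant base quality: quality is never consumed downstream.
_QUAL = 40


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads, path: str | Path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [_QUAL] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_table(frame: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a TSV with optional '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_table`; returns (frame, metadata)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = value
            pos = fh.tell()
        frame = pd.read_csv(fh, sep="\t")
    return frame, meta


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    write_table(truth, path, header_lines=[f"version={TRUTH_VERSION}"])


def read_truth(path: str | Path) -> pd.DataFrame:
    frame, meta = read_table(path)
    if meta.get("version") != TRUTH_VERSION:
        raise ValueError(f"{path}: not a {TRUTH_VERSION} table")
    return frame
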