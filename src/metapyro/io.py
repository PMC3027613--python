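"""Thin readers/writers for the package's on-disk formats.

Reads travel as FASTA (optionally FASTQ with a uniform placeholder
quality, since the synthetic generator models no per-base qualities);
tables are headered TSV throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .readqc import Read


def read_fasta(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_reads(path: str | Path) -> list[Read]:
    """Dispatch on extension: .fq/.fastq as FASTQ, otherwise FASTA."""
    suffix = Path(path).suffix.lower()
    return read_fastq(path) if suffix in {".fq", ".fastq"} else read_fasta(path)


def _records(reads: Iterable[Read], quality: int | None = None):
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        if quality is not None:
            rec.letter_annotations["phred_quality"] = [quality] * len(read.sequence)
        yield rec


def write_fasta(reads: Sequence[Read], path: str | Path) -> None:
    SeqIO.write(_records(reads), str(path), "fasta")


def write_fastq(reads: Sequence[Read], path: str | Path, quality: int = 30) -> None:
    SeqIO.write(_records(reads, quality), str(path), "fastq")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
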