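"""Shared sequence and table I/O.

FASTA/FASTQ parsing is delegated to Biopython; BED and TSV handling to pandas.
All coordinates are 0-based half-open (BED native). FASTQ may be plain or
gzip-compressed; records with CRLF line endings are tolerated.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

__all__ = [
    "BedInterval",
    "FastqRead",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "read_tsv",
    "write_tsv",
    "write_json",
]


@dataclass(frozen=True)
class BedInterval:
    """A 0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FastqRead:
    """One FASTQ record; ``header`` is the full line after '@'."""

    header: str
    sequence: str
    quality: str

    @property
    def read_id(self) -> str:
        return self.header.split()[0]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, newline=None)


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` mapping (case preserved)."""
    with _open_text(path) as fh:
        records = {}
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise FormatError(f"duplicate FASTA id {rec.id!r}", path=str(path))
            records[rec.id] = str(rec.seq)
    if not records:
        raise FormatError("no FASTA records found", path=str(path))
    return records


def write_fasta(path, records: dict[str, str] | Iterable[tuple[str, str]],
                descriptions: dict[str, str] | None = None, width: int = 70) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqrecs = []
    for name, seq in items:
        desc = (descriptions or {}).get(name, "")
        seqrecs.append(SeqRecord(Seq(seq), id=name, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_fastq(path) -> Iterator[FastqRead]:
    """Yield FASTQ records; permissive about CRLF, strict about structure."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\r\n")
            if not header.startswith("@"):
                raise FormatError("FASTQ header must start with '@'",
                                  path=str(path), line=lineno)
            seq = fh.readline().rstrip("\r\n")
            plus = fh.readline().rstrip("\r\n")
            qual = fh.readline().rstrip("\r\n")
            lineno += 3
            if not plus.startswith("+"):
                raise FormatError("FASTQ separator line must start with '+'",
                                  path=str(path), line=lineno - 1)
            if len(seq) != len(qual):
                raise FormatError("sequence/quality length mismatch",
                                  path=str(path), line=lineno)
            yield FastqRead(header=header[1:], sequence=seq, quality=qual)


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.header}\n{r.sequence}\n+\n{r.quality}\n")


def read_bed(path) -> list[BedInterval]:
    """Parse a BED file (3–6 columns, whitespace-separated, 0-based half-open)."""
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError("BED line has fewer than 3 columns",
                                  path=str(path), line=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError("BED start/end not integers",
                                  path=str(path), line=lineno) from None
            if end < start:
                raise FormatError("BED end < start", path=str(path), line=lineno)
            intervals.append(BedInterval(
                chrom=fields[0], start=start, end=end,
                name=fields[3] if len(fields) > 3 else ".",
                score=fields[4] if len(fields) > 4 else "0",
                strand=fields[5] if len(fields) > 5 else "+",
            ))
    return intervals


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
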