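"""Linker trimming of raw small-RNA reads.

A raw library read is insert + 3'-linker, sequenced to a fixed length.
The insert is recovered by locating the first perfect occurrence of the
linker's 5'-terminal 6-mer and cutting everything from that position on.
Reads in which the 6-mer never occurs are discarded outright — there is
no mismatch tolerance and no full-linker alignment.  ``N`` bases never
match.  Empty inserts (linker found at position 0) survive trimming and
are removed by the length filter, so read accounting stays exact:

    reads_in == inserts_out + discarded_no_linker + discarded_length
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Insert",
    "TrimReport",
    "find_linker",
    "trim_linker",
    "trim_reads",
    "length_filter",
    "trim_library",
    "read_sequences",
    "write_inserts_fasta",
]

MIN_LINKER_MATCH = 6


@dataclass(frozen=True)
class Insert:
    """A trimmed insert; length always equals len(sequence)."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TrimReport:
    """Read-conservation ledger for one library."""

    reads_in: int = 0
    inserts_out: int = 0
    discarded_no_linker: int = 0
    discarded_length: int = 0
    removed_by_length: Counter = field(default_factory=Counter)

    def check_conservation(self) -> None:
        if self.reads_in != (
            self.inserts_out + self.discarded_no_linker + self.discarded_length
        ):
            raise AssertionError("read conservation violated in trimming")


def _validate_linker(linker: str) -> str:
    linker = linker.upper()
    if len(linker) < MIN_LINKER_MATCH:
        raise ValueError(
            f"linker must be at least {MIN_LINKER_MATCH} nt, got {len(linker)}"
        )
    if not set(linker[:MIN_LINKER_MATCH]) <= set("ACGT"):
        raise ValueError("linker 6-mer must contain only A/C/G/T")
    return linker


def find_linker(sequence: str, linker: str) -> int:
    """Leftmost index where the linker's first 6-mer occurs, or -1.

    Matching is case-insensitive and exact; an ``N`` in the read can
    never match a linker base.
    """
    kmer = _validate_linker(linker)[:MIN_LINKER_MATCH]
    return sequence.upper().find(kmer)


def trim_linker(read_id: str, sequence: str, linker: str) -> Insert | None:
    """Trim one raw read; None means no linker 6-mer was found (discard)."""
    if not sequence:
        raise ValueError(f"empty sequence for read {read_id!r}")
    k = find_linker(sequence, linker)
    if k < 0:
        return None
    return Insert(read_id, sequence[:k].upper())


def trim_reads(
    reads: Iterable[tuple[str, str]], linker: str, report: TrimReport | None = None
) -> Iterator[Insert]:
    """Trim a stream of (read_id, sequence), updating *report* if given."""
    _validate_linker(linker)
    for read_id, seq in reads:
        if report is not None:
            report.reads_in += 1
        insert = trim_linker(read_id, seq, linker)
        if insert is None:
            if report is not None:
                report.discarded_no_linker += 1
            continue
        yield insert


def length_filter(
    inserts: Iterable[Insert],
    min_len: int = 18,
    max_len: int = 30,
    report: TrimReport | None = None,
) -> Iterator[Insert]:
    """Keep inserts with min_len <= length <= max_len; log removals by length."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    for insert in inserts:
        if min_len <= insert.length <= max_len:
            if report is not None:
                report.inserts_out += 1
            yield insert
        elif report is not None:
            report.discarded_length += 1
            report.removed_by_length[insert.length] += 1


def trim_library(
    reads: Iterable[tuple[str, str]],
    linker: str,
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[list[Insert], TrimReport]:
    """Full trim + length-filter pass with exact read accounting."""
    report = TrimReport()
    inserts = list(
        length_filter(trim_reads(reads, linker, report), min_len, max_len, report)
    )
    report.check_conservation()
    return inserts, report


# -- I/O -----------------------------------------------------------------

def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ, sniffed from the first byte."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq)


def write_inserts_fasta(inserts: Iterable[Insert], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ins in inserts:
            fh.write(f">{ins.read_id}\n{ins.sequence}\n")
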