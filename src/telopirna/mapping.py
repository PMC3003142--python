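"""Exact full-length placement of inserts on a genome, both strands.

The mapper reports *every* genomic position where an insert matches
perfectly over its whole length — no mismatches, no gaps, no seed-and-
extend heuristics.  Multi-mappers are retained with all placements and
an ``n_hits`` count per read; an optional cap discards reads exceeding
it.  Minus-strand placements are found by searching the reverse
complement of the insert against the forward genome, so the reported
interval is always in forward-genome coordinates.

ncRNA / pre-miRNA filtering removes the whole read (all placements)
whenever any placement overlaps an annotated interval by >= 1 nt,
strand-agnostically.  The per-library normalization denominator is the
number of distinct reads that survive with >= 1 placement.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .annotations import AnnotationSet
from .trim import Insert

__all__ = [
    "ALIGNMENT_COLUMNS",
    "MappingReport",
    "GenomeIndex",
    "revcomp",
    "read_genome_fasta",
    "write_genome_fasta",
    "map_inserts",
    "filter_ncrna",
    "mapped_depth",
    "write_alignments_tsv",
    "read_alignments_tsv",
]

ALIGNMENT_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "n_hits"]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not genome:
        raise ValueError(f"no sequences in genome FASTA {path}")
    return genome


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class MappingReport:
    """Accounting for one mapping pass."""

    inserts_in: int = 0
    mapped_reads: int = 0
    unmapped: int = 0
    capped: int = 0
    unmapped_ids: list[str] = field(default_factory=list)

    def check_conservation(self) -> None:
        if self.inserts_in != self.mapped_reads + self.unmapped + self.capped:
            raise AssertionError("read conservation violated in mapping")


class GenomeIndex:
    """Seed-and-verify exact matcher over a chromosome dictionary.

    Forward-strand k-mer positions are indexed once per seed length; a
    query is located by looking up its leading k-mer and verifying the
    full-length slice.  Equivalent to a brute-force substring scan of
    both strands, but O(occurrences) per query.
    """

    def __init__(self, genome: dict[str, str], seed: int = 18):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.default_seed = seed
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._indexes:
            idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for chrom, seq in self.genome.items():
                for pos in range(len(seq) - k + 1):
                    idx[seq[pos : pos + k]].append((chrom, pos))
            self._indexes[k] = dict(idx)
        return self._indexes[k]

    def _hits_forward(self, query: str, k: int) -> list[tuple[str, int]]:
        idx = self._index_for(k)
        out = []
        for chrom, pos in idx.get(query[:k], ()):
            if self.genome[chrom].startswith(query, pos):
                out.append((chrom, pos))
        return out

    def placements(self, query: str) -> list[tuple[str, int, int, str]]:
        """All (chrom, start, end, strand) exact full-length placements."""
        query = query.upper()
        if not query or "N" in query:
            return []
        k = min(self.default_seed, len(query))
        hits = [(c, p, p + len(query), "+") for c, p in self._hits_forward(query, k)]
        rc = revcomp(query)
        if rc != query:
            hits += [
                (c, p, p + len(query), "-") for c, p in self._hits_forward(rc, k)
            ]
        else:
            # palindromic insert: same interval matches both strands
            hits += [(c, s, e, "-") for c, s, e, _ in list(hits)]
        hits.sort()
        return hits


def map_inserts(
    inserts: Sequence[Insert],
    genome: dict[str, str] | GenomeIndex,
    max_hits: int | None = None,
    chrom_blocklist: Iterable[str] = (),
    seed: int = 18,
) -> tuple[pd.DataFrame, MappingReport]:
    """Map inserts exactly; returns the alignment table and its ledger.

    ``chrom_blocklist`` drops chromosomes before mapping (the analysis
    this models excluded the heterochromatic Y scaffold this way).
    """
    if isinstance(genome, GenomeIndex):
        index = genome
        if chrom_blocklist:
            index = GenomeIndex(
                {c: s for c, s in index.genome.items() if c not in set(chrom_blocklist)},
                seed=index.default_seed,
            )
    else:
        blocked = set(chrom_blocklist)
        index = GenomeIndex(
            {c: s for c, s in genome.items() if c not in blocked}, seed=seed
        )

    report = MappingReport()
    cache: dict[str, list[tuple[str, int, int, str]]] = {}
    rows: list[tuple[str, str, int, int, str, int]] = []
    for ins in inserts:
        report.inserts_in += 1
        seq = ins.sequence.upper()
        if seq not in cache:
            cache[seq] = index.placements(seq)
        hits = cache[seq]
        if not hits:
            report.unmapped += 1
            report.unmapped_ids.append(ins.read_id)
            continue
        if max_hits is not None and len(hits) > max_hits:
            report.capped += 1
            continue
        report.mapped_reads += 1
        for chrom, start, end, strand in hits:
            rows.append((ins.read_id, chrom, start, end, strand, len(hits)))
    report.check_conservation()
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    return df, report


def filter_ncrna(
    alignments: pd.DataFrame,
    annotations: AnnotationSet,
    tracks: Sequence[str] = ("ncrna",),
) -> tuple[pd.DataFrame, list[str]]:
    """Drop every read with any placement overlapping an ncRNA-type track.

    Overlap is >= 1 nt under half-open arithmetic and ignores strand.
    Returns (filtered alignments, removed read ids).
    """
    if alignments.empty:
        return alignments.copy(), []
    removed: set[str] = set()
    present = [t for t in tracks if annotations.tracks.get(t)]
    if present:
        for row in alignments.itertuples(index=False):
            if row.read_id in removed:
                continue
            for track in present:
                if annotations.any_overlap(track, row.chrom, row.start, row.end):
                    removed.add(row.read_id)
                    break
    kept = alignments[~alignments["read_id"].isin(removed)].reset_index(drop=True)
    return kept, sorted(removed)


def mapped_depth(alignments: pd.DataFrame) -> int:
    """Distinct reads with >= 1 surviving alignment — the RPM denominator."""
    if alignments.empty:
        return 0
    return int(alignments["read_id"].nunique())


def write_alignments_tsv(alignments: pd.DataFrame, path: str | Path) -> None:
    alignments.to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns {sorted(missing)}")
    return df
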