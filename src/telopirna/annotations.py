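"""Genomic interval tracks and the designated cluster span.

All coordinates are 0-based half-open internally.  Region strings of the
form ``chr4:1280000-1350999`` follow the genome-browser convention
(1-based, both ends inclusive) and are converted on ingest, so that the
printed span chr4:1280000-1350999 covers exactly 71 kb.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "AnnotationSet",
    "parse_region",
    "format_region",
    "read_bed6",
    "write_bed6",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Overlap by >= 1 nt; abutting half-open intervals do not overlap."""
        return self.chrom == chrom and self.start < end and start < self.end


def parse_region(region: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (1-based inclusive) into half-open coords."""
    m = re.fullmatch(r"([^:]+):([\d,]+)[-–]([\d,]+)", region.strip())
    if m is None:
        raise ValueError(f"cannot parse region string {region!r}")
    chrom = m.group(1)
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    if start1 < 1 or end1 < start1:
        raise ValueError(f"invalid region bounds in {region!r}")
    return GenomicInterval(chrom, start1 - 1, end1)


def format_region(iv: GenomicInterval) -> str:
    """Inverse of :func:`parse_region` (back to 1-based inclusive)."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


class AnnotationSet:
    """Named interval tracks plus one designated cluster span.

    Tracks are plain lists of :class:`GenomicInterval`; overlap queries go
    through per-(track, chromosome) interval trees built lazily.
    """

    def __init__(
        self,
        tracks: dict[str, list[GenomicInterval]] | None = None,
        cluster: GenomicInterval | None = None,
    ) -> None:
        self.tracks: dict[str, list[GenomicInterval]] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._cluster: GenomicInterval | None = None
        for name, ivs in (tracks or {}).items():
            for iv in ivs:
                self.add(name, iv)
        if cluster is not None:
            self.set_cluster(cluster)

    # -- construction ----------------------------------------------------
    def add(self, track: str, interval: GenomicInterval) -> None:
        self.tracks.setdefault(track, []).append(interval)
        self._trees.pop((track, interval.chrom), None)

    def set_cluster(self, interval: GenomicInterval) -> None:
        if self._cluster is not None:
            raise ValueError("cluster already designated")
        self._cluster = interval

    @property
    def cluster(self) -> GenomicInterval:
        if self._cluster is None:
            raise ValueError("no cluster span designated")
        return self._cluster

    @property
    def has_cluster(self) -> bool:
        return self._cluster is not None

    # -- queries ---------------------------------------------------------
    def _tree(self, track: str, chrom: str) -> IntervalTree:
        key = (track, chrom)
        if key not in self._trees:
            tree = IntervalTree()
            for iv in self.tracks.get(track, []):
                if iv.chrom == chrom:
                    tree.addi(iv.start, iv.end, iv)
            self._trees[key] = tree
        return self._trees[key]

    def overlapping(
        self, track: str, chrom: str, start: int, end: int
    ) -> list[GenomicInterval]:
        """All intervals of *track* overlapping [start, end) on *chrom*."""
        return [hit.data for hit in self._tree(track, chrom).overlap(start, end)]

    def any_overlap(self, track: str, chrom: str, start: int, end: int) -> bool:
        return bool(self._tree(track, chrom).overlaps(start, end))

    def validate_against(self, chromosome_lengths: dict[str, int]) -> None:
        """Raise if any interval (or the cluster) exceeds chromosome bounds."""
        everything: Iterable[GenomicInterval] = (
            iv for ivs in self.tracks.values() for iv in ivs
        )
        check = list(everything)
        if self._cluster is not None:
            check.append(self._cluster)
        for iv in check:
            if iv.chrom not in chromosome_lengths:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > chromosome_lengths[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {chromosome_lengths[iv.chrom]}"
                )

    def __iter__(self) -> Iterator[tuple[str, GenomicInterval]]:
        for name, ivs in self.tracks.items():
            for iv in ivs:
                yield name, iv


# -- BED6 I/O ------------------------------------------------------------

def read_bed6(path: str | Path, cluster_track: str = "cluster") -> AnnotationSet:
    """Load an AnnotationSet from BED6 where column 4 is ``track/name``.

    A single interval on *cluster_track* becomes the designated cluster.
    """
    ann = AnnotationSet()
    cluster: GenomicInterval | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            track, _, name = label.partition("/")
            iv = GenomicInterval(chrom, start, end, strand, name or ".")
            if track == cluster_track:
                if cluster is not None:
                    raise ValueError("multiple cluster intervals in BED")
                cluster = iv
            else:
                ann.add(track, iv)
    if cluster is not None:
        ann.set_cluster(cluster)
    return ann


def write_bed6(ann: AnnotationSet, path: str | Path, cluster_track: str = "cluster") -> None:
    """Write all tracks (cluster included) as BED6, track encoded in column 4."""
    with open(path, "w") as fh:
        rows: list[tuple[str, GenomicInterval]] = list(ann)
        if ann.has_cluster:
            rows.append((cluster_track, ann.cluster))
        for track, iv in rows:
            label = track if iv.name == "." else f"{track}/{iv.name}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}\n"
            )
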