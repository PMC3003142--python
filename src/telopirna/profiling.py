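"""Cluster-restricted, strand-split small-RNA profiling.

This module produces the analysis' headline quantities for one library:

* a depth-normalized length histogram of reads overlapping the cluster,
  split by genomic strand (reads per million mapped non-ncRNA reads);
* size-class abundances — the "short" class sums lengths {19, 20, 22}
  (21 nt is excluded wholesale as the endo-siRNA peak) and the "long"
  piRNA class sums 23-29 nt inclusive;
* mutant / wild-type fold-change tables of those classes;
* the fraction of telomeric-element reads attributable to the cluster;
* the ping-pong 5'-overlap histogram with a z-score for the 10-nt bin.

A multi-mapped read contributes once to the histogram: strand and
length are taken from its leftmost cluster-overlapping placement, and a
counter records reads whose cluster placements disagree on strand.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, GenomicInterval

__all__ = [
    "SHORT_LENGTHS",
    "LONG_LENGTHS",
    "LengthHistogram",
    "SizeClassSummary",
    "cluster_histogram",
    "size_class_summary",
    "fold_change",
    "cluster_attribution",
    "ping_pong_signature",
    "PingPongResult",
]

#: lengths summed into the short size class; 21 nt is deliberately absent
SHORT_LENGTHS = (19, 20, 22)
#: lengths summed into the canonical piRNA size class
LONG_LENGTHS = tuple(range(23, 30))

STRANDS = ("+", "-")


@dataclass
class LengthHistogram:
    """Strand x length histogram of cluster reads, raw and per-million."""

    min_len: int
    max_len: int
    depth: int
    raw: dict[tuple[str, int], int]
    ambiguous_strand_reads: int = 0

    @property
    def normalized(self) -> dict[tuple[str, int], float]:
        return {k: v * 1e6 / self.depth for k, v in self.raw.items()}

    def total_reads(self) -> int:
        return sum(self.raw.values())

    def to_frame(self, label: str | None = None) -> pd.DataFrame:
        rows = [
            {
                "strand": s,
                "length": ln,
                "raw": self.raw[(s, ln)],
                "normalized": self.normalized[(s, ln)],
            }
            for s in STRANDS
            for ln in range(self.min_len, self.max_len + 1)
        ]
        df = pd.DataFrame(rows)
        if label is not None:
            df.insert(0, "genotype", label)
        return df


@dataclass
class SizeClassSummary:
    """Per-strand short / long class abundances, in reads per million."""

    label: str
    short_minus: float
    short_plus: float
    long_minus: float
    long_plus: float

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {
            ("short", "-"): self.short_minus,
            ("short", "+"): self.short_plus,
            ("long", "-"): self.long_minus,
            ("long", "+"): self.long_plus,
        }


def cluster_histogram(
    alignments: pd.DataFrame,
    annotations: AnnotationSet,
    min_len: int = 18,
    max_len: int = 30,
    depth: int | None = None,
) -> LengthHistogram:
    """Length histogram of reads with >= 1 placement overlapping the cluster.

    ``depth`` is the library-wide mapped, ncRNA-filtered read count; it
    defaults to the distinct reads in *alignments*, which is correct when
    the full filtered table is passed.
    """
    cluster = annotations.cluster
    if depth is None:
        depth = int(alignments["read_id"].nunique()) if len(alignments) else 0
    if depth <= 0:
        raise ValueError("mapped depth is zero; cannot normalize")

    raw = {(s, ln): 0 for s in STRANDS for ln in range(min_len, max_len + 1)}
    ambiguous = 0
    if len(alignments):
        on = alignments[
            (alignments["chrom"] == cluster.chrom)
            & (alignments["start"] < cluster.end)
            & (alignments["end"] > cluster.start)
        ]
        # leftmost cluster placement decides strand and length per read
        for read_id, grp in on.sort_values(["start", "end", "strand"]).groupby(
            "read_id", sort=False
        ):
            first = grp.iloc[0]
            if grp["strand"].nunique() > 1:
                ambiguous += 1
            length = int(first["end"] - first["start"])
            if min_len <= length <= max_len:
                raw[(str(first["strand"]), length)] += 1
    return LengthHistogram(min_len, max_len, depth, raw, ambiguous)


def size_class_summary(hist: LengthHistogram, label: str = "") -> SizeClassSummary:
    """Sum normalized abundance over the short and long length sets."""
    if hist.min_len > min(SHORT_LENGTHS) or hist.max_len < max(LONG_LENGTHS):
        raise ValueError(
            f"histogram [{hist.min_len},{hist.max_len}] does not cover 19-29"
        )
    norm = hist.normalized

    def total(strand: str, lengths: tuple[int, ...]) -> float:
        return float(sum(norm[(strand, ln)] for ln in lengths))

    return SizeClassSummary(
        label=label,
        short_minus=total("-", SHORT_LENGTHS),
        short_plus=total("+", SHORT_LENGTHS),
        long_minus=total("-", LONG_LENGTHS),
        long_plus=total("+", LONG_LENGTHS),
    )


def fold_change(mutant: SizeClassSummary, wt: SizeClassSummary) -> pd.DataFrame:
    """Elementwise mutant/wt ratios; wt == 0 is flagged, never dropped."""
    m, w = mutant.as_dict(), wt.as_dict()
    if m.keys() != w.keys():
        raise ValueError("size-class sets differ between mutant and wt")
    rows = []
    for (size_class, strand), wt_val in w.items():
        mut_val = m[(size_class, strand)]
        defined = wt_val > 0
        rows.append(
            {
                "genotype": mutant.label,
                "size_class": size_class,
                "strand": strand,
                "mutant": mut_val,
                "wt": wt_val,
                "mutant_over_wt": mut_val / wt_val if defined else math.nan,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def cluster_attribution(
    alignments: pd.DataFrame,
    annotations: AnnotationSet,
    telomeric_track: str = "telomeric_element",
) -> tuple[float, int, int]:
    """Fraction of telomeric-element reads that also touch the cluster.

    Returns (fraction, n_cluster_and_telomeric, n_telomeric); the
    fraction is NaN when no read overlaps a telomeric element.
    """
    cluster = annotations.cluster
    telomeric: set[str] = set()
    in_cluster: set[str] = set()
    for row in alignments.itertuples(index=False):
        if annotations.any_overlap(telomeric_track, row.chrom, row.start, row.end):
            telomeric.add(row.read_id)
        if GenomicInterval.overlaps(cluster, row.chrom, row.start, row.end):
            in_cluster.add(row.read_id)
    denom = len(telomeric)
    numer = len(telomeric & in_cluster)
    frac = numer / denom if denom else math.nan
    return frac, numer, denom


@dataclass
class PingPongResult:
    """5'-overlap histogram over opposite-strand pairs, plus a 10-nt z-score."""

    counts: dict[int, int]
    max_overlap: int = 30
    signature_overlap: int = 10

    @property
    def z_score(self) -> float:
        others = [
            self.counts.get(d, 0)
            for d in range(1, self.max_overlap + 1)
            if d != self.signature_overlap
        ]
        mu, sd = float(np.mean(others)), float(np.std(others, ddof=1))
        focal = self.counts.get(self.signature_overlap, 0)
        return (focal - mu) / sd if sd > 0 else math.nan

    @property
    def modal_overlap(self) -> int | None:
        if not any(self.counts.values()):
            return None
        return max(self.counts, key=lambda d: (self.counts[d], -d))


def ping_pong_signature(
    alignments: pd.DataFrame,
    region: GenomicInterval | None = None,
    max_overlap: int = 30,
) -> PingPongResult:
    """Histogram of 5'-to-5' overlaps between plus/minus alignment pairs.

    For a plus placement starting at ``p`` and a minus placement whose 5'
    end sits at ``q = end - 1``, the overlap is ``q - p + 1`` (inclusive,
    in plus-read coordinates).  Only overlaps in [1, max_overlap] are
    binned; pairs on different chromosomes never pair.  Counting is done
    per placement via position Counters, which is equivalent to the
    O(n^2) all-pairs enumeration.
    """
    counts = {d: 0 for d in range(1, max_overlap + 1)}
    if len(alignments):
        aln = alignments
        if region is not None:
            aln = aln[
                (aln["chrom"] == region.chrom)
                & (aln["start"] < region.end)
                & (aln["end"] > region.start)
            ]
        plus_5p: dict[str, Counter] = {}
        minus_5p: dict[str, Counter] = {}
        for row in aln.itertuples(index=False):
            if row.strand == "+":
                plus_5p.setdefault(row.chrom, Counter())[row.start] += 1
            else:
                minus_5p.setdefault(row.chrom, Counter())[row.end - 1] += 1
        for chrom, plus in plus_5p.items():
            minus = minus_5p.get(chrom)
            if not minus:
                continue
            for p, np_ in plus.items():
                for d in range(1, max_overlap + 1):
                    nm = minus.get(p + d - 1)
                    if nm:
                        counts[d] += np_ * nm
    return PingPongResult(counts, max_overlap=max_overlap)
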