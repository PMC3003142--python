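"""Cluster histograms, size classes, fold changes, attribution, ping-pong."""

import math

import numpy as np
import pandas as pd
import pytest

from telopirna.annotations import AnnotationSet, GenomicInterval
from telopirna.profiling import (
    LONG_LENGTHS,
    SHORT_LENGTHS,
    LengthHistogram,
    cluster_attribution,
    cluster_histogram,
    fold_change,
    ping_pong_signature,
    size_class_summary,
)

ALN_COLS = ["read_id", "chrom", "start", "end", "strand", "n_hits"]


def make_aln(rows):
    return pd.DataFrame(rows, columns=ALN_COLS)


@pytest.fixture
def cluster_ann():
    return AnnotationSet(cluster=GenomicInterval("chrA", 1000, 2000, ".", "cluster"))


class TestClusterHistogram:
    def test_normalization_arithmetic(self, cluster_ann):
        rows = [(f"r{i}", "chrA", 1100, 1125, "-", 1) for i in range(10)]
        hist = cluster_histogram(make_aln(rows), cluster_ann, depth=10**6)
        assert hist.normalized[("-", 25)] == pytest.approx(10.0)
        assert hist.raw[("-", 25)] == 10

    def test_no_cluster_reads_gives_all_zero(self, cluster_ann):
        rows = [("r0", "chrA", 10, 35, "+", 1)]
        hist = cluster_histogram(make_aln(rows), cluster_ann, depth=1)
        assert hist.total_reads() == 0

    def test_zero_depth_is_an_error(self, cluster_ann):
        with pytest.raises(ValueError, match="depth"):
            cluster_histogram(make_aln([]), cluster_ann, depth=0)

    def test_multimapper_counts_once_leftmost_strand(self, cluster_ann):
        rows = [
            ("r0", "chrA", 1500, 1525, "-", 2),
            ("r0", "chrA", 1200, 1225, "+", 2),
        ]
        hist = cluster_histogram(make_aln(rows), cluster_ann, depth=100)
        assert hist.raw[("+", 25)] == 1 and hist.raw[("-", 25)] == 0
        assert hist.ambiguous_strand_reads == 1

    def test_conservation_and_constant_ratio(self, cluster_ann):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(400):
            ln = int(rng.integers(18, 31))
            s = int(rng.integers(900, 2100))
            rows.append((f"r{i}", "chrA", s, s + ln, "-+"[i % 2], 1))
        aln = make_aln(rows)
        hist = cluster_histogram(aln, cluster_ann, depth=400)
        n_cluster_reads = aln[(aln.start < 2000) & (aln.end > 1000)][
            "read_id"
        ].nunique()
        # some reads near the edge may exceed max_len after slicing: none here
        assert hist.total_reads() == n_cluster_reads
        ratios = {
            hist.normalized[k] / v for k, v in hist.raw.items() if v > 0
        }
        assert all(math.isclose(r, 1e6 / 400) for r in ratios)

    def test_planted_wt_mixture_recovered(self, toy_genome, small_wt_library, toy_index):
        """Histogram matches ground-truth class counts within binomial noise,
        with the 21-nt peak on the minus strand."""
        from telopirna.mapping import filter_ncrna, map_inserts, mapped_depth
        from telopirna.trim import trim_library

        genome, ann = toy_genome
        spec, reads, truth = small_wt_library
        inserts, _ = trim_library(reads, spec.linker)
        aln, _ = map_inserts(inserts, toy_index)
        kept, _ = filter_ncrna(aln, ann)
        hist = cluster_histogram(kept, ann, depth=mapped_depth(kept))
        n21 = truth[truth["read_class"] == "endo_sirna_21"]
        # trimming loses ~1% of reads to coincidental linker 6-mers; the
        # planted count is a binomial mean, so allow 4 sigma + that loss
        expected = len(n21)
        sigma = math.sqrt(expected)
        assert abs(hist.raw[("-", 21)] - expected) < 4 * sigma + 0.02 * expected
        # 21-nt minus bin towers over neighbouring short minus bins
        assert hist.raw[("-", 21)] > hist.raw[("-", 20)]
        assert hist.raw[("-", 21)] > hist.raw[("-", 22)]


class TestSizeClasses:
    def make_hist(self, raw, depth=10**6):
        full = {(s, ln): 0 for s in "+-" for ln in range(18, 31)}
        full.update(raw)
        return LengthHistogram(18, 30, depth, full)

    def test_21nt_bin_is_excluded_from_short(self):
        hist = self.make_hist(
            {("-", 19): 5, ("-", 20): 5, ("-", 21): 100, ("-", 22): 5}
        )
        s = size_class_summary(hist)
        assert s.short_minus == pytest.approx(15.0)

    def test_all_zero(self):
        s = size_class_summary(self.make_hist({}))
        assert (s.short_minus, s.short_plus, s.long_minus, s.long_plus) == (0, 0, 0, 0)

    def test_classes_equal_brute_force_sums(self):
        rng = np.random.default_rng(11)
        raw = {
            (s, ln): int(rng.integers(0, 50))
            for s in "+-"
            for ln in range(18, 31)
        }
        hist = self.make_hist(raw, depth=12345)
        s = size_class_summary(hist)
        norm = hist.normalized
        assert s.short_minus == pytest.approx(
            sum(norm[("-", ln)] for ln in SHORT_LENGTHS)
        )
        assert s.long_plus == pytest.approx(
            sum(norm[("+", ln)] for ln in LONG_LENGTHS)
        )
        assert 21 not in SHORT_LENGTHS

    def test_histogram_must_cover_19_to_29(self):
        hist = LengthHistogram(23, 29, 10, {("+", ln): 0 for ln in range(23, 30)})
        with pytest.raises(ValueError):
            size_class_summary(hist)


class TestFoldChange:
    def make_summary(self, label, **kw):
        from telopirna.profiling import SizeClassSummary

        base = dict(short_minus=0.0, short_plus=0.0, long_minus=0.0, long_plus=0.0)
        base.update(kw)
        return SizeClassSummary(label=label, **base)

    def test_five_fold_reduction(self):
        fc = fold_change(
            self.make_summary("mut", short_minus=4.0),
            self.make_summary("wt", short_minus=20.0),
        )
        row = fc.set_index(["size_class", "strand"]).loc[("short", "-")]
        assert row["mutant_over_wt"] == pytest.approx(0.20)

    def test_identity(self):
        s = self.make_summary("x", short_minus=3, short_plus=2, long_minus=9, long_plus=4)
        fc = fold_change(s, s)
        assert (fc["mutant_over_wt"] == 1.0).all()

    def test_wt_zero_flagged_not_dropped(self):
        fc = fold_change(
            self.make_summary("mut", short_minus=4.0), self.make_summary("wt")
        )
        row = fc.set_index(["size_class", "strand"]).loc[("short", "-")]
        assert not row["defined"] and math.isnan(row["mutant_over_wt"])
        assert len(fc) == 4


class TestClusterAttribution:
    def test_all_fragments_inside_cluster_gives_one(self, tiny_annotations):
        rows = [(f"r{i}", "chrA", 160, 185, "-", 1) for i in range(5)]
        frac, n, d = cluster_attribution(make_aln(rows), tiny_annotations)
        assert frac == 1.0 and (n, d) == (5, 5)

    def test_no_telomeric_reads_is_undefined(self, tiny_annotations):
        frac, n, d = cluster_attribution(
            make_aln([("r0", "chrA", 600, 625, "+", 1)]), tiny_annotations
        )
        assert math.isnan(frac) and d == 0

    def test_off_cluster_fragment_share(self):
        ann = AnnotationSet(cluster=GenomicInterval("chrA", 0, 1000))
        ann.add("telomeric_element", GenomicInterval("chrA", 100, 400, "-", "in"))
        ann.add("telomeric_element", GenomicInterval("chrA", 5000, 5300, "-", "out"))
        rows = [(f"in{i}", "chrA", 150, 175, "-", 1) for i in range(75)]
        rows += [(f"out{i}", "chrA", 5100, 5125, "-", 1) for i in range(25)]
        frac, n, d = cluster_attribution(make_aln(rows), ann)
        assert frac == pytest.approx(0.75)

    def test_planted_quarter_off_cluster(self, toy_genome):
        """Generator route: 25% of telomeric reads planted off-cluster."""
        from telopirna.mapping import map_inserts
        from telopirna.simulate import LibrarySpec, generate_library
        from telopirna.trim import trim_library

        genome, ann = toy_genome
        weights = {f.name: 0.0 for f in ann.tracks["telomeric_element"]}
        in_cluster = [n for n in weights if n != "HeTA_offcluster"]
        for n in in_cluster:
            weights[n] = 0.75 / len(in_cluster)
        weights["HeTA_offcluster"] = 0.25
        spec = LibrarySpec(
            genotype_label="attr",
            n_reads=8000,
            class_weights={"pirna_minus_23_29": 1.0},
            fragment_weights=weights,
            seed=21,
        )
        reads, truth = generate_library(genome, ann, spec)
        inserts, _ = trim_library(reads, spec.linker)
        aln, _ = map_inserts(inserts, genome)
        frac, n, d = cluster_attribution(aln, ann)
        assert frac == pytest.approx(0.75, abs=0.03)


def oracle_ping_pong(aln: pd.DataFrame, max_overlap=30):
    """O(n^2) all-pairs 5'-overlap enumeration."""
    counts = {d: 0 for d in range(1, max_overlap + 1)}
    plus = aln[aln.strand == "+"]
    minus = aln[aln.strand == "-"]
    for p in plus.itertuples(index=False):
        for m in minus.itertuples(index=False):
            if p.chrom != m.chrom:
                continue
            d = (m.end - 1) - p.start + 1
            if 1 <= d <= max_overlap:
                counts[d] += 1
    return counts


class TestPingPong:
    def test_single_pair_overlap_16(self):
        rows = [("p", "chrA", 100, 125, "+", 1), ("m", "chrA", 91, 116, "-", 1)]
        res = ping_pong_signature(make_aln(rows))
        assert res.counts[16] == 1 and sum(res.counts.values()) == 1

    def test_opposite_chromosomes_never_pair(self):
        rows = [("p", "chrA", 100, 125, "+", 1), ("m", "chrB", 91, 116, "-", 1)]
        res = ping_pong_signature(make_aln(rows))
        assert sum(res.counts.values()) == 0

    def test_agrees_with_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        rows = []
        for i in range(500):
            s = int(rng.integers(0, 3000))
            ln = int(rng.integers(19, 30))
            rows.append(
                (f"r{i}", "chrA" if rng.random() < 0.8 else "chrB",
                 s, s + ln, "+" if rng.random() < 0.5 else "-", 1)
            )
        aln = make_aln(rows)
        assert ping_pong_signature(aln).counts == oracle_ping_pong(aln)

    def test_planted_10nt_pairs_are_modal(self, toy_genome):
        from telopirna.mapping import map_inserts
        from telopirna.simulate import LibrarySpec, generate_library
        from telopirna.trim import trim_library

        genome, ann = toy_genome
        spec = LibrarySpec(
            genotype_label="pp",
            n_reads=2000,
            class_weights={"pirna_minus_23_29": 0.5, "pirna_plus_23_29": 0.5},
            n_ping_pong_pairs=400,
            seed=23,
        )
        reads, _ = generate_library(genome, ann, spec)
        inserts, _ = trim_library(reads, spec.linker)
        aln, _ = map_inserts(inserts, genome)
        res = ping_pong_signature(aln, region=ann.cluster)
        assert res.modal_overlap == 10
        assert res.z_score > 3
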