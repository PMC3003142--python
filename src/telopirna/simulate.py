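"""Synthetic data with the statistical structure the analysis assumes.

The generator builds a toy genome carrying one "chromosome-4-like"
piRNA cluster whose telomeric-transposon fragments all sit on the minus
genomic strand, then samples genotype-specific small-RNA libraries as
mixtures of read classes:

* ``pirna_minus_23_29`` / ``pirna_plus_23_29`` — canonical-length
  piRNAs from the cluster, minus-strand reads drawn from the transposon
  fragments (the elements' sense strand) and plus-strand reads from the
  cluster span;
* ``endo_sirna_21`` — the sharp 21-nt minus-strand endo-siRNA peak;
* ``short_minus_19_22`` — the short minus-strand species whose
  abundance is genotype-dependent (strongly depleted in aub/armi-like
  genotypes, near wild type in rhi/ago3-like ones).  Its length support
  is {19, 20, 22}: 21 nt is reserved for the siRNA class;
* ``background_offcluster`` — genome-mapping reads outside the cluster;
* ``unmatched_junk`` — reads that never contain the linker's leading
  6-mer and are therefore discarded at trimming.

Every read is a genome-derived insert with the 3'-linker appended and
truncated to the read length; a ground-truth table (class, origin,
strand) is always produced alongside, so recovery tests compare against
planted truth rather than reverse-engineering outputs.  Reads carry no
sequencing errors by default (mapping downstream is exact-match only);
an error-rate knob exists.

qPCR plates and per-embryo anaphase/telophase bridge-count tables are
generated with the same ground-truth-first discipline.  All generators
are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotations import AnnotationSet, GenomicInterval
from .mapping import revcomp

__all__ = [
    "READ_CLASSES",
    "DEFAULT_LINKER",
    "DEFAULT_LENGTH_DISTRIBUTIONS",
    "DEFAULT_CLASS_WEIGHTS",
    "SyntheticGenomeSpec",
    "LibrarySpec",
    "default_genome_spec",
    "wt_library_spec",
    "depleted_spec",
    "generate_genome",
    "generate_library",
    "generate_qpcr_plate",
    "generate_embryo_counts",
    "write_fastq",
    "spec_to_yaml",
    "library_spec_from_dict",
    "genome_spec_from_dict",
]

READ_CLASSES = (
    "pirna_minus_23_29",
    "pirna_plus_23_29",
    "endo_sirna_21",
    "short_minus_19_22",
    "background_offcluster",
    "unmatched_junk",
)

#: fixed arbitrary 3'-linker; only its first 6-mer matters for trimming
DEFAULT_LINKER = "CTGTAGGCACCATCAATCGT"

DEFAULT_LENGTH_DISTRIBUTIONS: dict[str, dict[int, float]] = {
    "pirna_minus_23_29": {23: 0.08, 24: 0.16, 25: 0.28, 26: 0.24, 27: 0.14, 28: 0.07, 29: 0.03},
    "pirna_plus_23_29": {23: 0.08, 24: 0.16, 25: 0.28, 26: 0.24, 27: 0.14, 28: 0.07, 29: 0.03},
    "endo_sirna_21": {21: 1.0},
    "short_minus_19_22": {19: 0.30, 20: 0.40, 22: 0.30},
    "background_offcluster": {n: 1 / 11 for n in range(19, 30)},
    "unmatched_junk": {n: 0.25 for n in range(24, 28)},
}

#: wild-type mixture; mutants are derived from it by class depletion
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "pirna_minus_23_29": 0.30,
    "pirna_plus_23_29": 0.18,
    "endo_sirna_21": 0.10,
    "short_minus_19_22": 0.20,
    "background_offcluster": 0.17,
    "unmatched_junk": 0.05,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class SyntheticGenomeSpec:
    """Layout of the toy genome: chromosomes, cluster, fragments, ncRNAs."""

    chromosome_lengths: dict[str, int]
    cluster: tuple[str, int, int]
    element_fragments: list[tuple[str, str, int, int, str]]
    ncrna_intervals: list[tuple[str, int, int]]
    seed: int = 0

    def validate(self) -> None:
        chrom, start, end = self.cluster
        intervals = [("cluster", chrom, start, end)] + [
            (name, c, s, e) for name, c, s, e, _ in self.element_fragments
        ] + [("ncrna", c, s, e) for c, s, e in self.ncrna_intervals]
        for name, c, s, e in intervals:
            if c not in self.chromosome_lengths:
                raise ValueError(f"{name}: unknown chromosome {c!r}")
            if not (0 <= s < e <= self.chromosome_lengths[c]):
                raise ValueError(
                    f"{name}: interval {c}:{s}-{e} outside chromosome bounds"
                )


@dataclass
class LibrarySpec:
    """Mixture definition for one genotype's small-RNA library."""

    genotype_label: str
    n_reads: int
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    linker: str = DEFAULT_LINKER
    length_distributions: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            c: dict(d) for c, d in DEFAULT_LENGTH_DISTRIBUTIONS.items()
        }
    )
    seed: int = 0
    read_length: int = 36
    error_rate: float = 0.0
    fragment_weights: dict[str, float] | None = None
    n_ping_pong_pairs: int = 0

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if len(self.linker) < 6:
            raise ValueError("linker must be at least 6 nt")
        unknown = set(self.class_weights) - set(READ_CLASSES)
        if unknown:
            raise ValueError(f"unknown read classes {sorted(unknown)}")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class weights sum to {total!r}, not 1")
        if any(w < 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be non-negative")
        for cls, dist in self.length_distributions.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"length distribution for {cls} does not sum to 1")
        short = set(self.length_distributions.get("short_minus_19_22", {19: 1}))
        if not short <= {19, 20, 22}:
            raise ValueError(
                "short_minus_19_22 support must be within {19,20,22}; "
                "21 nt is reserved for the endo-siRNA class"
            )
        for cls in ("pirna_minus_23_29", "pirna_plus_23_29"):
            support = set(self.length_distributions.get(cls, {23: 1}))
            if not support <= set(range(23, 30)):
                raise ValueError(f"{cls} length support must lie within [23, 29]")


def default_genome_spec(seed: int = 0) -> SyntheticGenomeSpec:
    """100-kb cluster chromosome (71-kb cluster span, mirroring the real
    4th-chromosome span's size) plus a 50-kb background chromosome.

    Six minus-strand telomeric-element fragments sit inside the cluster
    and one diverged fragment sits outside it, so cluster-attribution
    behaviour is exercised by default.
    """
    frag = [
        ("HeTA_frag1", "chr4sim", 12_000, 16_000, "-"),
        ("HeTA_frag2", "chr4sim", 21_000, 24_500, "-"),
        ("TART_frag1", "chr4sim", 30_000, 34_000, "-"),
        ("HeTA_frag3", "chr4sim", 43_000, 47_500, "-"),
        ("TART_frag2", "chr4sim", 55_000, 58_000, "-"),
        ("HeTA_frag4", "chr4sim", 66_000, 70_000, "-"),
        ("HeTA_offcluster", "chr4sim", 85_000, 88_000, "-"),
    ]
    ncrna = [
        ("chr2sim", 5_000, 5_200),
        ("chr2sim", 20_000, 20_150),
        ("chr4sim", 92_000, 92_120),
    ]
    return SyntheticGenomeSpec(
        chromosome_lengths={"chr4sim": 100_000, "chr2sim": 50_000},
        cluster=("chr4sim", 10_000, 81_000),
        element_fragments=frag,
        ncrna_intervals=ncrna,
        seed=seed,
    )


def wt_library_spec(n_reads: int, seed: int = 0, label: str = "wt") -> LibrarySpec:
    return LibrarySpec(genotype_label=label, n_reads=n_reads, seed=seed)


def depleted_spec(
    base: LibrarySpec,
    factors: Mapping[str, float],
    label: str,
    seed: int | None = None,
) -> LibrarySpec:
    """Derive a mutant spec by dividing class weights by planted factors.

    The removed probability mass moves into ``background_offcluster``,
    so the mapped-depth fraction — and with it the expected normalized
    fold change, which then equals exactly 1/factor — is preserved.
    """
    weights = dict(base.class_weights)
    freed = 0.0
    for cls, f in factors.items():
        if f < 1:
            raise ValueError("depletion factors must be >= 1")
        freed += weights[cls] * (1 - 1 / f)
        weights[cls] = weights[cls] / f
    weights["background_offcluster"] += freed
    return replace(
        base,
        genotype_label=label,
        class_weights=weights,
        seed=base.seed if seed is None else seed,
    )


# -- genome --------------------------------------------------------------

def generate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, str], AnnotationSet]:
    """Random genome plus annotation tracks; deterministic per seed.

    Element fragments are annotated on the minus strand (their sense
    strand), so minus-strand reads sampled from them are the elements'
    sense-strand RNAs.  Fragments are independent random sequence —
    diverged copies rather than literal repeats — so each read has one
    true origin.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genome = {
        name: "".join(rng.choice(_BASES, size=length))
        for name, length in spec.chromosome_lengths.items()
    }
    chrom, start, end = spec.cluster
    ann = AnnotationSet(cluster=GenomicInterval(chrom, start, end, ".", "cluster"))
    for name, c, s, e, strand in spec.element_fragments:
        if strand != "-":
            raise ValueError(
                f"element fragment {name} must be annotated on the minus strand"
            )
        ann.add("telomeric_element", GenomicInterval(c, s, e, strand, name))
    for c, s, e in spec.ncrna_intervals:
        ann.add("ncrna", GenomicInterval(c, s, e, ".", "ncrna"))
    ann.validate_against(spec.chromosome_lengths)
    return genome, ann


# -- library -------------------------------------------------------------

def _choose_weighted(rng: np.random.Generator, items: Sequence, weights: Sequence[float]):
    p = np.asarray(weights, dtype=float)
    return items[int(rng.choice(len(items), p=p / p.sum()))]


def _sample_length(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lengths = sorted(dist)
    return int(_choose_weighted(rng, lengths, [dist[l] for l in lengths]))


def _random_junk(rng: np.random.Generator, length: int, banned: str) -> str:
    while True:
        seq = "".join(rng.choice(_BASES, size=length))
        if banned not in seq:
            return seq


def generate_library(
    genome: dict[str, str],
    annotations: AnnotationSet,
    spec: LibrarySpec,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample one library; returns (reads, ground-truth table).

    Reads are (read_id, sequence) with the linker appended and the
    whole thing truncated to ``spec.read_length``.  Truth columns:
    read_id, read_class, chrom, start, end, strand, insert_len
    (off-genome junk reads carry chrom="*" and -1 coordinates).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cluster = annotations.cluster
    fragments = annotations.tracks.get("telomeric_element", [])
    cluster_frags = [
        f for f in fragments
        if f.overlaps(cluster.chrom, cluster.start, cluster.end)
    ]
    if spec.fragment_weights is None:
        frag_pool = cluster_frags
        frag_w = [len(f) for f in frag_pool]
    else:
        by_name = {f.name: f for f in fragments}
        missing = set(spec.fragment_weights) - set(by_name)
        if missing:
            raise ValueError(f"fragment_weights name unknown fragments {sorted(missing)}")
        frag_pool = [by_name[n] for n in sorted(spec.fragment_weights)]
        frag_w = [spec.fragment_weights[f.name] for f in frag_pool]

    on_cluster_minus = {"pirna_minus_23_29", "endo_sirna_21", "short_minus_19_22"}
    if any(spec.class_weights.get(c, 0) > 0 for c in on_cluster_minus | {"pirna_plus_23_29"}):
        if not frag_pool:
            raise ValueError("on-cluster read classes need cluster element fragments")

    chrom_names = sorted(genome)
    chrom_w = [len(genome[c]) for c in chrom_names]
    linker6 = spec.linker[:6].upper()

    classes = list(spec.class_weights)
    draws = rng.choice(
        len(classes), size=spec.n_reads,
        p=np.asarray([spec.class_weights[c] for c in classes]),
    )

    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    def emit(read_id: str, read_class: str, chrom: str, start: int, end: int,
             strand: str, insert: str) -> None:
        seq = (insert + spec.linker.upper())[: spec.read_length]
        if spec.error_rate > 0:
            chars = list(seq)
            for i in range(len(chars)):
                if rng.random() < spec.error_rate:
                    chars[i] = str(rng.choice(_BASES))
            seq = "".join(chars)
        reads.append((read_id, seq))
        truth_rows.append(
            {
                "read_id": read_id,
                "read_class": read_class,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "insert_len": len(insert),
            }
        )

    def sample_fragment_insert(length: int) -> tuple[str, int, int, str]:
        frag = _choose_weighted(rng, frag_pool, frag_w)
        if length > len(frag):
            raise ValueError(
                f"insert of {length} nt exceeds fragment {frag.name} "
                f"({len(frag)} nt)"
            )
        start = int(rng.integers(frag.start, frag.end - length + 1))
        return frag.chrom, start, start + length, "-"

    for i, cls_idx in enumerate(draws):
        cls = classes[int(cls_idx)]
        read_id = f"{spec.genotype_label}_{i:07d}"
        length = _sample_length(rng, spec.length_distributions[cls])
        if cls in on_cluster_minus:
            chrom, s, e, strand = sample_fragment_insert(length)
            insert = revcomp(genome[chrom][s:e])
        elif cls == "pirna_plus_23_29":
            chrom = cluster.chrom
            s = int(rng.integers(cluster.start, cluster.end - length + 1))
            e, strand = s + length, "+"
            insert = genome[chrom][s:e]
        elif cls == "background_offcluster":
            while True:
                chrom = _choose_weighted(rng, chrom_names, chrom_w)
                s = int(rng.integers(0, len(genome[chrom]) - length + 1))
                e = s + length
                if not cluster.overlaps(chrom, s, e):
                    break
            strand = "+" if rng.random() < 0.5 else "-"
            insert = genome[chrom][s:e]
            if strand == "-":
                insert = revcomp(insert)
        else:  # unmatched_junk: whole read avoids the linker 6-mer
            seq = _random_junk(rng, spec.read_length, linker6)
            reads.append((read_id, seq))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "read_class": cls,
                    "chrom": "*",
                    "start": -1,
                    "end": -1,
                    "strand": ".",
                    "insert_len": -1,
                }
            )
            continue
        emit(read_id, cls, chrom, s, e, strand, insert)

    # forced ping-pong pairs: plus partner 5' end 10 nt into the minus read
    pp_minus_dist = spec.length_distributions["pirna_minus_23_29"]
    pp_plus_dist = spec.length_distributions["pirna_plus_23_29"]
    for j in range(spec.n_ping_pong_pairs):
        m_len = _sample_length(rng, pp_minus_dist)
        chrom, ms, me, _ = sample_fragment_insert(m_len)
        emit(f"{spec.genotype_label}_pp{j:05d}_m", "ping_pong_minus",
             chrom, ms, me, "-", revcomp(genome[chrom][ms:me]))
        p_len = _sample_length(rng, pp_plus_dist)
        ps = me - 10  # plus 5' end overlaps the minus 5' end by exactly 10
        pe = min(ps + p_len, len(genome[chrom]))
        emit(f"{spec.genotype_label}_pp{j:05d}_p", "ping_pong_plus",
             chrom, ps, pe, "+", genome[chrom][ps:pe])

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "read_class", "chrom", "start", "end", "strand", "insert_len"],
    )
    return reads, truth


# -- qPCR ----------------------------------------------------------------

def generate_qpcr_plate(
    quantities: pd.DataFrame,
    efficiencies: Mapping[str, float],
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    intercept: float = 20.0,
    n_dilutions: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Ct measurements plus per-primer ten-fold dilution series.

    *quantities* has columns (sample, primer_pair, role, quantity) with
    quantities on an arbitrary common scale (reference quantity 1 maps
    to ``intercept`` cycles): ``Ct = intercept + log_E(1/q) + noise``.
    The dilution series spans ``n_dilutions`` ten-fold points (>= 4).
    Returns (ct_table, dilution_table).
    """
    required = {"sample", "primer_pair", "role", "quantity"}
    if not required <= set(quantities.columns):
        raise ValueError(f"quantities table needs columns {sorted(required)}")
    if (quantities["quantity"] <= 0).any():
        raise ValueError("quantities must be positive")
    if n_dilutions < 4:
        raise ValueError("dilution series needs >= 4 ten-fold points")
    for primer, eff in efficiencies.items():
        if not 1 < eff <= 2:
            raise ValueError(f"efficiency for {primer} must be in (1, 2], got {eff}")
    rng = np.random.default_rng(seed)

    ct_rows = []
    for row in quantities.itertuples(index=False):
        eff = efficiencies[row.primer_pair]
        true_ct = intercept - math.log(row.quantity) / math.log(eff)
        for rep in range(1, n_replicates + 1):
            ct_rows.append(
                {
                    "sample": row.sample,
                    "primer_pair": row.primer_pair,
                    "role": row.role,
                    "replicate": rep,
                    "ct": true_ct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                }
            )

    dil_rows = []
    for primer in sorted(efficiencies):
        eff = efficiencies[primer]
        for step in range(n_dilutions):
            log10_dil = -float(step)
            true_ct = intercept - (log10_dil * math.log(10) / math.log(eff))
            for rep in range(1, n_replicates + 1):
                dil_rows.append(
                    {
                        "primer_pair": primer,
                        "log10_dilution": log10_dil,
                        "replicate": rep,
                        "ct": true_ct
                        + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                    }
                )
    return pd.DataFrame(ct_rows), pd.DataFrame(dil_rows)


# -- embryo counts -------------------------------------------------------

def generate_embryo_counts(
    genotype_probs: Mapping[str, float],
    n_embryos: int = 20,
    figures_per_embryo: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomially sampled per-embryo bridged/total A/T figure counts."""
    if not 10 <= n_embryos <= 30:
        raise ValueError("n_embryos must be between 10 and 30")
    if figures_per_embryo < 1:
        raise ValueError("figures_per_embryo must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, p in genotype_probs.items():
        if not 0 <= p <= 1:
            raise ValueError(f"bridge probability for {genotype} not in [0, 1]")
        bridged = rng.binomial(figures_per_embryo, p, size=n_embryos)
        for i, b in enumerate(bridged):
            rows.append(
                {
                    "genotype": genotype,
                    "embryo_id": f"{genotype}_e{i:02d}",
                    "bridged": int(b),
                    "total": figures_per_embryo,
                }
            )
    return pd.DataFrame(rows)


# -- I/O and config ------------------------------------------------------

def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Phred+33 FASTQ with uniform dummy qualities."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def spec_to_yaml(
    genome_spec: SyntheticGenomeSpec,
    library_specs: Sequence[LibrarySpec],
    path: str | Path,
) -> None:
    payload = {
        "genome": asdict(genome_spec),
        "libraries": [asdict(s) for s in library_specs],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def genome_spec_from_dict(d: Mapping) -> SyntheticGenomeSpec:
    return SyntheticGenomeSpec(
        chromosome_lengths=dict(d["chromosome_lengths"]),
        cluster=tuple(d["cluster"]),
        element_fragments=[tuple(f) for f in d["element_fragments"]],
        ncrna_intervals=[tuple(iv) for iv in d["ncrna_intervals"]],
        seed=int(d.get("seed", 0)),
    )


def library_spec_from_dict(d: Mapping) -> LibrarySpec:
    kwargs = dict(d)
    if "length_distributions" in kwargs:
        kwargs["length_distributions"] = {
            cls: {int(k): float(v) for k, v in dist.items()}
            for cls, dist in kwargs["length_distributions"].items()
        }
    return LibrarySpec(**kwargs)
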