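"""End-to-end orchestration: trim -> map -> ncRNA filter -> cluster profile.

A single :class:`RunConfig` names the genome, the annotation BED, one
FASTQ per genotype (one of which is the designated wild type), and the
trimming/mapping knobs.  :func:`run_pipeline` executes every stage for
every library, writes tidy per-stage CSVs plus a JSON manifest with
input hashes, seeds and the read-conservation ledger, and returns the
in-memory results.  Re-running an identical config reproduces identical
outputs (the manifest timestamp aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotations import AnnotationSet, parse_region, read_bed6
from .mapping import (
    GenomeIndex,
    filter_ncrna,
    map_inserts,
    mapped_depth,
    read_genome_fasta,
    write_alignments_tsv,
)
from .profiling import (
    LengthHistogram,
    SizeClassSummary,
    cluster_attribution,
    cluster_histogram,
    fold_change,
    ping_pong_signature,
    size_class_summary,
)
from .trim import read_sequences, trim_library

__all__ = ["RunConfig", "LibraryResult", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    genome_fasta: str
    annotations_bed: str
    libraries: dict[str, str]  # genotype label -> FASTQ/FASTA path
    wt_label: str = "wt"
    linker: str = ""
    min_len: int = 18
    max_len: int = 30
    cluster: str = ""  # optional region override, 1-based inclusive
    chrom_blocklist: list[str] = field(default_factory=list)
    max_hits: int | None = None
    output_dir: str = "results"
    write_alignments: bool = False

    def validate(self) -> None:
        if not self.libraries:
            raise ValueError("no libraries configured")
        if self.wt_label not in self.libraries:
            raise ValueError(
                f"wild-type label {self.wt_label!r} not among libraries "
                f"{sorted(self.libraries)}"
            )
        if not self.linker or len(self.linker) < 6:
            raise ValueError("a linker of >= 6 nt is required")
        if self.cluster:
            parse_region(self.cluster)  # raises if malformed
        for label, path in self.libraries.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"library {label!r}: missing file {path}")
        for path in (self.genome_fasta, self.annotations_bed):
            if not Path(path).exists():
                raise FileNotFoundError(f"missing input file {path}")


@dataclass
class LibraryResult:
    label: str
    histogram: LengthHistogram
    summary: SizeClassSummary
    depth: int
    conservation: dict[str, int]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return RunConfig(**payload)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every configured library; see module docstring."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome = read_genome_fasta(config.genome_fasta)
    annotations = read_bed6(config.annotations_bed)
    if config.cluster:
        override = parse_region(config.cluster)
        annotations = AnnotationSet(tracks=annotations.tracks, cluster=override)
    index = GenomeIndex(
        {c: s for c, s in genome.items() if c not in set(config.chrom_blocklist)}
    )

    results: dict[str, LibraryResult] = {}
    hist_frames = []
    pingpong: dict[str, dict] = {}
    attribution: dict[str, dict] = {}
    for label, fastq in config.libraries.items():
        inserts, trim_report = trim_library(
            read_sequences(fastq), config.linker, config.min_len, config.max_len
        )
        alignments, map_report = map_inserts(
            inserts, index, max_hits=config.max_hits
        )
        filtered, removed = filter_ncrna(alignments, annotations)
        depth = mapped_depth(filtered)
        hist = cluster_histogram(
            filtered, annotations, config.min_len, config.max_len, depth=depth
        )
        summary = size_class_summary(hist, label=label)
        conservation = {
            "reads_in": trim_report.reads_in,
            "inserts_out": trim_report.inserts_out,
            "discarded_no_linker": trim_report.discarded_no_linker,
            "discarded_length": trim_report.discarded_length,
            "mapped_reads": map_report.mapped_reads,
            "unmapped": map_report.unmapped,
            "capped": map_report.capped,
            "ncrna_removed": len(removed),
            "depth": depth,
        }
        if trim_report.inserts_out != map_report.inserts_in:
            raise AssertionError(f"{label}: trim/map ledger mismatch")
        results[label] = LibraryResult(label, hist, summary, depth, conservation)
        hist_frames.append(hist.to_frame(label))
        pp = ping_pong_signature(filtered, region=annotations.cluster)
        pingpong[label] = {
            "modal_overlap": pp.modal_overlap,
            "z10": None if pd.isna(pp.z_score) else pp.z_score,
            "counts": {str(k): v for k, v in pp.counts.items()},
        }
        frac, numer, denom = cluster_attribution(filtered, annotations)
        attribution[label] = {
            "fraction": None if pd.isna(frac) else frac,
            "cluster_and_telomeric": numer,
            "telomeric": denom,
        }
        if config.write_alignments:
            write_alignments_tsv(filtered, out_dir / f"alignments_{label}.tsv")

    pd.concat(hist_frames, ignore_index=True).to_csv(
        out_dir / "length_histograms.csv", index=False
    )
    fold_frames = [
        fold_change(results[label].summary, results[config.wt_label].summary)
        for label in config.libraries
        if label != config.wt_label
    ]
    folds = (
        pd.concat(fold_frames, ignore_index=True) if fold_frames else pd.DataFrame()
    )
    folds.to_csv(out_dir / "size_class_fold_change.csv", index=False)
    with open(out_dir / "ping_pong.json", "w") as fh:
        json.dump(pingpong, fh, indent=2)
    with open(out_dir / "cluster_attribution.json", "w") as fh:
        json.dump(attribution, fh, indent=2)

    manifest = {
        "telopirna_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        "input_hashes": {
            "genome": _sha256(config.genome_fasta),
            "annotations": _sha256(config.annotations_bed),
            **{label: _sha256(p) for label, p in config.libraries.items()},
        },
        "conservation": {label: r.conservation for label, r in results.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "libraries": results,
        "fold_change": folds,
        "ping_pong": pingpong,
        "attribution": attribution,
        "manifest": manifest,
    }
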