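"""Canned study-condition experiments over planted synthetic truth.

Each function wires the generator to the pipeline under the fixed study
conditions the package emulates and returns tidy results:

* genotype-specific libraries over the default toy genome, with
  aub/armi-like short-RNA depletion or the rhi/ago3-like dissociation
  (long piRNA classes depleted, the short minus-strand class near wild
  type) planted at known factors;
* cluster attribution with a quarter of telomeric-element reads planted
  on an off-cluster fragment (emulating the reported 70-80% regime);
* forced 10-nt ping-pong pairs;
* qPCR efficiency / percent-input / copy-number recovery;
* per-embryo bridge-count contrasts at the reported 50% vs 15% regime.

All randomness descends from one integer seed per experiment.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cytology import summarize_bridges
from .mapping import GenomeIndex, filter_ncrna, map_inserts, mapped_depth
from .profiling import (
    cluster_attribution,
    cluster_histogram,
    fold_change,
    ping_pong_signature,
    size_class_summary,
)
from .qpcr import copy_number, fit_efficiency, percent_input
from .simulate import (
    LibrarySpec,
    default_genome_spec,
    depleted_spec,
    generate_embryo_counts,
    generate_genome,
    generate_library,
    generate_qpcr_plate,
    wt_library_spec,
)
from .trim import trim_library

__all__ = [
    "RHI_LIKE_FACTORS",
    "profile_library",
    "run_depletion_experiment",
    "run_attribution_experiment",
    "run_pingpong_experiment",
    "run_efficiency_recovery",
    "run_copy_number_recovery",
    "run_bridge_experiment",
    "bridge_power",
]

#: planted rhi/ago3-like condition: both long piRNA classes depleted
#: (minus 2.5x, plus 5x) while the short minus class sits at 90% of wt
RHI_LIKE_FACTORS = {
    "pirna_minus_23_29": 2.5,
    "pirna_plus_23_29": 5.0,
    "short_minus_19_22": 1 / 0.9,
}


def profile_library(genome, annotations, index: GenomeIndex, spec: LibrarySpec):
    """trim -> map -> ncRNA filter -> cluster profile for one library."""
    reads, truth = generate_library(genome, annotations, spec)
    inserts, trim_report = trim_library(reads, spec.linker)
    alignments, map_report = map_inserts(inserts, index)
    filtered, _ = filter_ncrna(alignments, annotations)
    depth = mapped_depth(filtered)
    hist = cluster_histogram(filtered, annotations, depth=depth)
    summary = size_class_summary(hist, label=spec.genotype_label)
    return {
        "spec": spec,
        "truth": truth,
        "alignments": filtered,
        "depth": depth,
        "histogram": hist,
        "summary": summary,
        "trim_report": trim_report,
        "map_report": map_report,
    }


def run_depletion_experiment(
    factors: tuple[float, ...] = (2, 5, 10),
    n_reads: int = 200_000,
    seed: int = 0,
    include_rhi_like: bool = True,
) -> pd.DataFrame:
    """Recover planted short-RNA depletions from wt/mutant library pairs.

    Returns one row per (genotype, size_class, strand) with the planted
    and recovered mutant/wt ratios.  Mutant genotypes: ``depleted_fX``
    with the short minus class divided by X (aub/armi-like), plus a
    ``rhi_like`` genotype under :data:`RHI_LIKE_FACTORS`.
    """
    genome, ann = generate_genome(default_genome_spec(seed=seed))
    index = GenomeIndex(genome)
    wt_spec = wt_library_spec(n_reads, seed=seed + 1)
    wt = profile_library(genome, ann, index, wt_spec)

    conditions: list[tuple[str, dict[str, float]]] = [
        (f"depleted_f{f:g}", {"short_minus_19_22": float(f)}) for f in factors
    ]
    if include_rhi_like:
        conditions.append(("rhi_like", dict(RHI_LIKE_FACTORS)))

    frames = []
    for offset, (label, planted) in enumerate(conditions, start=2):
        spec = depleted_spec(wt_spec, planted, label, seed=seed + offset)
        mut = profile_library(genome, ann, index, spec)
        fc = fold_change(mut["summary"], wt["summary"])
        fc["planted_ratio"] = [
            1.0
            / planted.get(
                {
                    ("short", "-"): "short_minus_19_22",
                    ("long", "-"): "pirna_minus_23_29",
                    ("long", "+"): "pirna_plus_23_29",
                }.get((row.size_class, row.strand), "_none"),
                1.0,
            )
            for row in fc.itertuples()
        ]
        frames.append(fc)
    return pd.concat(frames, ignore_index=True)


def run_attribution_experiment(
    n_reads: int = 50_000,
    off_cluster_share: float = 0.25,
    seed: int = 0,
) -> dict:
    """Cluster attribution with a planted off-cluster telomeric fragment."""
    genome, ann = generate_genome(default_genome_spec(seed=seed))
    weights: dict[str, float] = {}
    in_cluster = [
        f.name
        for f in ann.tracks["telomeric_element"]
        if f.overlaps(ann.cluster.chrom, ann.cluster.start, ann.cluster.end)
    ]
    off_cluster = [
        f.name for f in ann.tracks["telomeric_element"] if f.name not in in_cluster
    ]
    for name in in_cluster:
        weights[name] = (1 - off_cluster_share) / len(in_cluster)
    for name in off_cluster:
        weights[name] = off_cluster_share / len(off_cluster)
    spec = LibrarySpec(
        genotype_label="attribution",
        n_reads=n_reads,
        class_weights={"pirna_minus_23_29": 0.7, "short_minus_19_22": 0.3},
        fragment_weights=weights,
        seed=seed + 1,
    )
    reads, _ = generate_library(genome, ann, spec)
    inserts, _ = trim_library(reads, spec.linker)
    alignments, _ = map_inserts(inserts, GenomeIndex(genome))
    filtered, _ = filter_ncrna(alignments, ann)
    frac, numer, denom = cluster_attribution(filtered, ann)
    return {
        "fraction": frac,
        "planted": 1 - off_cluster_share,
        "n_cluster_and_telomeric": numer,
        "n_telomeric": denom,
    }


def run_pingpong_experiment(
    n_pairs: int = 2_000, n_background: int = 10_000, seed: int = 0
) -> dict:
    """Plant forced 10-nt 5'-overlap pairs and measure the signature."""
    genome, ann = generate_genome(default_genome_spec(seed=seed))
    spec = LibrarySpec(
        genotype_label="pingpong",
        n_reads=n_background,
        class_weights={"pirna_minus_23_29": 0.5, "pirna_plus_23_29": 0.5},
        n_ping_pong_pairs=n_pairs,
        seed=seed + 1,
    )
    reads, _ = generate_library(genome, ann, spec)
    inserts, _ = trim_library(reads, spec.linker)
    alignments, _ = map_inserts(inserts, GenomeIndex(genome))
    result = ping_pong_signature(alignments, region=ann.cluster)
    return {
        "modal_overlap": result.modal_overlap,
        "z10": result.z_score,
        "counts": result.counts,
    }


def run_efficiency_recovery(
    true_efficiency: float = 1.9,
    noise_sd: float = 0.1,
    n_plates: int = 100,
    seed: int = 0,
) -> dict:
    """Mean standard-curve efficiency recovery error over simulated plates."""
    quantities = pd.DataFrame(
        [{"sample": "s", "primer_pair": "p", "role": "target", "quantity": 1.0}]
    )
    estimates = []
    for k in range(n_plates):
        _, dilution = generate_qpcr_plate(
            quantities, {"p": true_efficiency}, noise_sd=noise_sd, seed=seed + k
        )
        estimates.append(fit_efficiency(dilution, "p").efficiency)
    estimates = np.asarray(estimates)
    return {
        "true_efficiency": true_efficiency,
        "mean_estimate": float(estimates.mean()),
        "mean_relative_error": float(
            abs(estimates.mean() - true_efficiency) / true_efficiency
        ),
        "n_plates": n_plates,
    }


def run_copy_number_recovery(
    planted_fold: float = 12.0,
    noise_sd: float = 0.1,
    n_plates: int = 10,
    seed: int = 0,
) -> dict:
    """Geometric-mean recovery of a planted element copy excess vs control."""
    quantities = pd.DataFrame(
        [
            {"sample": "excess", "primer_pair": "HeTA", "role": "target", "quantity": planted_fold},
            {"sample": "control", "primer_pair": "HeTA", "role": "target", "quantity": 1.0},
            {"sample": "excess", "primer_pair": "Rp49", "role": "reference", "quantity": 1.0},
            {"sample": "control", "primer_pair": "Rp49", "role": "reference", "quantity": 1.0},
        ]
    )
    folds = []
    for k in range(n_plates):
        ct, dilution = generate_qpcr_plate(
            quantities, {"HeTA": 2.0, "Rp49": 1.95}, noise_sd=noise_sd, seed=seed + k
        )
        eff = {
            p: fit_efficiency(dilution[dilution["primer_pair"] == p], p).efficiency
            for p in ("HeTA", "Rp49")
        }
        target = {
            s: g["ct"].tolist()
            for s, g in ct[ct["primer_pair"] == "HeTA"].groupby("sample")
        }
        ref = {
            s: g["ct"].tolist()
            for s, g in ct[ct["primer_pair"] == "Rp49"].groupby("sample")
        }
        res = copy_number(target, ref, eff["HeTA"], eff["Rp49"], "control")
        folds.append({r.sample: r.fold_vs_control for r in res}["excess"])
    return {
        "planted_fold": planted_fold,
        "recovered_fold": float(np.exp(np.mean(np.log(folds)))),
        "n_plates": n_plates,
    }


def run_bridge_experiment(
    probs: dict[str, float] | None = None,
    n_embryos: int = 20,
    figures_per_embryo: int = 20,
    seed: int = 0,
):
    """Bridge-frequency contrast at the reported 50% vs 15% regime."""
    if probs is None:
        probs = {"aub": 0.50, "ligIV_aub": 0.15, "wt": 0.02}
    counts = generate_embryo_counts(probs, n_embryos, figures_per_embryo, seed=seed)
    return summarize_bridges(counts, pairs=[("aub", "ligIV_aub")])


def bridge_power(
    p_a: float = 0.5,
    p_b: float = 0.15,
    n_embryos: int = 20,
    figures_per_embryo: int = 20,
    n_simulations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of simulated datasets where the Welch test rejects at alpha."""
    rejections = 0
    for k in range(n_simulations):
        counts = generate_embryo_counts(
            {"a": p_a, "b": p_b}, n_embryos, figures_per_embryo, seed=seed + k
        )
        res = summarize_bridges(counts, pairs=[("a", "b")])
        if res.pairwise.iloc[0]["p"] < alpha:
            rejections += 1
    return rejections / n_simulations


def recovered_ratio(table: pd.DataFrame, genotype: str, size_class: str, strand: str) -> float:
    row = table[
        (table["genotype"] == genotype)
        & (table["size_class"] == size_class)
        & (table["strand"] == strand)
    ]
    if len(row) != 1:
        raise KeyError(f"no unique row for {genotype}/{size_class}/{strand}")
    return float(row["mutant_over_wt"].iloc[0])
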