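#!/usr/bin/env python
"""Generate the study's synthetic inputs: toy genome, annotations, and
genotype-specific small-RNA libraries with planted ground truth.

Genotypes: wild type; aub/armi-like mutants with the short minus-strand
19-22 nt class depleted 5- and 10-fold; a rhi/ago3-like genotype with
the long piRNA classes depleted but the short class at 90% of wild
type.  Writes FASTA/BED/FASTQ plus per-library truth CSVs under
results/simulated/.  Defaults: 100,000 reads per library, seed 1.
"""

import argparse
from pathlib import Path

from telopirna.annotations import write_bed6
from telopirna.experiments import RHI_LIKE_FACTORS
from telopirna.mapping import write_genome_fasta
from telopirna.simulate import (
    default_genome_spec,
    depleted_spec,
    generate_genome,
    generate_library,
    spec_to_yaml,
    wt_library_spec,
    write_fastq,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-reads", type=int, default=100_000)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results/simulated"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    genome_spec = default_genome_spec(seed=args.seed)
    genome, ann = generate_genome(genome_spec)
    write_genome_fasta(genome, out / "genome.fa")
    write_bed6(ann, out / "annotations.bed")

    wt = wt_library_spec(args.n_reads, seed=args.seed + 1)
    specs = [
        wt,
        depleted_spec(wt, {"short_minus_19_22": 5}, "armi_like", seed=args.seed + 2),
        depleted_spec(wt, {"short_minus_19_22": 10}, "aub_like", seed=args.seed + 3),
        depleted_spec(wt, dict(RHI_LIKE_FACTORS), "rhi_like", seed=args.seed + 4),
    ]
    for spec in specs:
        reads, truth = generate_library(genome, ann, spec)
        write_fastq(reads, out / f"{spec.genotype_label}.fastq")
        truth.to_csv(out / f"{spec.genotype_label}_truth.csv", index=False)
        print(f"{spec.genotype_label}: {len(reads)} reads")
    spec_to_yaml(genome_spec, specs, out / "specs.yaml")
    print(f"wrote genome, annotations and {len(specs)} libraries to {out}/")


if __name__ == "__main__":
    main()
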