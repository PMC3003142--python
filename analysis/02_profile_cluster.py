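#!/usr/bin/env python
"""Profile the simulated libraries: trim, map, filter, and quantify the
cluster's strand-split length histograms and size-class fold changes.

Reads the outputs of 01_simulate_libraries.py and writes, under
results/profiles/: per-genotype length histograms (raw and per-million),
the mutant/wt size-class fold-change table, ping-pong reports, cluster
attribution, and the run manifest with its read-conservation ledger.
The short minus-strand class should show its planted depletion in the
aub/armi-like genotypes but sit near wild type in the rhi/ago3-like one.
"""

import argparse
import json
from pathlib import Path

from telopirna.pipeline import RunConfig, run_pipeline
from telopirna.simulate import DEFAULT_LINKER


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/profiles"))
    args = parser.parse_args()

    libraries = {
        p.stem: str(p) for p in sorted(args.in_dir.glob("*.fastq"))
    }
    config = RunConfig(
        genome_fasta=str(args.in_dir / "genome.fa"),
        annotations_bed=str(args.in_dir / "annotations.bed"),
        libraries=libraries,
        wt_label="wt",
        linker=DEFAULT_LINKER,
        output_dir=str(args.out_dir),
    )
    out = run_pipeline(config)
    print("read-conservation ledger per library:")
    print(json.dumps(out["manifest"]["conservation"], indent=2))
    folds = out["fold_change"]
    print("\nsize-class fold changes (mutant / wt, per-million units):")
    print(folds.to_string(index=False))


if __name__ == "__main__":
    main()
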