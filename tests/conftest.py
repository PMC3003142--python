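import numpy as np
import pytest

from telopirna.annotations import AnnotationSet, GenomicInterval
from telopirna.mapping import GenomeIndex
from telopirna.simulate import (
    default_genome_spec,
    generate_genome,
    generate_library,
    wt_library_spec,
)

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture(scope="session")
def toy_genome():
    """Deterministic toy genome + annotations shared across tests."""
    return generate_genome(default_genome_spec(seed=7))


@pytest.fixture(scope="session")
def toy_index(toy_genome):
    genome, _ = toy_genome
    return GenomeIndex(genome)


@pytest.fixture(scope="session")
def small_wt_library(toy_genome):
    """A 20k-read wild-type library with its ground truth."""
    genome, ann = toy_genome
    spec = wt_library_spec(20_000, seed=13)
    reads, truth = generate_library(genome, ann, spec)
    return spec, reads, truth


@pytest.fixture
def tiny_annotations():
    """Hand-built annotations on a hand-built coordinate frame."""
    ann = AnnotationSet(
        cluster=GenomicInterval("chrA", 100, 500, ".", "cluster")
    )
    ann.add("ncrna", GenomicInterval("chrA", 700, 750))
    ann.add("telomeric_element", GenomicInterval("chrA", 150, 300, "-", "elem1"))
    return ann
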