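"""Shared fixtures: small deterministic genomes, cassettes and designs."""

from __future__ import annotations

import numpy as np
import pytest

from delkit.design import design_gene_deletion
from delkit.genome_io import GeneModel, Genome
from delkit.synthetic import (
    FixtureSpec,
    GeneSpec,
    generate_genome,
    synthetic_cassette,
)


def random_sequence(seed: int, n: int, gc: float = 0.36) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def plus_gene() -> GeneModel:
    """The worked-example gene: 900 nt at 2001..2900 on the plus strand."""
    return GeneModel("g1", "chrI", 2001, 2900, "+")


@pytest.fixture(scope="session")
def minus_gene() -> GeneModel:
    return GeneModel("g1m", "chrI", 2001, 2900, "-")


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """10 kb single-chromosome genome (seeded, 36% GC)."""
    return Genome(sequences={"chrI": random_sequence(42, 10_000)}, source="<fixture>")


@pytest.fixture(scope="session")
def cassette():
    return synthetic_cassette(seed=1)


@pytest.fixture(scope="session")
def fixture_all_classes():
    """Genome with one planted gene per GC class (alternating strands)."""
    spec = FixtureSpec(
        seed=7,
        genes=(
            GeneSpec(900, "+", "normal"),
            GeneSpec(900, "-", "low_gc_5prime"),
            GeneSpec(600, "+", "low_gc_3prime"),
            GeneSpec(900, "-", "low_gc_inner"),
        ),
    )
    genome, genes, truth = generate_genome(spec)
    return genome, genes, truth


@pytest.fixture(scope="session")
def normal_design(fixture_all_classes, cassette):
    """Completed design for the GC-normal planted gene."""
    genome, genes, _ = fixture_all_classes
    return genome, design_gene_deletion(genome, genes[0], cassette)
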