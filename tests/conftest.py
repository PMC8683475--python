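import numpy as np
import pytest

from clonemut.genome import (
    build_blacklist,
    build_gene_models,
    build_toy_genome,
)

# Genome emulating the full-scale analysis: ~2.1e9 autosomal bases split
# into two 1-Mb context chromosomes plus 19 virtual chromosomes.
FULL_L = 2 * 1_000_000 + 19 * 110_420_000


@pytest.fixture(scope="session")
def full_genome():
    return build_toy_genome(
        n_context_chromosomes=2,
        context_length=1_000_000,
        n_virtual_chromosomes=19,
        virtual_length=110_420_000,
        gc_fraction=0.42,
        seed=1,
    )


@pytest.fixture(scope="session")
def full_blacklist(full_genome):
    return build_blacklist(full_genome, site_density=1e-5, seed=2)


@pytest.fixture(scope="session")
def context_genome():
    """All-sequence genome so every call has real trinucleotide context."""
    return build_toy_genome(
        n_context_chromosomes=2,
        context_length=400_000,
        n_virtual_chromosomes=0,
        virtual_length=1,
        gc_fraction=0.42,
        seed=3,
    )


@pytest.fixture(scope="session")
def context_genes(context_genome):
    return build_gene_models(context_genome, n_genes=20, seed=4)


@pytest.fixture(scope="session")
def small_genome():
    """Small mixed genome for pipeline-level tests."""
    return build_toy_genome(
        n_context_chromosomes=2,
        context_length=500_000,
        n_virtual_chromosomes=4,
        virtual_length=10_000_000,
        gc_fraction=0.42,
        seed=5,
    )
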