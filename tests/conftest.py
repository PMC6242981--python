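import numpy as np
import pytest

from seedcracker.regions import Region
from seedcracker.simdata import (
    generate_cohort,
    generate_gene_annotation,
    generate_haplotype_panel,
    generate_pool_af,
)


@pytest.fixture(scope="session")
def panel():
    """Small divergent two-haplogroup panel with a couple of recombinants."""
    return generate_haplotype_panel(
        n_anc=8,
        n_der=6,
        L=400,
        divergence=1.0,
        intra_diversity=0.05,
        n_recombinants=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort(panel):
    return generate_cohort(panel, n_small=10, n_large=10, n_mega=6, seed=12)


@pytest.fixture(scope="session")
def candidate_region():
    return Region("TGU1A", 55_070_008, 55_371_638)


@pytest.fixture(scope="session")
def pool_table(cohort, candidate_region):
    return generate_pool_af(
        cohort,
        candidate_region,
        background_sites=400,
        delta_in_region=0.95,
        seed=13,
        private_sites=25,
    )


@pytest.fixture(scope="session")
def gene_annotation():
    return generate_gene_annotation(
        chrom_length=1_000_000, n_genes=12, length_range=(5_000, 40_000), seed=14
    )
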