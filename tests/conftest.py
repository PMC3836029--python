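import numpy as np
import pytest

from satlineage import (
    GenotypeTable,
    Individual,
    LocusDef,
    SimulationConfig,
    simulate_two_lineages,
)


@pytest.fixture
def toy_table() -> GenotypeTable:
    """Four individuals, two loci, one missing genotype, both lineages."""
    return GenotypeTable(
        loci=[LocusDef("L01"), LocusDef("L02")],
        individuals=[
            Individual("A1", "sexual", "Nanporo",
                       {"L01": (210, 214), "L02": (100, 100)}),
            Individual("A2", "sexual", "Kuriyama",
                       {"L01": (210, 218), "L02": (100, 102)}),
            Individual("B1", "asexual", "Nanporo",
                       {"L01": (230, 234), "L02": (110, 112)}),
            Individual("B2", "asexual", "Kuriyama",
                       {"L01": (230, 234), "L02": None}),
        ],
    )


@pytest.fixture(scope="session")
def isolated_table() -> GenotypeTable:
    """Fully isolated lineages: disjoint allele pools at every locus."""
    return simulate_two_lineages(SimulationConfig(divergence=1.0, seed=11))


@pytest.fixture(scope="session")
def default_table() -> GenotypeTable:
    return simulate_two_lineages(SimulationConfig(seed=7))


def random_genotype(rng: np.random.Generator, n_alleles: int = 6):
    return tuple(int(a) for a in rng.integers(1, n_alleles + 1, size=2))


def random_table(rng: np.random.Generator, n_ind=6, n_loci=4,
                 missing_rate=0.1) -> GenotypeTable:
    loci = [LocusDef(f"L{k:02d}") for k in range(n_loci)]
    individuals = []
    for i in range(n_ind):
        genotypes = {
            l.name: None if rng.random() < missing_rate else random_genotype(rng)
            for l in loci
        }
        # first locus always typed so every pair shares a computable locus
        genotypes[loci[0].name] = random_genotype(rng)
        individuals.append(
            Individual(
                id=f"I{i:03d}",
                lineage=("sexual", "asexual")[i % 2],
                location=("Nanporo", "Kuriyama")[i % 2],
                genotypes=genotypes,
            )
        )
    return GenotypeTable(loci=loci, individuals=individuals)
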