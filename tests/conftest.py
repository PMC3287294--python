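import numpy as np
import pytest

from raftgen.data import (
    Genotype,
    GenotypeDataset,
    Individual,
    Marker,
    MISSING_GENOTYPE,
    SampleSite,
)


def make_dataset(pop_genotypes, locus_names=None, sites=None, habitat="unknown"):
    """Build a dataset from {population: [genotype-tuple-per-locus, ...]}.

    Each individual is a list of (a, b) pairs or None (blank) per locus.
    """
    first = next(iter(pop_genotypes.values()))
    n_loci = len(first[0])
    locus_names = locus_names or [f"L{j + 1}" for j in range(n_loci)]
    if sites is None:
        sites = [SampleSite(pop, 0.0, float(i)) for i, pop in enumerate(pop_genotypes)]
    individuals = []
    allele_sets = [set() for _ in range(n_loci)]
    counter = 0
    for pop, rows in pop_genotypes.items():
        for row in rows:
            genos = []
            for j, pair in enumerate(row):
                if pair is None:
                    genos.append(MISSING_GENOTYPE)
                else:
                    genos.append(Genotype(*pair))
                    allele_sets[j].update(pair)
            individuals.append(
                Individual(f"ind{counter}", pop, habitat, tuple(genos))
            )
            counter += 1
    markers = [
        Marker(locus_names[j], tuple(sorted(allele_sets[j])) if allele_sets[j] else (1,))
        for j in range(n_loci)
    ]
    return GenotypeDataset(individuals, markers, sites)


@pytest.fixture
def fixed_difference_pair():
    """Two populations fixed for different alleles at one locus."""
    return make_dataset(
        {
            "A": [[(1, 1)] for _ in range(30)],
            "B": [[(2, 2)] for _ in range(30)],
        }
    )


@pytest.fixture
def identical_pair():
    """Two populations with the same genotype composition, large n."""
    row = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]] * 125
    return make_dataset({"A": list(row), "B": list(row)})


@pytest.fixture(scope="session")
def paper_like():
    from raftgen.synthetic import paper_like_dataset

    return paper_like_dataset(seed=7)
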