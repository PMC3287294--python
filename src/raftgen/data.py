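"""Domain model for codominant multiallelic genotype datasets.

A dataset holds apparent genotypes (what the scoring pipeline reports,
including fully blank loci) for a set of individuals collected at
georeferenced sampling sites.  Allele labels are integers — fragment
sizes in base pairs — but are opaque to every statistic downstream; no
ordering of labels is used except by the allele-dropout diagnostic.

Populations are sampling sites: each site carries a ``population_label``
(defaulting to its ``site_id``) and every statistic that says
"population" groups individuals by that label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

HABITATS = ("rock", "kelp-holdfast", "kelp-surface", "unknown")

#: Sentinel allele label for the (unobservable) null allele class when a
#: frequency vector is augmented with it.  Real allele labels are
#: positive fragment sizes, so -1 can never collide.
NULL_ALLELE = -1


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of allele calls, or a fully blank locus.

    Half-missing calls are invalid: the scoring pipeline this models
    yields either a complete genotype or a blank.
    """

    allele_a: int | None
    allele_b: int | None

    def __post_init__(self) -> None:
        if (self.allele_a is None) != (self.allele_b is None):
            raise ValueError(
                "half-missing genotype: either both alleles are called or both are missing"
            )
        # canonical order so that a/b == b/a
        if self.allele_a is not None and self.allele_a > self.allele_b:
            a, b = self.allele_a, self.allele_b
            object.__setattr__(self, "allele_a", b)
            object.__setattr__(self, "allele_b", a)

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_homozygous(self) -> bool:
        return self.allele_a is not None and self.allele_a == self.allele_b

    def alleles(self) -> tuple[int, int]:
        if self.is_missing:
            raise ValueError("missing genotype has no alleles")
        return (self.allele_a, self.allele_b)


MISSING_GENOTYPE = Genotype(None, None)


@dataclass(frozen=True)
class Marker:
    """A microsatellite locus with its universe of observed allele labels."""

    name: str
    allele_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.allele_labels) < 1:
            raise ValueError(f"marker {self.name!r} needs at least one allele")
        if len(set(self.allele_labels)) != len(self.allele_labels):
            raise ValueError(f"marker {self.name!r} has duplicate allele labels")


@dataclass(frozen=True)
class SampleSite:
    site_id: str
    latitude: float
    longitude: float
    population_label: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of range")
        if not self.population_label:
            object.__setattr__(self, "population_label", self.site_id)


@dataclass(frozen=True)
class Individual:
    individual_id: str
    site_id: str
    habitat: str
    genotypes: tuple[Genotype, ...]

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(
                f"habitat {self.habitat!r} not in allowed vocabulary {HABITATS}"
            )

    def n_scored(self) -> int:
        return sum(1 for g in self.genotypes if not g.is_missing)


@dataclass
class GenotypeDataset:
    individuals: list[Individual]
    markers: list[Marker]
    sites: list[SampleSite]

    def __post_init__(self) -> None:
        site_ids = {s.site_id for s in self.sites}
        for ind in self.individuals:
            if ind.site_id not in site_ids:
                raise ValueError(
                    f"individual {ind.individual_id!r}: unknown site {ind.site_id!r}"
                )
            if len(ind.genotypes) != len(self.markers):
                raise ValueError(
                    f"individual {ind.individual_id!r}: expected "
                    f"{len(self.markers)} genotypes, got {len(ind.genotypes)}"
                )
            for g, m in zip(ind.genotypes, self.markers):
                if not g.is_missing:
                    for a in g.alleles():
                        if a not in m.allele_labels:
                            raise ValueError(
                                f"individual {ind.individual_id!r}, locus {m.name!r}: "
                                f"allele {a} not in marker allele set"
                            )

    # -- lookups -------------------------------------------------------

    @property
    def site_map(self) -> dict[str, SampleSite]:
        return {s.site_id: s for s in self.sites}

    @property
    def populations(self) -> list[str]:
        """Population labels in site order, without duplicates."""
        seen: list[str] = []
        for s in self.sites:
            if s.population_label not in seen:
                seen.append(s.population_label)
        return seen

    def population_of(self, ind: Individual) -> str:
        return self.site_map[ind.site_id].population_label

    def individuals_in(self, population: str) -> list[Individual]:
        return [i for i in self.individuals if self.population_of(i) == population]

    def locus_index(self, locus: str) -> int:
        for j, m in enumerate(self.markers):
            if m.name == locus:
                return j
        raise KeyError(f"unknown locus {locus!r}")

    # -- derived counts ------------------------------------------------

    def genotype_counts(
        self, population: str, locus: str
    ) -> tuple[dict[tuple[int, int], int], int]:
        """Counts of apparent genotypes and blanks in one population x locus cell.

        Returns ``(counts, n_blank)`` where ``counts`` maps canonical
        (a, b) pairs with a <= b to their multiplicity.
        """
        j = self.locus_index(locus)
        counts: dict[tuple[int, int], int] = {}
        blanks = 0
        for ind in self.individuals_in(population):
            g = ind.genotypes[j]
            if g.is_missing:
                blanks += 1
            else:
                key = g.alleles()
                counts[key] = counts.get(key, 0) + 1
        return counts, blanks


# ---------------------------------------------------------------------
# Allele frequency tables


@dataclass(frozen=True)
class FrequencyCell:
    """Allele frequencies and scored sample size in one population x locus cell.

    ``available`` is False when the cell has no scored genotypes at all;
    downstream operations must then skip the cell or fail loudly.
    Frequencies sum to 1 within an available cell (to 1e-12) unless the
    vector has been null-augmented, in which case the ``NULL_ALLELE``
    key participates in the sum.
    """

    freqs: Mapping[int, float]
    n: int
    available: bool = True

    def vector(self, labels: Sequence[int]) -> list[float]:
        return [self.freqs.get(a, 0.0) for a in labels]


@dataclass
class AlleleFrequencyTable:
    populations: list[str]
    loci: list[str]
    cells: dict[tuple[str, str], FrequencyCell]

    def cell(self, population: str, locus: str) -> FrequencyCell:
        return self.cells[(population, locus)]

    def require_available(self) -> None:
        for key, c in self.cells.items():
            if not c.available:
                raise ValueError(f"population x locus cell {key} has no scored data")


def allele_frequencies(
    dataset: GenotypeDataset, by_population: bool = True
) -> AlleleFrequencyTable:
    """Observed (uncorrected) allele frequencies per population x locus cell.

    Frequencies are allele-copy counts over 2n, with n the number of
    scored individuals in the cell.  With ``by_population=False`` all
    individuals form a single pooled population labelled ``"all"``.
    """
    pops = dataset.populations if by_population else ["all"]
    cells: dict[tuple[str, str], FrequencyCell] = {}
    for pop in pops:
        inds = (
            dataset.individuals_in(pop) if by_population else list(dataset.individuals)
        )
        for j, m in enumerate(dataset.markers):
            counts: dict[int, int] = {}
            n = 0
            for ind in inds:
                g = ind.genotypes[j]
                if g.is_missing:
                    continue
                n += 1
                for a in g.alleles():
                    counts[a] = counts.get(a, 0) + 1
            if n == 0:
                cells[(pop, m.name)] = FrequencyCell({}, 0, available=False)
            else:
                total = 2 * n
                cells[(pop, m.name)] = FrequencyCell(
                    {a: c / total for a, c in counts.items()}, n
                )
    return AlleleFrequencyTable(pops, [m.name for m in dataset.markers], cells)


def filter_by_scored_loci(dataset: GenotypeDataset, min_loci: int) -> GenotypeDataset:
    """Keep individuals successfully genotyped at ``min_loci`` or more loci.

    Sites that lose all their individuals stay in the metadata so that
    coordinate-dependent analyses keep a consistent site list.
    """
    if min_loci < 0:
        raise ValueError("min_loci must be >= 0")
    kept = [i for i in dataset.individuals if i.n_scored() >= min_loci]
    return GenotypeDataset(kept, list(dataset.markers), list(dataset.sites))


def relabel_habitat(ind: Individual, habitat: str) -> Individual:
    return replace(ind, habitat=habitat)


def subset_individuals(
    dataset: GenotypeDataset, keep: Iterable[str]
) -> GenotypeDataset:
    keep_set = set(keep)
    kept = [i for i in dataset.individuals if i.individual_id in keep_set]
    return GenotypeDataset(kept, list(dataset.markers), list(dataset.sites))
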