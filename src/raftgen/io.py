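"""Readers and writers: Genepop files, delimited genotype tables, sites files.

Genepop is the exchange format; it carries genotypes and population
grouping but neither habitat labels nor coordinates, so the delimited
table (which is lossless) is the round-trip format of record and a
sites CSV carries coordinates.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import pandas as pd

from .data import (
    Genotype,
    GenotypeDataset,
    HABITATS,
    Individual,
    Marker,
    MISSING_GENOTYPE,
    SampleSite,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------
# Genepop


def _split_locus_names(lines: list[str]) -> list[str]:
    names: list[str] = []
    for line in lines:
        names.extend(part.strip() for part in line.split(",") if part.strip())
    return names


def read_genepop(
    path: str | Path, sites: Sequence[SampleSite] | None = None
) -> GenotypeDataset:
    """Parse a Genepop file into a dataset.

    Populations appear in file order; when ``sites`` is given they are
    matched to it positionally, otherwise placeholder sites ``pop_1``,
    ``pop_2``, ... at coordinate (0, 0) are created.  Allele codes must
    use a consistent 2- or 3-digit width within each locus; 00/000
    encodes a missing allele and a fully-zero genotype a blank locus.
    """
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise ParseError(f"{path}: empty file")
    lines = [ln.rstrip() for ln in raw]
    header: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().lower() != "pop":
        if lines[i].strip():
            header.append(lines[i])
        i += 1
    locus_names = _split_locus_names(header)
    if not locus_names:
        raise ParseError(f"{path}: no locus names before first POP")

    pops: list[list[tuple[str, list[Genotype]]]] = []
    widths: list[int | None] = [None] * len(locus_names)
    lineno = i
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pops.append([])
            continue
        if not pops:
            raise ParseError(f"{path}:{lineno + 1}: genotype row before first POP")
        if "," not in line:
            raise ParseError(f"{path}:{lineno + 1}: missing ',' separator")
        ind_id, _, geno_part = line.partition(",")
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise ParseError(
                f"{path}:{lineno + 1}: expected {len(locus_names)} genotypes, "
                f"got {len(tokens)}"
            )
        genos: list[Genotype] = []
        for j, tok in enumerate(tokens):
            if not re.fullmatch(r"\d+", tok) or len(tok) not in (4, 6):
                raise ParseError(
                    f"{path}:{lineno + 1}: malformed genotype code {tok!r} "
                    f"at locus {locus_names[j]}"
                )
            w = len(tok) // 2
            if widths[j] is None:
                widths[j] = w
            elif widths[j] != w:
                raise ParseError(
                    f"{path}:{lineno + 1}: mixed {2}/{3}-digit allele coding "
                    f"at locus {locus_names[j]}"
                )
            a, b = int(tok[:w]), int(tok[w:])
            try:
                genos.append(
                    Genotype(a if a != 0 else None, b if b != 0 else None)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno + 1}: {exc}") from exc
        pops[-1].append((ind_id.strip(), genos))

    if sites is None:
        sites = [
            SampleSite(f"pop_{k + 1}", 0.0, 0.0) for k in range(len(pops))
        ]
    elif len(sites) != len(pops):
        raise ParseError(
            f"{path}: file has {len(pops)} populations but {len(sites)} sites given"
        )

    markers = []
    for j, name in enumerate(locus_names):
        alleles = sorted(
            {
                a
                for pop in pops
                for _, genos in pop
                if not genos[j].is_missing
                for a in genos[j].alleles()
            }
        )
        markers.append(Marker(name, tuple(alleles) if alleles else (0,)))

    individuals = [
        Individual(ind_id, sites[k].site_id, "unknown", tuple(genos))
        for k, pop in enumerate(pops)
        for ind_id, genos in pop
    ]
    return GenotypeDataset(individuals, markers, list(sites))


def write_genepop(
    dataset: GenotypeDataset, path: str | Path, title: str = "raftgen export"
) -> None:
    """Write a dataset in Genepop dialect with 3-digit allele coding."""
    for m in dataset.markers:
        for a in m.allele_labels:
            if not 0 < a <= 999:
                raise ValueError(
                    f"allele label {a} at locus {m.name} not encodable in 3 digits"
                )
    out = [title]
    out.extend(m.name for m in dataset.markers)
    for pop in dataset.populations:
        out.append("POP")
        for ind in dataset.individuals_in(pop):
            codes = []
            for g in ind.genotypes:
                if g.is_missing:
                    codes.append("000000")
                else:
                    codes.append(f"{g.allele_a:03d}{g.allele_b:03d}")
            out.append(f"{ind.individual_id} , " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------
# Delimited table (lossless round-trip format)


def write_table(dataset: GenotypeDataset, path: str | Path) -> None:
    rows = []
    for ind in dataset.individuals:
        row: dict[str, object] = {
            "individual_id": ind.individual_id,
            "site_id": ind.site_id,
            "habitat": ind.habitat,
        }
        for m, g in zip(dataset.markers, ind.genotypes):
            row[f"{m.name}_a"] = "" if g.is_missing else g.allele_a
            row[f"{m.name}_b"] = "" if g.is_missing else g.allele_b
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_table(
    path: str | Path, sites: Sequence[SampleSite] | None = None
) -> GenotypeDataset:
    """Read a delimited genotype table (see :func:`write_table` for layout).

    Columns: ``individual_id, site_id, habitat`` then two columns per
    locus (``<locus>_a``, ``<locus>_b``).  Duplicate individual ids and
    habitat values outside the allowed vocabulary are errors.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "site_id": str})
    required = ["individual_id", "site_id", "habitat"]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ParseError(f"{path}: duplicate individual_id {dup!r}")
    locus_cols = [c for c in df.columns if c.endswith("_a") and c not in required]
    locus_names = [c[:-2] for c in locus_cols]
    for name in locus_names:
        if f"{name}_b" not in df.columns:
            raise ParseError(f"{path}: locus {name} has _a column but no _b")

    individuals = []
    allele_sets: dict[str, set[int]] = {name: set() for name in locus_names}
    for _, row in df.iterrows():
        habitat = str(row["habitat"])
        if habitat not in HABITATS:
            raise ParseError(
                f"{path}: habitat {habitat!r} not in allowed vocabulary {HABITATS}"
            )
        genos = []
        for name in locus_names:
            a, b = row[f"{name}_a"], row[f"{name}_b"]
            a_missing = pd.isna(a) or a == ""
            b_missing = pd.isna(b) or b == ""
            if a_missing and b_missing:
                genos.append(MISSING_GENOTYPE)
            elif a_missing or b_missing:
                raise ParseError(
                    f"{path}: half-missing genotype for {row['individual_id']} "
                    f"at {name}"
                )
            else:
                g = Genotype(int(a), int(b))
                allele_sets[name].update(g.alleles())
                genos.append(g)
        individuals.append(
            Individual(str(row["individual_id"]), str(row["site_id"]), habitat, tuple(genos))
        )
    markers = [
        Marker(name, tuple(sorted(allele_sets[name])) if allele_sets[name] else (0,))
        for name in locus_names
    ]
    if sites is None:
        seen: list[str] = []
        for ind in individuals:
            if ind.site_id not in seen:
                seen.append(ind.site_id)
        sites = [SampleSite(s, 0.0, 0.0) for s in seen]
    return GenotypeDataset(individuals, markers, list(sites))


# ---------------------------------------------------------------------
# Sites CSV


def read_sites(path: str | Path) -> list[SampleSite]:
    df = pd.read_csv(path, dtype={"site_id": str})
    sites = []
    for _, row in df.iterrows():
        sites.append(
            SampleSite(
                str(row["site_id"]),
                float(row["latitude"]),
                float(row["longitude"]),
                str(row["population_label"])
                if "population_label" in df.columns and not pd.isna(row.get("population_label"))
                else "",
            )
        )
    return sites


def write_sites(sites: Sequence[SampleSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "latitude": s.latitude,
                "longitude": s.longitude,
                "population_label": s.population_label,
            }
            for s in sites
        ]
    ).to_csv(path, index=False)
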