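"""End-to-end study pipeline: assign -> filter -> null-correct ->
differentiation statistics -> distances -> spatial tests.

The workflow mirrors the study design it reimplements: a genetic
assignment analysis on the pooled two-species dataset comes first,
individuals with ambiguous cluster membership are discarded, and every
population-genetic statistic is then computed per species.  Reruns
with the same config and seeds are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import ClusterModel, fit_no_admixture, q_table, split_by_assignment
from .data import GenotypeDataset, filter_by_scored_loci
from .diffstats import nm_matrix, pairwise_report
from .distances import DistanceMatrix, dc_matrix, gap_matrix, great_circle_matrix
from .io import read_sites, read_table
from .null_alleles import estimate_all, summarize_null_frequencies
from .spatial import mantel, partial_mantel, sasha


@dataclass
class PipelineConfig:
    genotypes: str | None = None          # delimited table path
    sites: str | None = None              # sites CSV path
    geo_matrix: str | None = None         # labelled CSV; great-circle fallback if None
    gap_groups: tuple[list[str], list[str]] | None = None
    k: int = 2
    assignment_threshold: float = 0.8
    min_loci: int = 4
    min_pop_size: int = 10
    blank_mode: str = "blanks-as-nulls"
    n_boot: int = 1000
    mantel_perms: int = 30000
    sasha_perms: int = 10000
    hwe_perms: int = 1000
    burnin: int = 2000
    iters: int = 10000
    chains: int = 5
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("gap_groups"):
            raw["gap_groups"] = tuple(raw["gap_groups"])
        return cls(**raw)


def _species_block(
    ds: GenotypeDataset,
    config: PipelineConfig,
    geo: DistanceMatrix,
    gap: DistanceMatrix | None,
    seed: int,
) -> dict:
    rng = np.random.default_rng(seed)
    report = pairwise_report(
        ds, n_boot=config.n_boot, seed=int(rng.integers(2**31)),
        blank_mode=config.blank_mode, hwe_perms=config.hwe_perms,
    )
    pops = ds.populations
    estimates = estimate_all(ds, config.blank_mode)
    null_summary = summarize_null_frequencies(estimates)
    dc = dc_matrix(ds, ina=True, blank_mode=config.blank_mode)
    geo_sub = geo.reorder(pops) if set(pops).issubset(geo.labels) else geo
    block: dict = {
        "populations": pops,
        "n_individuals": len(ds.individuals),
        "table4": report.to_dict(orient="records"),
        "nm_matrix": nm_matrix(report, pops).to_dict(),
        "null_by_population": null_summary["by_population"].to_dict(orient="records"),
        "null_by_locus": null_summary["by_locus"].to_dict(orient="records"),
        "dc_matrix": {"labels": dc.labels, "values": dc.values.tolist()},
    }
    mantel_rows = []
    if len(pops) >= 3:
        m1 = mantel(dc, geo_sub, config.mantel_perms, int(rng.integers(2**31)))
        mantel_rows.append(
            {"variables": "Gen,Geo", "r": m1.r, "p": m1.p_one_sided}
        )
        if gap is not None:
            gap_sub = gap.reorder(pops)
            m2 = partial_mantel(
                dc, geo_sub, gap_sub, config.mantel_perms, int(rng.integers(2**31))
            )
            m3 = mantel(dc, gap_sub, config.mantel_perms, int(rng.integers(2**31)))
            m4 = partial_mantel(
                dc, gap_sub, geo_sub, config.mantel_perms, int(rng.integers(2**31))
            )
            mantel_rows += [
                {"variables": "Gen,Geo|Gap", "r": m2.r_partial, "p": m2.p_one_sided},
                {"variables": "Gen,Gap", "r": m3.r, "p": m3.p_one_sided},
                {"variables": "Gen,Gap|Geo", "r": m4.r_partial, "p": m4.p_one_sided},
            ]
    block["mantel"] = mantel_rows
    sr = sasha(ds, geo, config.sasha_perms, int(rng.integers(2**31)))
    block["sasha"] = {
        "om_km": sr.om, "em_km": sr.em, "p": sr.p_two_sided,
        "per_locus_om": sr.per_locus_om,
    }
    return block


def run_pipeline(
    config: PipelineConfig, dataset: GenotypeDataset | None = None
) -> dict:
    """Run the whole workflow; returns the study report as a JSON-able dict.

    ``dataset`` may be passed in memory (e.g. from the simulator); the
    config's input paths are used otherwise.  When ``config.out_dir``
    is set the report and per-stage CSVs are written there.
    """
    if dataset is None:
        if config.genotypes is None:
            raise ValueError("either a dataset or config.genotypes is required")
        sites = read_sites(config.sites) if config.sites else None
        dataset = read_table(config.genotypes, sites)

    dataset = filter_by_scored_loci(dataset, config.min_loci)
    model = ClusterModel(
        k=config.k, n_burnin=config.burnin, n_iter=config.iters,
        n_chains=config.chains, seed=config.seed,
    )
    result = fit_no_admixture(dataset, model)
    clusters, crosstab = split_by_assignment(
        dataset, result, config.assignment_threshold
    )

    geo = (
        DistanceMatrix.from_csv(config.geo_matrix)
        if config.geo_matrix
        else great_circle_matrix(dataset.sites)
    )
    gap = gap_matrix(dataset.sites, config.gap_groups) if config.gap_groups else None

    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config": _config_hash(config),
        },
        "assignment": {
            "n_total": len(dataset.individuals),
            "n_ambiguous": len(dataset.individuals)
            - sum(len(d.individuals) for d in clusters.values()),
            "converged": bool(result.converged),
            "min_chain_correlation": result.min_chain_correlation,
            "crosstab": crosstab.to_dict(),
        },
        "species": {},
    }

    for k, ds in sorted(clusters.items()):
        # drop undersized populations from connectivity statistics
        sizes = {p: len(ds.individuals_in(p)) for p in ds.populations}
        keep_pops = [p for p, n in sizes.items() if n >= config.min_pop_size]
        dropped = sorted(set(sizes) - set(keep_pops))
        if dropped:
            warnings.warn(f"cluster {k}: populations {dropped} below min size, dropped")
        keep_ids = [
            i.individual_id
            for i in ds.individuals
            if ds.population_of(i) in keep_pops
        ]
        from .data import subset_individuals

        ds_kept = subset_individuals(ds, keep_ids)
        ds_kept.sites = [s for s in ds_kept.sites if s.population_label in keep_pops]
        if len(ds_kept.populations) < 2:
            report["species"][str(k)] = {"skipped": "fewer than 2 usable populations"}
            continue
        gap_k = (
            gap_matrix(
                ds_kept.sites,
                (
                    [g for g in config.gap_groups[0] if g in keep_pops],
                    [g for g in config.gap_groups[1] if g in keep_pops],
                ),
            )
            if config.gap_groups
            else None
        )
        geo_k = geo.reorder([s.site_id for s in ds_kept.sites])
        report["species"][str(k)] = _species_block(
            ds_kept, config, geo_k, gap_k, seed=config.seed + 1000 + k
        )

    if config.out_dir:
        _write_outputs(report, q_table(result), config, Path(config.out_dir))
    return report


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def report_hash(report: dict) -> str:
    return hashlib.sha256(
        json.dumps(report, sort_keys=True).encode()
    ).hexdigest()


def _write_outputs(
    report: dict, q: pd.DataFrame, config: PipelineConfig, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    q.to_csv(out / "q_values.csv", index=False)
    for k, block in report["species"].items():
        if "table4" in block:
            pd.DataFrame(block["table4"]).to_csv(
                out / f"table4_species{k}.csv", index=False
            )
            pd.DataFrame(block["nm_matrix"]).to_csv(out / f"nm_matrix_species{k}.csv")
            pd.DataFrame(block["mantel"]).to_csv(
                out / f"table5_species{k}.csv", index=False
            )
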