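"""Heterozygosity, Jost's D, Weir's theta (raw and null-corrected),
standardized G''_ST and island-model migrant numbers.

All statistics operate on population x locus allele-frequency cells.
H_S and H_T use Nei & Chesser's small-sample bias corrections with the
harmonic-mean sample size; D_est is computed per locus from raw
frequencies and averaged arithmetically, with a bootstrap CI that
resamples alleles or genotypes depending on the HWE status of the cell;
F_ST is Weir's theta assembled as a ratio of summed variance components
over alleles and loci, with an ENA variant computed on null-corrected
visible frequencies; G''_ST is Hedrick's standardized measure, and N_m
the equilibrium island-model transform (1 - G''_ST) / (4 F_ST).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AlleleFrequencyTable, GenotypeDataset, allele_frequencies
from .null_alleles import corrected_frequencies, estimate_all, hwe_test


# ---------------------------------------------------------------------
# Heterozygosity


@dataclass
class HeterozygosityStats:
    loci: list[str]
    h_s_per_locus: np.ndarray
    h_t_per_locus: np.ndarray
    h_s: float  # arithmetic mean over loci
    h_t: float
    k: int
    n_harmonic: np.ndarray  # per locus


def _cell_vectors(
    table: AlleleFrequencyTable, populations: list[str], locus: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stack frequency vectors over a shared allele universe."""
    labels = sorted(
        {a for pop in populations for a in table.cell(pop, locus).freqs}
    )
    mat = np.array(
        [table.cell(pop, locus).vector(labels) for pop in populations]
    )
    ns = np.array([table.cell(pop, locus).n for pop in populations], dtype=float)
    return mat, ns


def heterozygosity(
    table: AlleleFrequencyTable, populations: list[str] | None = None
) -> HeterozygosityStats:
    """Bias-corrected H_S and H_T per locus and averaged over loci.

    Per locus, with p_ka the frequency of allele a in population k and
    n~ the harmonic mean of per-cell scored sample sizes:

        H_S = (n~ / (n~ - 1)) * (1 - mean_k sum_a p_ka^2)
        H_T = 1 - sum_a pbar_a^2 + H_S / (k * n~)

    where pbar is the unweighted across-population mean frequency.
    """
    pops = populations if populations is not None else list(table.populations)
    if len(pops) < 1:
        raise ValueError("need at least one population")
    for pop in pops:
        for locus in table.loci:
            if not table.cell(pop, locus).available:
                raise ValueError(f"cell ({pop}, {locus}) has no scored data")
    k = len(pops)
    hs_l, ht_l, nh_l = [], [], []
    for locus in table.loci:
        mat, ns = _cell_vectors(table, pops, locus)
        n_h = k / (1.0 / ns).sum()
        j_mean = float((mat**2).sum(axis=1).mean())
        h_s = (n_h / (n_h - 1.0)) * (1.0 - j_mean)
        pbar = mat.mean(axis=0)
        h_t = 1.0 - float((pbar**2).sum()) + h_s / (k * n_h)
        hs_l.append(h_s)
        ht_l.append(h_t)
        nh_l.append(n_h)
    hs_arr, ht_arr = np.array(hs_l), np.array(ht_l)
    return HeterozygosityStats(
        list(table.loci), hs_arr, ht_arr, float(hs_arr.mean()), float(ht_arr.mean()),
        k, np.array(nh_l),
    )


# ---------------------------------------------------------------------
# Jost's D


def _d_from_hs_ht(h_s: float, h_t: float, k: int) -> float:
    return (h_t - h_s) / (1.0 - h_s) * k / (k - 1.0)


def _per_locus_d(mat: np.ndarray, ns: np.ndarray) -> float:
    k = mat.shape[0]
    n_h = k / (1.0 / ns).sum()
    j_mean = float((mat**2).sum(axis=1).mean())
    h_s = (n_h / (n_h - 1.0)) * (1.0 - j_mean)
    pbar = mat.mean(axis=0)
    h_t = 1.0 - float((pbar**2).sum()) + h_s / (k * n_h)
    if h_s >= 1.0:
        return math.nan
    return _d_from_hs_ht(h_s, h_t, k)


def jost_d(
    dataset: GenotypeDataset,
    populations: list[str] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    hwe_alpha: float = 0.05,
    hwe_perms: int = 1000,
) -> tuple[float, tuple[float, float], dict[str, float]]:
    """Mean D_est over loci with a percentile bootstrap CI.

    Per locus D = [(H_T - H_S)/(1 - H_S)] * k/(k - 1) from raw
    (uncorrected) bias-adjusted frequencies.  In each bootstrap
    replicate a locus is resampled at the allele level when every
    involved population is in HWE there (homozygote-excess p >=
    ``hwe_alpha``), and at the genotype level otherwise.
    """
    pops = populations if populations is not None else dataset.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    k = len(pops)

    # per (locus, pop): allele-copy array and genotype array in index space
    copy_arrays: dict[tuple[str, str], np.ndarray] = {}
    geno_arrays: dict[tuple[str, str], np.ndarray] = {}
    labels_by_locus: dict[str, list[int]] = {}
    for m in dataset.markers:
        universe: set[int] = set()
        per_pop = {}
        for pop in pops:
            counts, _ = dataset.genotype_counts(pop, m.name)
            genos = [pair for pair, c in counts.items() for _ in range(c)]
            per_pop[pop] = genos
            universe.update(a for pair in genos for a in pair)
        labels = sorted(universe)
        idx = {a: i for i, a in enumerate(labels)}
        labels_by_locus[m.name] = labels
        for pop in pops:
            genos = per_pop[pop]
            arr = np.array([[idx[a], idx[b]] for a, b in genos], dtype=int)
            geno_arrays[(pop, m.name)] = arr
            copy_arrays[(pop, m.name)] = arr.ravel() if arr.size else arr.reshape(0)

    # point estimate and HWE status
    per_locus: dict[str, float] = {}
    allele_level: dict[str, bool] = {}
    used_loci: list[str] = []
    for m in dataset.markers:
        mats, ns = [], []
        for pop in pops:
            arr = copy_arrays[(pop, m.name)]
            n = len(geno_arrays[(pop, m.name)])
            if n == 0:
                raise ValueError(f"cell ({pop}, {m.name}) has no scored data")
            freqs = np.bincount(arr, minlength=len(labels_by_locus[m.name])) / (2 * n)
            mats.append(freqs)
            ns.append(n)
        d = _per_locus_d(np.array(mats), np.array(ns, dtype=float))
        if math.isnan(d):
            warnings.warn(f"locus {m.name}: H_S = 1, D undefined; locus skipped")
            continue
        per_locus[m.name] = d
        used_loci.append(m.name)
        allele_level[m.name] = all(
            hwe_test(dataset, pop, m.name, n_perm=hwe_perms,
                     seed=int(rng.integers(2**31))).p_excess >= hwe_alpha
            for pop in pops
        )
    if not used_loci:
        raise ValueError("no usable loci")
    d_est = float(np.mean([per_locus[l] for l in used_loci]))

    # bootstrap
    boot_means = np.empty(n_boot)
    for b in range(n_boot):
        ds = []
        for locus in used_loci:
            n_labels = len(labels_by_locus[locus])
            mats, ns = [], []
            for pop in pops:
                if allele_level[locus]:
                    copies = copy_arrays[(pop, locus)]
                    resampled = copies[rng.integers(0, len(copies), len(copies))]
                else:
                    genos = geno_arrays[(pop, locus)]
                    resampled = genos[rng.integers(0, len(genos), len(genos))].ravel()
                mats.append(np.bincount(resampled, minlength=n_labels) / len(resampled))
                ns.append(len(resampled) // 2)
            d = _per_locus_d(np.array(mats), np.array(ns, dtype=float))
            if not math.isnan(d):
                ds.append(d)
        boot_means[b] = np.mean(ds) if ds else math.nan
    # recentred (basic) percentile interval: data resampling adds apparent
    # differentiation, so the raw bootstrap distribution is biased upward
    # relative to the point estimate; recentring removes that bias and
    # keeps the point estimate inside its own interval
    shifted = boot_means - np.nanmean(boot_means) + d_est
    lo, hi = np.nanpercentile(shifted, [2.5, 97.5])
    return d_est, (float(lo), float(hi)), per_locus


# ---------------------------------------------------------------------
# Weir's theta


def _variance_components(
    p: np.ndarray, h: np.ndarray, ns: np.ndarray
) -> tuple[float, float]:
    """Summed a and a+b+c over the alleles of one locus.

    ``p``: (r, A) allele frequencies per population; ``h``: (r, A)
    per-population frequency of heterozygotes carrying each allele;
    ``ns``: per-population sample sizes.
    """
    r = p.shape[0]
    n_bar = ns.mean()
    n_c = (r * n_bar - (ns**2).sum() / (r * n_bar)) / (r - 1.0)
    num = 0.0
    den = 0.0
    for a in range(p.shape[1]):
        p_bar = float((ns * p[:, a]).sum() / ns.sum())
        s2 = float((ns * (p[:, a] - p_bar) ** 2).sum() / ((r - 1.0) * n_bar))
        h_bar = float((ns * h[:, a]).sum() / ns.sum())
        inner = p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0
        comp_a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        comp_b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        comp_c = h_bar / 2.0
        num += comp_a
        den += comp_a + comp_b + comp_c
    return num, den


def weir_fst_components(
    dataset: GenotypeDataset,
    populations: list[str] | None = None,
    use_ena: bool = False,
    blank_mode: str = "blanks-as-nulls",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-locus (sum_a, sum_(a+b+c)) components of Weir's theta.

    Raw mode uses observed frequencies and observed heterozygote
    carriage.  ENA mode uses EM-corrected visible frequencies with the
    null class excluded and renormalized; since corrected individual
    genotypes do not exist, heterozygote carriage is replaced by its
    expectation under the fitted null model — the HWE heterozygosity of
    the renormalized frequencies damped by (1 - r)/(1 + r), which is
    the expected *apparent* heterozygote frequency when a null allele
    at frequency r hides itself inside apparent homozygotes.  This
    keeps the ENA estimator centred while removing the het-sampling
    noise; it is a documented approximation.
    """
    pops = populations if populations is not None else dataset.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    if use_ena:
        estimates = estimate_all(dataset, blank_mode)
        r_by_cell = {(e.population, e.locus): e.r for e in estimates}
        table = corrected_frequencies(
            dataset, blank_mode, include_null=False, estimates=estimates
        )
    else:
        table = allele_frequencies(dataset)
    nums, dens, loci = [], [], []
    for m in dataset.markers:
        labels = sorted(
            {a for pop in pops for a in table.cell(pop, m.name).freqs}
        )
        if not labels:
            continue
        ns = np.array([table.cell(pop, m.name).n for pop in pops], dtype=float)
        if (ns < 2).any():
            continue  # cell too small for variance components
        p = np.array([table.cell(pop, m.name).vector(labels) for pop in pops])
        if use_ena:
            damp = np.array(
                [
                    (1 - r_by_cell[(pop, m.name)]) / (1 + r_by_cell[(pop, m.name)])
                    for pop in pops
                ]
            )
            h = 2 * p * (1 - p) * damp[:, None]
        else:
            h = np.zeros_like(p)
            for i, pop in enumerate(pops):
                counts, _ = dataset.genotype_counts(pop, m.name)
                n = sum(counts.values())
                for (a, b), c in counts.items():
                    if a != b:
                        h[i, labels.index(a)] += c / n
                        h[i, labels.index(b)] += c / n
        num, den = _variance_components(p, h, ns)
        nums.append(num)
        dens.append(den)
        loci.append(m.name)
    if not loci:
        raise ValueError("no locus has >= 2 scored individuals in every population")
    return np.array(nums), np.array(dens), loci


def weir_fst(
    dataset: GenotypeDataset,
    populations: list[str] | None = None,
    use_ena: bool = False,
    blank_mode: str = "blanks-as-nulls",
) -> float:
    nums, dens, _ = weir_fst_components(dataset, populations, use_ena, blank_mode)
    return float(nums.sum() / dens.sum())


def fst_bootstrap_ci(
    nums: np.ndarray, dens: np.ndarray, n_boot: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """Percentile CI for theta by bootstrap-resampling loci."""
    rng = np.random.default_rng(seed)
    n_loci = len(nums)
    idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
    thetas = nums[idx].sum(axis=1) / dens[idx].sum(axis=1)
    lo, hi = np.percentile(thetas, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------
# Standardized differentiation and migrant numbers


def g_double_prime_st(h_t: float, h_s: float, k: int) -> float:
    """Hedrick's standardized G''_ST = k (H_T - H_S) / [(k H_T - H_S)(1 - H_S)]."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if h_s >= 1.0:
        raise ValueError("H_S must be < 1")
    if h_t == 0.0:
        return 0.0
    return k * (h_t - h_s) / ((k * h_t - h_s) * (1.0 - h_s))


def migrants_nm(g2st: float, fst: float) -> float:
    """Equilibrium island-model migrants per generation, (1 - G''_ST)/(4 F_ST).

    Indefinite (returned as inf) when F_ST <= 0.
    """
    if fst <= 0.0:
        return math.inf
    return (1.0 - g2st) / (4.0 * fst)


# ---------------------------------------------------------------------
# Full report


def pairwise_report(
    dataset: GenotypeDataset,
    n_boot: int = 1000,
    seed: int | None = None,
    blank_mode: str = "blanks-as-nulls",
    hwe_perms: int = 1000,
) -> pd.DataFrame:
    """Global plus all-pairs differentiation table.

    One row per scope: H_S/H_T from null-corrected frequencies (the
    null class participating as one allelic state), D_est with data-
    resampling CI, raw and ENA theta with over-loci bootstrap CIs,
    G''_ST (k = 2 for pairs, k = number of populations globally) and
    N_m = (1 - G''_ST)/(4 theta_ENA).
    """
    rng = np.random.default_rng(seed)
    pops = dataset.populations
    estimates = estimate_all(dataset, blank_mode)
    corr_table = corrected_frequencies(
        dataset, blank_mode, include_null=True, estimates=estimates
    )
    scopes: list[tuple[str, list[str]]] = [("global", pops)]
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            scopes.append((f"{pops[i]}|{pops[j]}", [pops[i], pops[j]]))

    rows = []
    for name, group in scopes:
        het = heterozygosity(corr_table, group)
        d_est, (d_lo, d_hi), _ = jost_d(
            dataset, group, n_boot=n_boot, seed=int(rng.integers(2**31)),
            hwe_perms=hwe_perms,
        )
        n_raw, d_raw, _ = weir_fst_components(dataset, group, use_ena=False)
        n_ena, d_ena, _ = weir_fst_components(
            dataset, group, use_ena=True, blank_mode=blank_mode
        )
        fst_raw = float(n_raw.sum() / d_raw.sum())
        fst_ena = float(n_ena.sum() / d_ena.sum())
        raw_ci = fst_bootstrap_ci(n_raw, d_raw, n_boot, int(rng.integers(2**31)))
        ena_ci = fst_bootstrap_ci(n_ena, d_ena, n_boot, int(rng.integers(2**31)))
        g2 = g_double_prime_st(het.h_t, het.h_s, len(group))
        rows.append(
            {
                "scope": name,
                "k": len(group),
                "h_s": het.h_s,
                "h_t": het.h_t,
                "d_est": d_est,
                "d_est_lo": d_lo,
                "d_est_hi": d_hi,
                "fst_raw": fst_raw,
                "fst_raw_lo": raw_ci[0],
                "fst_raw_hi": raw_ci[1],
                "fst_ena": fst_ena,
                "fst_ena_lo": ena_ci[0],
                "fst_ena_hi": ena_ci[1],
                "g2st": g2,
                "n_m": migrants_nm(g2, fst_ena),
            }
        )
    return pd.DataFrame(rows)


def nm_matrix(report: pd.DataFrame, populations: list[str]) -> pd.DataFrame:
    """Pairwise N_m matrix (inf sentinel preserved) from a report table."""
    mat = pd.DataFrame(
        np.zeros((len(populations), len(populations))),
        index=populations,
        columns=populations,
    )
    for _, row in report.iterrows():
        if row["scope"] == "global":
            continue
        a, b = row["scope"].split("|")
        mat.loc[a, b] = mat.loc[b, a] = row["n_m"]
    return mat
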