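"""Hardy-Weinberg testing, null-allele EM estimation and artefact diagnosis.

A null allele is a microsatellite allele that fails to PCR-amplify
(typically a primer-site mutation).  Under random mating it produces an
excess of apparent homozygotes (visible/null pairs) and fully blank
genotypes (null/null pairs).  This module tests for homozygote excess
by Monte-Carlo re-pairing of the observed allele pool, estimates the
null frequency ``r`` per population x locus cell by EM under HWE, and
offers a simplified diagnostic that separates null-allele-like from
large-allele-dropout-like heterozygote deficits by allele-size class.

The EM observation model: with visible-allele frequencies p_i and null
frequency r, true genotype classes have HWE probabilities p_i^2,
2 p_i p_j, 2 p_i r and r^2; true (i, j) is seen as a heterozygote,
(i, i) and (i, null) both as apparent homozygote i, and (null, null) as
a blank.  ``blanks-as-nulls`` counts observed blanks as the (null,
null) class; ``blanks-excluded`` conditions the likelihood on a
non-blank outcome (blank individuals carry no information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    AlleleFrequencyTable,
    FrequencyCell,
    GenotypeDataset,
    NULL_ALLELE,
    allele_frequencies,
)

BLANK_MODES = ("blanks-as-nulls", "blanks-excluded")


# ---------------------------------------------------------------------
# HWE testing


@dataclass(frozen=True)
class HWETestResult:
    population: str
    locus: str
    observed_homozygosity: int
    p_excess: float
    n_permutations: int


def hwe_test(
    dataset: GenotypeDataset,
    population: str,
    locus: str,
    n_perm: int = 10000,
    seed: int | None = None,
) -> HWETestResult:
    """One-tailed Monte-Carlo test for homozygote excess.

    The 2n observed allele copies are pooled and re-paired at random;
    the statistic is the number of homozygous pairs.  The p-value uses
    the +1 pseudo-count correction, so p is never exactly 0.
    """
    counts, _ = dataset.genotype_counts(population, locus)
    pool: list[int] = []
    obs_hom = 0
    n_scored = 0
    for (a, b), c in counts.items():
        pool.extend([a] * c + [b] * c)
        n_scored += c
        if a == b:
            obs_hom += c
    if n_scored < 2:
        raise ValueError(
            f"HWE test needs >= 2 scored individuals in cell ({population}, {locus})"
        )
    pool_arr = np.asarray(pool)
    if len(set(pool)) == 1:  # monomorphic: excess is undefined
        return HWETestResult(population, locus, obs_hom, 1.0, n_perm)

    rng = np.random.default_rng(seed)
    tiled = np.tile(pool_arr, (n_perm, 1))
    perm = rng.permuted(tiled, axis=1)
    hom = (perm[:, 0::2] == perm[:, 1::2]).sum(axis=1)
    p = (1 + int((hom >= obs_hom).sum())) / (1 + n_perm)
    return HWETestResult(population, locus, obs_hom, p, n_perm)


# ---------------------------------------------------------------------
# EM estimation


@dataclass
class NullAlleleEstimate:
    population: str
    locus: str
    r: float
    visible_freqs: dict[int, float]
    n_iterations: int
    converged: bool
    blank_mode: str
    n_scored: int = 0
    n_blank: int = 0
    note: str = ""

    @property
    def total(self) -> float:
        return self.r + sum(self.visible_freqs.values())


def _cell_counts(
    dataset: GenotypeDataset, population: str, locus: str
) -> tuple[list[int], np.ndarray, np.ndarray, int]:
    """Apparent het/hom counts in index space plus the blank count."""
    counts, blanks = dataset.genotype_counts(population, locus)
    alleles = sorted({a for pair in counts for a in pair})
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    het = np.zeros((k, k))
    hom = np.zeros(k)
    for (a, b), c in counts.items():
        if a == b:
            hom[idx[a]] += c
        else:
            het[idx[a], idx[b]] += c
    return alleles, het, hom, blanks


def _loglik(het: np.ndarray, hom: np.ndarray, blanks: int, p: np.ndarray, r: float,
            condition_on_visible: bool) -> float:
    ll = 0.0
    k = len(p)
    with np.errstate(divide="ignore"):
        for i in range(k):
            for j in range(i + 1, k):
                if het[i, j]:
                    ll += het[i, j] * math.log(max(2 * p[i] * p[j], 1e-300))
            if hom[i]:
                ll += hom[i] * math.log(max(p[i] ** 2 + 2 * p[i] * r, 1e-300))
    n_obs = het.sum() + hom.sum()
    if condition_on_visible:
        ll -= n_obs * math.log(max(1 - r * r, 1e-300))
    elif blanks:
        ll += blanks * math.log(max(r * r, 1e-300))
    return ll


def estimate_null_em(
    dataset: GenotypeDataset,
    population: str,
    locus: str,
    blank_mode: str = "blanks-as-nulls",
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> NullAlleleEstimate:
    """EM estimate of the null-allele frequency in one cell.

    Iterates until the largest absolute change in any frequency falls
    below ``tol``.  The observed-data log-likelihood is non-decreasing
    across iterations (an EM guarantee; asserted in the test suite).
    """
    if blank_mode not in BLANK_MODES:
        raise ValueError(f"blank_mode must be one of {BLANK_MODES}")
    alleles, het, hom, blanks = _cell_counts(dataset, population, locus)
    n_scored = int(het.sum() + hom.sum())

    if not alleles:
        return NullAlleleEstimate(
            population, locus, 0.0, {}, 0, True, blank_mode, 0, blanks, note="empty"
        )
    if len(alleles) == 1:
        return NullAlleleEstimate(
            population, locus, 0.0, {alleles[0]: 1.0}, 0, True, blank_mode,
            n_scored, blanks, note="monomorphic",
        )
    if hom.sum() == 0 and (blank_mode == "blanks-excluded" or blanks == 0):
        # no apparent homozygotes and no usable blanks: MLE is r = 0
        copies = het.sum(axis=0) + het.sum(axis=1)
        p = copies / copies.sum()
        return NullAlleleEstimate(
            population, locus, 0.0, dict(zip(alleles, p)), 0, True, blank_mode,
            n_scored, blanks, note="no-homozygotes",
        )

    k = len(alleles)
    as_nulls = blank_mode == "blanks-as-nulls"
    # initialize from observed copy counts with a modest null mass
    copies = het.sum(axis=0) + het.sum(axis=1) + 2 * hom
    r = 0.1
    p = copies / copies.sum() * (1 - r)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split apparent homozygotes between (i,i) and (i,null)
        denom = p + 2 * r
        with np.errstate(invalid="ignore"):
            w_true_hom = np.where(denom > 0, p / denom, 1.0)
        e_hom = hom * w_true_hom          # expected true (i,i)
        e_hnull = hom - e_hom             # expected true (i,null)
        if as_nulls:
            e_blank = float(blanks)
            n_eff = n_scored + blanks
        else:
            e_blank = n_scored * (r * r) / max(1 - r * r, 1e-12)
            n_eff = n_scored + e_blank
        # M-step: expected allele-copy counts
        y = het.sum(axis=0) + het.sum(axis=1) + 2 * e_hom + e_hnull
        y_null = e_hnull.sum() + 2 * e_blank
        new_p = y / (2 * n_eff)
        new_r = y_null / (2 * n_eff)
        delta = max(float(np.abs(new_p - p).max()), abs(new_r - r))
        p, r = new_p, float(new_r)
        if delta < tol:
            converged = True
            break

    # boundary check: EM converges sublinearly toward r = 0, so a tiny
    # residual r can survive the tolerance; snap to the boundary when the
    # null-free model explains the data at least as well
    if converged and 0.0 < r < 1e-3:
        cond = not as_nulls
        copies0 = het.sum(axis=0) + het.sum(axis=1) + 2 * hom
        p0 = copies0 / copies0.sum()
        if _loglik(het, hom, blanks, p0, 0.0, cond) >= _loglik(
            het, hom, blanks, p, r, cond
        ) - 1e-9:
            p, r = p0, 0.0

    return NullAlleleEstimate(
        population, locus, r, dict(zip(alleles, p)), it, converged, blank_mode,
        n_scored, blanks,
    )


def cell_loglik(est: NullAlleleEstimate, dataset: GenotypeDataset) -> float:
    """Observed-data log-likelihood of an estimate (for oracle checks)."""
    alleles, het, hom, blanks = _cell_counts(dataset, est.population, est.locus)
    p = np.array([est.visible_freqs.get(a, 0.0) for a in alleles])
    return _loglik(het, hom, blanks, p, est.r, est.blank_mode == "blanks-excluded")


def estimate_all(
    dataset: GenotypeDataset,
    blank_mode: str = "blanks-as-nulls",
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> list[NullAlleleEstimate]:
    return [
        estimate_null_em(dataset, pop, m.name, blank_mode, tol, max_iter)
        for pop in dataset.populations
        for m in dataset.markers
    ]


def corrected_frequencies(
    dataset: GenotypeDataset,
    blank_mode: str = "blanks-as-nulls",
    include_null: bool = False,
    estimates: list[NullAlleleEstimate] | None = None,
) -> AlleleFrequencyTable:
    """Null-corrected allele frequency table.

    With ``include_null=True`` each cell's vector is the EM-corrected
    visible frequencies augmented with the null class under the
    ``NULL_ALLELE`` label (sum = 1 including the null; the INA
    convention used for chord distances).  With ``include_null=False``
    the visible frequencies are renormalized to sum to 1 with the null
    class excluded (the ENA convention used for F_ST).
    """
    if estimates is None:
        estimates = estimate_all(dataset, blank_mode)
    raw = allele_frequencies(dataset)
    by_cell = {(e.population, e.locus): e for e in estimates}
    cells: dict[tuple[str, str], FrequencyCell] = {}
    for key, cell in raw.cells.items():
        if not cell.available:
            cells[key] = cell
            continue
        est = by_cell[key]
        vis = dict(est.visible_freqs)
        if include_null:
            freqs = dict(vis)
            if est.r > 0:
                freqs[NULL_ALLELE] = est.r
        else:
            total = sum(vis.values())
            freqs = {a: f / total for a, f in vis.items()} if total > 0 else vis
        cells[key] = FrequencyCell(freqs, cell.n)
    return AlleleFrequencyTable(raw.populations, raw.loci, cells)


# ---------------------------------------------------------------------
# Artefact diagnosis


@dataclass(frozen=True)
class ArtifactDiagnosis:
    population: str
    locus: str
    verdict: str  # consistent-with-null-alleles | consistent-with-dropout | no-excess
    p_excess: float
    deficit_by_quartile: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    note: str = ""


def diagnose_artifact(
    dataset: GenotypeDataset,
    population: str,
    locus: str,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = None,
) -> ArtifactDiagnosis:
    """Classify a significant homozygote excess by its size-class signature.

    Null alleles depress heterozygote classes regardless of the size
    difference between the two alleles, whereas large-allele dropout
    preferentially removes heterozygotes whose alleles differ most in
    size.  The heterozygote deficit (HWE-expected minus observed count,
    positive part) is partitioned by quartile of the allele-size
    difference; a deficit concentrated (> half) in the top quartile is
    called dropout-like.  This is a deliberately simplified stand-in
    for a full scoring-artefact battery.
    """
    test = hwe_test(dataset, population, locus, n_perm=n_perm, seed=seed)
    if test.p_excess >= alpha:
        return ArtifactDiagnosis(population, locus, "no-excess", test.p_excess)

    alleles, het, hom, _ = _cell_counts(dataset, population, locus)
    copies = het.sum(axis=0) + het.sum(axis=1) + 2 * hom
    n = (het.sum() + hom.sum())
    p = copies / copies.sum()
    k = len(alleles)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    diffs = np.array([abs(alleles[j] - alleles[i]) for i, j in pairs], dtype=float)
    if len(set(diffs.tolist())) < 4:
        return ArtifactDiagnosis(
            population, locus, "consistent-with-null-alleles", test.p_excess,
            note="too few size classes for dropout test",
        )
    expected = np.array([2 * p[i] * p[j] * n for i, j in pairs])
    observed = np.array([het[i, j] for i, j in pairs])
    # quartile boundaries weighted by expected heterozygote mass, so each
    # quartile holds ~equal expected heterozygosity
    order = np.argsort(diffs, kind="stable")
    cum = np.cumsum(expected[order]) / expected.sum()
    bins_sorted = np.minimum((cum * 4 - 1e-9).astype(int), 3)
    bins = np.empty(len(pairs), dtype=int)
    bins[order] = bins_sorted
    # null alleles thin heterozygote classes uniformly, dropout thins the
    # large-size-difference classes specifically; comparing normalized
    # shares cancels the uniform component so only differential thinning
    # registers as a deficit
    exp_q = np.array([expected[bins == b].sum() for b in range(4)])
    obs_q = np.array([observed[bins == b].sum() for b in range(4)], dtype=float)
    n_het = obs_q.sum()
    if n_het == 0:
        return ArtifactDiagnosis(
            population, locus, "consistent-with-null-alleles", test.p_excess,
            note="no heterozygotes observed",
        )
    deficit_q = np.maximum(exp_q / exp_q.sum() - obs_q / n_het, 0.0) * n_het
    by_q = tuple(float(x) for x in deficit_q)
    total = sum(by_q)
    # the top-quartile deficit must dominate AND exceed twice its binomial
    # sampling SD under uniform thinning, else chance concentration of
    # noise would masquerade as dropout
    s_top = exp_q[3] / exp_q.sum()
    noise_sd = math.sqrt(n_het * s_top * (1 - s_top))
    verdict = (
        "consistent-with-dropout"
        if total > 0 and by_q[3] > 0.5 * total and by_q[3] > 2.0 * noise_sd
        else "consistent-with-null-alleles"
    )
    return ArtifactDiagnosis(population, locus, verdict, test.p_excess, by_q)


# ---------------------------------------------------------------------
# Summaries


def summarize_null_frequencies(
    estimates: list[NullAlleleEstimate],
) -> dict[str, pd.DataFrame]:
    """Mean/SD of r per population over loci, and min-max per locus over
    populations.  SD is the sample SD (n-1 denominator); a single value
    has SD 0 by convention."""
    df = pd.DataFrame(
        [{"population": e.population, "locus": e.locus, "r": e.r} for e in estimates]
    )
    by_pop = (
        df.groupby("population", sort=False)["r"]
        .agg(mean_r="mean", sd_r=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    by_locus = (
        df.groupby("locus", sort=False)["r"]
        .agg(min_r="min", max_r="max")
        .reset_index()
    )
    return {"by_population": by_pop, "by_locus": by_locus}
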