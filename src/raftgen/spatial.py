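"""Mantel and partial Mantel permutation tests, and the spatial analysis
of shared alleles (SAShA).

Mantel tests correlate the upper triangles of two distance matrices and
build the null by simultaneous random row/column permutation of the
predictor matrix; the partial variant computes the first-order partial
correlation controlling for a third matrix and permutes the predictor
(Smouse-Long-Sokal style).  SAShA treats every allele copy as an
instance located at its carrier's site and compares the observed mean
geographic distance between same-allele instance pairs (OM) with the
mean over all instance pairs at the same locus (EM), the panmictic
expectation; the null permutes allele identities across instances
within each locus with the site slots fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GenotypeDataset
from .distances import DistanceMatrix


@dataclass
class MantelResult:
    r: float
    p_one_sided: float
    n_permutations: int
    alternative: str
    r_partial: float | None = None
    controlled_for: str | None = None


@dataclass
class SAShAResult:
    om: float
    em: float
    p_two_sided: float
    n_permutations: int
    per_locus_om: dict[str, float]


def _check_pair(m_a: DistanceMatrix, m_b: DistanceMatrix) -> DistanceMatrix:
    if set(m_a.labels) != set(m_b.labels):
        raise ValueError("matrices must share labels")
    return m_b.reorder(m_a.labels) if m_a.labels != m_b.labels else m_b


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant matrix: correlation undefined")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _tail_count(r_perm: np.ndarray, r_obs: float, alternative: str) -> int:
    if alternative == "greater":
        return int((r_perm >= r_obs).sum())
    if alternative == "less":
        return int((r_perm <= r_obs).sum())
    raise ValueError("alternative must be 'greater' or 'less'")


def mantel(
    m_gen: DistanceMatrix,
    m_x: DistanceMatrix,
    n_perm: int = 30000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of matrix correlation with a one-sided permutation p.

    p = (1 + #{r_perm in tail}) / (1 + n_perm); the predictor matrix
    ``m_x`` is the one permuted.
    """
    m_x = _check_pair(m_gen, m_x)
    n = len(m_gen.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    iu = np.triu_indices(n, k=1)
    g = m_gen.values[iu]
    x = m_x.values[iu]
    r_obs = _corr(g, x)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(n)
        r_perm[b] = _corr(g, m_x.values[np.ix_(idx, idx)][iu])
    p = (1 + _tail_count(r_perm, r_obs, alternative)) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, alternative)


def _partial_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0.0:
        raise ValueError("partial correlation undefined: a control correlation is +-1")
    return (r_xy - r_xz * r_yz) / math.sqrt(denom)


def partial_mantel(
    m_gen: DistanceMatrix,
    m_x: DistanceMatrix,
    m_z: DistanceMatrix,
    n_perm: int = 30000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel test: correlation of gen and x controlling for z."""
    m_x = _check_pair(m_gen, m_x)
    m_z = _check_pair(m_gen, m_z)
    n = len(m_gen.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    iu = np.triu_indices(n, k=1)
    g, x, z = m_gen.values[iu], m_x.values[iu], m_z.values[iu]
    r_gz = _corr(g, z)
    r_obs = _partial_r(_corr(g, x), _corr(x, z), r_gz)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(n)
        xp = m_x.values[np.ix_(idx, idx)][iu]
        r_perm[b] = _partial_r(_corr(g, xp), _corr(xp, z), r_gz)
    p = (1 + _tail_count(r_perm, r_obs, alternative)) / (1 + n_perm)
    return MantelResult(
        _corr(g, x), p, n_perm, alternative, r_partial=r_obs,
        controlled_for=m_z.kind,
    )


def pearson_matched(
    m_a: DistanceMatrix, m_b: DistanceMatrix
) -> tuple[float, float]:
    """Plain Pearson correlation of two matched upper triangles with a
    two-tailed t-distribution p-value (n - 2 df); used for comparing
    the two species' pairwise genetic distances."""
    m_b = _check_pair(m_a, m_b)
    iu = np.triu_indices(len(m_a.labels), k=1)
    r, p = stats.pearsonr(m_a.values[iu], m_b.values[iu])
    return float(r), float(p)


# ---------------------------------------------------------------------
# SAShA


def _locus_instances(
    dataset: GenotypeDataset, site_index: dict[str, int]
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(locus name, site index per allele copy, allele index per copy)."""
    out = []
    for j, m in enumerate(dataset.markers):
        idx = {a: i for i, a in enumerate(m.allele_labels)}
        sites_l, alleles_l = [], []
        for ind in dataset.individuals:
            g = ind.genotypes[j]
            if g.is_missing:
                continue
            s = site_index[ind.site_id]
            for a in g.alleles():
                sites_l.append(s)
                alleles_l.append(idx[a])
        out.append((m.name, np.asarray(sites_l), np.asarray(alleles_l)))
    return out


def _shared_pair_stats(
    s: np.ndarray, a: np.ndarray, n_sites: int, n_alleles: int, dmat: np.ndarray
) -> tuple[float, float]:
    """Sum of distances and count over unordered same-allele instance pairs."""
    c = np.zeros((n_sites, n_alleles))
    np.add.at(c, (s, a), 1.0)
    dist_sum = 0.5 * float((c * (dmat @ c)).sum())
    m = c.sum(axis=0)
    n_pairs = float((m * (m - 1) / 2).sum())
    return dist_sum, n_pairs


def sasha(
    dataset: GenotypeDataset,
    geo_matrix: DistanceMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
) -> SAShAResult:
    """Observed vs expected mean distance between allele co-occurrences.

    OM pools same-allele pair distances across alleles and loci; EM is
    the all-pairs mean per locus, averaged over loci with each locus
    weighted by its same-allele pair count so OM and EM are directly
    comparable.  Within-site pairs enter at distance 0.  Two-sided
    p = (1 + #{|OM_perm - EM| >= |OM_obs - EM|}) / (1 + n_perm).
    """
    site_ids = [s.site_id for s in dataset.sites]
    geo = geo_matrix.reorder([l for l in site_ids if l in geo_matrix.labels]) \
        if geo_matrix.labels != site_ids else geo_matrix
    missing = set(site_ids) - set(geo.labels)
    if missing:
        raise ValueError(f"sites without geographic position: {sorted(missing)}")
    site_index = {sid: geo.labels.index(sid) for sid in site_ids}
    dmat = geo.values
    n_sites = len(geo.labels)

    loci = _locus_instances(dataset, site_index)
    per_locus_om: dict[str, float] = {}
    used: list[tuple[str, np.ndarray, np.ndarray, int]] = []
    tot_shared_sum = 0.0
    tot_shared_pairs = 0.0
    em_weighted = 0.0
    for name, s, a, in loci:
        if len(s) == 0:
            warnings.warn(f"locus {name}: no scored instances, skipped")
            continue
        n_all = int(a.max()) + 1
        dist_sum, n_pairs = _shared_pair_stats(s, a, n_sites, n_all, dmat)
        if n_pairs == 0:
            warnings.warn(f"locus {name}: every allele is a singleton, skipped")
            continue
        t = np.bincount(s, minlength=n_sites).astype(float)
        all_sum = 0.5 * float(t @ dmat @ t)
        n_total = len(s)
        all_pairs = n_total * (n_total - 1) / 2.0
        em_l = all_sum / all_pairs
        per_locus_om[name] = dist_sum / n_pairs
        tot_shared_sum += dist_sum
        tot_shared_pairs += n_pairs
        em_weighted += em_l * n_pairs
        used.append((name, s, a, n_all))
    if not used:
        raise ValueError("no locus contributes same-allele pairs")

    om = tot_shared_sum / tot_shared_pairs
    em = em_weighted / tot_shared_pairs
    obs_dev = abs(om - em)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_sum = 0.0
        perm_pairs = 0.0
        for _, s, a, n_all in used:
            ap = rng.permutation(a)
            ds, npair = _shared_pair_stats(s, ap, n_sites, n_all, dmat)
            perm_sum += ds
            perm_pairs += npair
        om_p = perm_sum / perm_pairs
        if abs(om_p - em) >= obs_dev - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return SAShAResult(float(om), float(em), p, n_perm, per_locus_om)
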