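"""No-admixture Bayesian clustering of multilocus genotypes.

A Gibbs sampler for the classic model: each individual belongs wholly
to one of K clusters; each cluster has its own allele-frequency vector
per locus with a symmetric Dirichlet(lambda) prior; genotypes within a
cluster follow HWE (p_a^2 for homozygotes, 2 p_a p_b for
heterozygotes); missing loci contribute likelihood 1; the label prior
is uniform.  The sampler alternates (i) cluster allele frequencies
from their Dirichlet full conditional given current memberships and
(ii) memberships from their multinomial full conditional given the
frequencies.  Q-values are posterior membership frequencies over
post-burn-in sweeps, with label switching resolved sweep-to-sweep by
greedy matching of cluster frequency vectors (minimum total variation
distance) and chains aligned to the first chain the same way.

Apparent genotypes are used at face value: no null-allele modelling
happens inside the clustering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .data import GenotypeDataset, subset_individuals

AMBIGUOUS = "AMBIGUOUS"


@dataclass
class ClusterModel:
    k: int = 2
    lam: float = 1.0  # Dirichlet prior parameter for allele frequencies
    n_burnin: int = 2000
    n_iter: int = 10000
    n_chains: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.lam <= 0 or self.n_iter <= 0:
            raise ValueError("invalid cluster model parameters")


@dataclass
class AssignmentResult:
    individual_ids: list[str]
    q: np.ndarray  # (n, K), mean over chains, rows sum to 1
    q_per_chain: np.ndarray  # (chains, n, K)
    converged: bool
    min_chain_correlation: float
    model: ClusterModel


def _encode(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Genotypes as two (n, L) index arrays, -1 for missing."""
    n, L = len(dataset.individuals), len(dataset.markers)
    a1 = np.full((n, L), -1, dtype=int)
    a2 = np.full((n, L), -1, dtype=int)
    sizes = []
    for j, m in enumerate(dataset.markers):
        idx = {a: i for i, a in enumerate(m.allele_labels)}
        sizes.append(len(m.allele_labels))
        for i, ind in enumerate(dataset.individuals):
            g = ind.genotypes[j]
            if not g.is_missing:
                a1[i, j] = idx[g.allele_a]
                a2[i, j] = idx[g.allele_b]
    return a1, a2, sizes


def _run_chain(
    a1: np.ndarray,
    a2: np.ndarray,
    sizes: list[int],
    model: ClusterModel,
    rng: np.random.Generator,
    order: np.ndarray,
) -> np.ndarray:
    """One MCMC chain; returns the (n, K) Q matrix.

    Per-individual random draws are assigned through ``order`` (the
    argsort of individual ids) so that the sampler is equivariant under
    permutation of the input rows at a fixed seed: allele-count sums,
    and hence the Dirichlet draws, are order-invariant, and each
    individual receives the same uniform deviate regardless of its
    position in the dataset.
    """
    n, L = a1.shape
    K = model.k
    maxA = max(sizes)

    z = np.empty(n, dtype=int)
    z[order] = rng.integers(0, K, size=n)
    qcount = np.zeros((n, K))
    ref = None  # reference frequency block for label alignment

    total = model.n_burnin + model.n_iter
    for sweep in range(total):
        # (i) allele frequencies per cluster x locus
        p = np.zeros((K, L, maxA))
        logp = np.full((K, L, maxA), -np.inf)
        for k in range(K):
            mask = z == k
            for l in range(L):
                A = sizes[l]
                obs = np.concatenate([a1[mask, l], a2[mask, l]])
                obs = obs[obs >= 0]
                counts = np.bincount(obs, minlength=A)
                draw = rng.gamma(model.lam + counts)
                draw = draw / draw.sum()
                p[k, l, :A] = draw
                logp[k, l, :A] = np.log(np.maximum(draw, 1e-300))

        # (ii) memberships
        ll = np.zeros((n, K))
        for k in range(K):
            lp = logp[k]
            v1 = np.where(a1 >= 0, lp[np.arange(L)[None, :], np.maximum(a1, 0)], 0.0)
            v2 = np.where(a2 >= 0, lp[np.arange(L)[None, :], np.maximum(a2, 0)], 0.0)
            ll[:, k] = (v1 + v2).sum(axis=1)
        ll -= ll.max(axis=1, keepdims=True)
        w = np.exp(ll)
        w /= w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        u = np.empty(n)
        u[order] = rng.random(n)
        z = (u[:, None] > cum[:, :-1]).sum(axis=1)

        # label alignment against the running reference
        flat = p.reshape(K, -1)
        if ref is None:
            perm = np.arange(K)
        else:
            tv = np.abs(flat[:, None, :] - ref[None, :, :]).sum(axis=2)
            rows, cols = linear_sum_assignment(tv)
            perm = np.empty(K, dtype=int)
            perm[rows] = cols  # cluster row -> reference label col
        ref = np.empty_like(flat)
        ref[perm] = flat
        z_aligned = perm[z]
        if sweep >= model.n_burnin:
            qcount[np.arange(n), z_aligned] += 1
        z = z_aligned
        # keep p consistent with relabelled z for the next sweep's counts:
        # counts are recomputed from z, so nothing else to do

    return qcount / model.n_iter


def fit_no_admixture(dataset: GenotypeDataset, model: ClusterModel) -> AssignmentResult:
    """Fit the no-admixture model with ``model.n_chains`` independent chains.

    Chains get distinct sub-seeds spawned from ``model.seed``.  A
    convergence warning flag (not an exception) is set when the minimum
    over chain pairs of the Pearson correlation of flattened Q matrices
    falls below 0.99.
    """
    if not dataset.individuals:
        raise ValueError("empty dataset")
    a1, a2, sizes = _encode(dataset)
    ids = [ind.individual_id for ind in dataset.individuals]
    order = np.argsort(np.array(ids))
    ss = np.random.SeedSequence(model.seed)
    chains = []
    for child in ss.spawn(model.n_chains):
        rng = np.random.default_rng(child)
        chains.append(_run_chain(a1, a2, sizes, model, rng, order))
    q_chains = np.stack(chains)

    # align chains 1.. to chain 0 by minimal total |Q| difference
    K = model.k
    for c in range(1, len(q_chains)):
        cost = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                cost[i, j] = np.abs(q_chains[c][:, i] - q_chains[0][:, j]).sum()
        rows, cols = linear_sum_assignment(cost)
        inv = np.empty(K, dtype=int)
        inv[cols] = rows  # reference label j takes the chain's column matched to it
        q_chains[c] = q_chains[c][:, inv]

    min_corr = 1.0
    if len(q_chains) > 1 and K > 1:
        for c1, c2 in itertools.combinations(range(len(q_chains)), 2):
            x, y = q_chains[c1].ravel(), q_chains[c2].ravel()
            if x.std() == 0 or y.std() == 0:
                continue
            min_corr = min(min_corr, float(np.corrcoef(x, y)[0, 1]))
    q = q_chains.mean(axis=0)
    q = q / q.sum(axis=1, keepdims=True)
    return AssignmentResult(ids, q, q_chains, min_corr >= 0.99, min_corr, model)


def assign_species(result: AssignmentResult, threshold: float = 0.8) -> list[object]:
    """Per-individual cluster label, or AMBIGUOUS when max Q <= threshold.

    The boundary Q == threshold is discarded (the qualifying rule is
    strictly 'greater than').
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    labels: list[object] = []
    for row in result.q:
        k = int(np.argmax(row))
        labels.append(k if row[k] > threshold else AMBIGUOUS)
    return labels


def split_by_assignment(
    dataset: GenotypeDataset,
    result: AssignmentResult,
    threshold: float = 0.8,
) -> tuple[dict[int, GenotypeDataset], pd.DataFrame]:
    """Split into per-cluster datasets (ambiguous individuals excluded)
    and emit the assigned-label x collection-habitat cross-tabulation."""
    labels = assign_species(result, threshold)
    by_id = dict(zip(result.individual_ids, labels))
    rows = [
        {"habitat": ind.habitat, "assigned": str(by_id[ind.individual_id])}
        for ind in dataset.individuals
    ]
    crosstab = pd.crosstab(
        pd.DataFrame(rows)["habitat"], pd.DataFrame(rows)["assigned"]
    )
    out: dict[int, GenotypeDataset] = {}
    for k in range(result.model.k):
        keep = [i for i, lab in by_id.items() if lab == k]
        if keep:
            out[k] = subset_individuals(dataset, keep)
    return out, crosstab


def q_table(result: AssignmentResult) -> pd.DataFrame:
    df = pd.DataFrame(
        result.q, columns=[f"Q{k + 1}" for k in range(result.q.shape[1])]
    )
    df.insert(0, "individual_id", result.individual_ids)
    return df
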