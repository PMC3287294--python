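"""HWE testing, EM null-allele estimation and artefact diagnosis."""

import itertools

import numpy as np
import pytest

from raftgen.data import Genotype, GenotypeDataset, Individual
from raftgen.null_alleles import (
    cell_loglik,
    diagnose_artifact,
    estimate_null_em,
    hwe_test,
    summarize_null_frequencies,
    NullAlleleEstimate,
)
from raftgen.synthetic import SimConfig, simulate

from conftest import make_dataset


def exact_hom_distribution(alleles):
    """Exact distribution of homozygous-pair counts over all pairings of
    an allele pool (oracle by enumeration of perfect matchings)."""
    from collections import Counter

    n = len(alleles) // 2
    outcomes = Counter()
    seen = 0
    for perm in itertools.permutations(alleles):
        pairs = [tuple(sorted(perm[2 * i: 2 * i + 2])) for i in range(n)]
        outcomes[sum(a == b for a, b in pairs)] += 1
        seen += 1
    return {k: v / seen for k, v in outcomes.items()}


class TestHWE:
    def test_two_homozygotes_match_enumeration(self):
        # pool {1,1,2,2}: P(2 homozygous pairs) = 1/3 by enumeration
        dist = exact_hom_distribution([1, 1, 2, 2])
        assert dist[2] == pytest.approx(1 / 3)
        ds = make_dataset({"A": [[(1, 1)], [(2, 2)]]})
        res = hwe_test(ds, "A", "L1", n_perm=4000, seed=1)
        assert res.p_excess < 0.5
        assert res.p_excess == pytest.approx(1 / 3, abs=0.04)

    def test_monomorphic_p_one(self):
        ds = make_dataset({"A": [[(1, 1)], [(1, 1)]]})
        assert hwe_test(ds, "A", "L1", n_perm=100, seed=0).p_excess == 1.0

    def test_single_individual_rejected(self):
        ds = make_dataset({"A": [[(1, 2)]]})
        with pytest.raises(ValueError):
            hwe_test(ds, "A", "L1")

    def test_p_never_zero(self):
        ds = make_dataset({"A": [[(1, 1)]] * 20 + [[(2, 2)]] * 20})
        res = hwe_test(ds, "A", "L1", n_perm=500, seed=2)
        assert 0.0 < res.p_excess <= 1.0


class TestNullEM:
    def grid_argmax(self, ds, blank_mode, resolution=1e-4):
        """Brute-force likelihood grid over (p1, r) for a biallelic cell."""
        best = (-np.inf, None)
        for r in np.arange(0.0, 0.6, resolution):
            p1 = (1.0 - r) / 2.0  # symmetric counts: p1 = p2 at the optimum
            est = NullAlleleEstimate("A", "L1", r, {1: p1, 2: 1 - r - p1},
                                     0, True, blank_mode)
            ll = cell_loglik(est, ds)
            if ll > best[0]:
                best = (ll, r)
        return best[1]

    def test_em_matches_likelihood_grid(self):
        ds = make_dataset(
            {"A": [[(1, 2)]] * 32 + [[(1, 1)]] * 34 + [[(2, 2)]] * 34}
        )
        est = estimate_null_em(ds, "A", "L1", blank_mode="blanks-excluded")
        assert est.converged
        assert est.r == pytest.approx(0.2, abs=0.03)
        r_grid = self.grid_argmax(ds, "blanks-excluded")
        assert est.r == pytest.approx(r_grid, abs=1e-3)

    def test_em_matches_grid_blanks_as_nulls(self):
        ds = make_dataset(
            {"A": [[(1, 2)]] * 30 + [[(1, 1)]] * 30 + [[(2, 2)]] * 30 + [[None]] * 10}
        )
        est = estimate_null_em(ds, "A", "L1", blank_mode="blanks-as-nulls")
        r_grid = self.grid_argmax(ds, "blanks-as-nulls")
        assert est.r == pytest.approx(r_grid, abs=1e-3)

    def test_loglik_monotone_across_iterations(self):
        ds = make_dataset(
            {"A": [[(1, 2)]] * 20 + [[(1, 1)]] * 25 + [[(2, 2)]] * 25 + [[None]] * 5}
        )
        lls = []
        for n_iter in range(1, 40):
            est = estimate_null_em(ds, "A", "L1", max_iter=n_iter)
            lls.append(cell_loglik(est, ds))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_no_excess_gives_zero(self):
        # exact HWE proportions of two alleles at 0.5: 25/50/25
        ds = make_dataset(
            {"A": [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25}
        )
        est = estimate_null_em(ds, "A", "L1", blank_mode="blanks-excluded")
        assert est.r < 1e-6
        assert est.total == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_allele_relabelling(self):
        rows = [[(1, 2)]] * 15 + [[(1, 1)]] * 20 + [[(2, 2)]] * 10 + [[None]] * 5
        ds = make_dataset({"A": rows})
        relabelled = [
            [None if row[0] is None else (row[0][0] * 7, row[0][1] * 7)]
            for row in rows
        ]
        ds2 = make_dataset({"A": relabelled})
        e1 = estimate_null_em(ds, "A", "L1")
        e2 = estimate_null_em(ds2, "A", "L1")
        assert e1.r == pytest.approx(e2.r, abs=1e-12)

    def test_monomorphic_flagged(self):
        ds = make_dataset({"A": [[(1, 1)]] * 10 + [[None]] * 2})
        est = estimate_null_em(ds, "A", "L1")
        assert est.r == 0.0 and est.note == "monomorphic"

    def test_parameter_recovery(self):
        """Mean |r_hat - r| < 0.02 at n=500, r=0.2, 10 visible alleles."""
        errs = []
        for i in range(100):
            ds, _ = simulate(SimConfig(n_pops=1, n_per_pop=500, n_loci=1,
                                       alleles_per_locus=10, fst=0.0,
                                       null_freq=0.2, seed=2000 + i))
            errs.append(abs(estimate_null_em(ds, "site_1", "loc1").r - 0.2))
        assert np.mean(errs) < 0.02


class TestDiagnosis:
    def test_null_mechanism_recognized(self):
        rng = np.random.default_rng(3)
        hits = 0
        for i in range(60):
            ds, _ = simulate(SimConfig(n_pops=1, n_per_pop=200, n_loci=1,
                                       alleles_per_locus=10, fst=0.0,
                                       null_freq=0.25, seed=30000 + i))
            d = diagnose_artifact(ds, "site_1", "loc1", n_perm=500,
                                  seed=int(rng.integers(2**31)))
            hits += d.verdict == "consistent-with-null-alleles"
        assert hits >= 48  # >= 80% of replicate cells

    def test_dropout_mechanism_recognized(self):
        rng = np.random.default_rng(3)
        hits = 0
        for i in range(60):
            ds, _ = simulate(SimConfig(n_pops=1, n_per_pop=400, n_loci=1,
                                       alleles_per_locus=10, fst=0.0, seed=40000 + i))
            labels = sorted(ds.markers[0].allele_labels)
            pairs = [(a, b) for ai, a in enumerate(labels) for b in labels[ai + 1:]]
            thr = np.quantile(np.array([b - a for a, b in pairs]), 0.75)
            rloc = np.random.default_rng(50000 + i)
            new = []
            for ind in ds.individuals:
                g = ind.genotypes[0]
                if (not g.is_missing and not g.is_homozygous
                        and (g.allele_b - g.allele_a) >= thr and rloc.random() < 0.5):
                    g = Genotype(g.allele_b, g.allele_b)
                new.append(Individual(ind.individual_id, ind.site_id,
                                      ind.habitat, (g,)))
            ds2 = GenotypeDataset(new, ds.markers, ds.sites)
            d = diagnose_artifact(ds2, "site_1", "loc1", n_perm=500,
                                  seed=int(rng.integers(2**31)))
            hits += d.verdict == "consistent-with-dropout"
        assert hits >= 42  # >= 70% at this sample size; see methods note

    def test_hwe_data_mostly_no_excess(self):
        rng = np.random.default_rng(5)
        hits = 0
        for i in range(60):
            ds, _ = simulate(SimConfig(n_pops=1, n_per_pop=100, n_loci=1,
                                       alleles_per_locus=8, fst=0.0, seed=60000 + i))
            d = diagnose_artifact(ds, "site_1", "loc1", n_perm=500,
                                  seed=int(rng.integers(2**31)))
            hits += d.verdict == "no-excess"
        assert hits >= 51  # ~ 1 - alpha


class TestSummaries:
    def test_single_estimate(self):
        ests = [NullAlleleEstimate("A", "L1", 0.1, {}, 1, True, "blanks-as-nulls")]
        out = summarize_null_frequencies(ests)
        row = out["by_population"].iloc[0]
        assert row["mean_r"] == 0.1 and row["sd_r"] == 0.0

    def test_sample_sd_convention(self):
        ests = [
            NullAlleleEstimate("A", "L1", 0.0, {}, 1, True, "blanks-as-nulls"),
            NullAlleleEstimate("A", "L2", 0.2, {}, 1, True, "blanks-as-nulls"),
        ]
        out = summarize_null_frequencies(ests)
        row = out["by_population"].iloc[0]
        assert row["mean_r"] == pytest.approx(0.1)
        assert row["sd_r"] == pytest.approx(0.1414, abs=1e-3)

    def test_matches_independent_recount(self):
        from raftgen.null_alleles import estimate_all

        ds, _ = simulate(SimConfig(n_pops=3, n_per_pop=30, n_loci=4,
                                   alleles_per_locus=8, fst=0.02,
                                   null_freq=(0.0, 0.3), seed=77))
        ests = estimate_all(ds)
        out = summarize_null_frequencies(ests)
        for _, row in out["by_locus"].iterrows():
            rs = [e.r for e in ests if e.locus == row["locus"]]
            assert row["min_r"] == pytest.approx(min(rs))
            assert row["max_r"] == pytest.approx(max(rs))
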