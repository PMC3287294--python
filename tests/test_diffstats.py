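"""Heterozygosity, D_est, Weir's theta, G''_ST and N_m."""

import math

import numpy as np
import pytest

from raftgen.data import allele_frequencies, subset_individuals
from raftgen.diffstats import (
    fst_bootstrap_ci,
    g_double_prime_st,
    heterozygosity,
    jost_d,
    migrants_nm,
    nm_matrix,
    pairwise_report,
    weir_fst,
    weir_fst_components,
)
from raftgen.synthetic import SimConfig, simulate

from conftest import make_dataset


def direct_h_stats(table, pops, locus):
    """Independent direct-summation oracle for bias-corrected H_S/H_T."""
    labels = sorted({a for p in pops for a in table.cell(p, locus).freqs})
    mat = np.array([[table.cell(p, locus).freqs.get(a, 0.0) for a in labels]
                    for p in pops])
    ns = [table.cell(p, locus).n for p in pops]
    k = len(pops)
    n_h = k / sum(1.0 / n for n in ns)
    h_s = n_h / (n_h - 1) * (1 - np.mean([sum(f * f for f in row) for row in mat]))
    pbar = mat.mean(axis=0)
    h_t = 1 - sum(f * f for f in pbar) + h_s / (k * n_h)
    return h_s, h_t


class TestHeterozygosity:
    def test_fixed_difference_limits(self, fixed_difference_pair):
        het = heterozygosity(allele_frequencies(fixed_difference_pair))
        assert het.h_s == pytest.approx(0.0, abs=1e-12)
        assert het.h_t == pytest.approx(0.5, abs=0.01)

    def test_matches_direct_summation(self):
        ds, _ = simulate(SimConfig(n_pops=4, n_per_pop=25, n_loci=3,
                                   alleles_per_locus=8, fst=0.05,
                                   blank_failure_rate=0.1, seed=13))
        table = allele_frequencies(ds)
        het = heterozygosity(table)
        for j, locus in enumerate(table.loci):
            h_s, h_t = direct_h_stats(table, table.populations, locus)
            assert het.h_s_per_locus[j] == pytest.approx(h_s, abs=1e-12)
            assert het.h_t_per_locus[j] == pytest.approx(h_t, abs=1e-12)

    def test_unavailable_cell_is_error(self):
        ds = make_dataset({"A": [[(1, 2)], [(1, 1)]], "B": [[None], [None]]})
        with pytest.raises(ValueError, match="no scored data"):
            heterozygosity(allele_frequencies(ds))


class TestJostD:
    def test_fixed_difference_gives_one(self, fixed_difference_pair):
        d, (lo, hi), per_locus = jost_d(fixed_difference_pair, n_boot=50, seed=1)
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_identical_populations_near_zero(self, identical_pair):
        d, _, _ = jost_d(identical_pair, n_boot=50, seed=1)
        assert abs(d) < 0.01

    def test_ci_contains_point(self):
        ds, _ = simulate(SimConfig(n_pops=4, n_per_pop=30, n_loci=7,
                                   alleles_per_locus=20, fst=0.01, seed=17))
        d, (lo, hi), _ = jost_d(ds, n_boot=200, seed=5)
        assert lo <= d <= hi

    def test_invariant_to_population_order(self):
        ds, _ = simulate(SimConfig(n_pops=3, n_per_pop=20, n_loci=3,
                                   alleles_per_locus=6, fst=0.05, seed=19))
        d1, _, _ = jost_d(ds, ["site_1", "site_2", "site_3"], n_boot=10, seed=0)
        d2, _, _ = jost_d(ds, ["site_3", "site_1", "site_2"], n_boot=10, seed=0)
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestWeirFst:
    def test_fixed_difference_approaches_one(self, fixed_difference_pair):
        assert weir_fst(fixed_difference_pair) > 0.9

    def test_duplicated_population_near_zero(self, identical_pair):
        assert abs(weir_fst(identical_pair)) < 0.02

    def test_too_small_cells_error(self):
        ds = make_dataset({"A": [[(1, 2)]], "B": [[(1, 1)]]})
        with pytest.raises(ValueError):
            weir_fst(ds)

    def test_ena_close_to_raw_without_nulls(self):
        ds, _ = simulate(SimConfig(n_pops=4, n_per_pop=40, n_loci=5,
                                   alleles_per_locus=8, fst=0.05, seed=23))
        raw = weir_fst(ds)
        ena = weir_fst(ds, use_ena=True)
        assert ena == pytest.approx(raw, abs=0.02)

    def test_loci_bootstrap_ci_contains_point(self):
        ds, _ = simulate(SimConfig(n_pops=4, n_per_pop=30, n_loci=7,
                                   alleles_per_locus=10, fst=0.05, seed=29))
        nums, dens, _ = weir_fst_components(ds)
        point = nums.sum() / dens.sum()
        lo, hi = fst_bootstrap_ci(nums, dens, n_boot=500, seed=4)
        assert lo <= point <= hi


class TestGDoublePrime:
    @pytest.mark.parametrize(
        "h_t,h_s,k,expected,tol",
        [
            (0.749, 0.732, 4, 0.113, 0.002),  # printed kelp-species values
            (0.755, 0.737, 4, 0.118, 0.002),  # printed rock-species values
            (0.5, 0.0, 2, 1.0, 1e-12),        # fixed differences
        ],
    )
    def test_worked_examples(self, h_t, h_s, k, expected, tol):
        assert g_double_prime_st(h_t, h_s, k) == pytest.approx(expected, abs=tol)

    def test_no_differentiation(self):
        assert g_double_prime_st(0.6, 0.6, 4) == 0.0
        assert g_double_prime_st(0.0, 0.0, 2) == 0.0

    def test_monotone_in_h_t(self):
        vals = [g_double_prime_st(ht, 0.5, 4) for ht in (0.55, 0.6, 0.7, 0.8)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            g_double_prime_st(0.5, 1.0, 4)
        with pytest.raises(ValueError):
            g_double_prime_st(0.5, 0.4, 1)


class TestMigrantsNm:
    def test_worked_examples(self):
        assert migrants_nm(0.113, 0.011) == pytest.approx(20.2, abs=0.05)
        assert migrants_nm(0.118, 0.007) == pytest.approx(31.5, abs=0.05)

    def test_nonpositive_fst_is_indefinite(self):
        assert migrants_nm(0.1, 0.0) == math.inf
        assert migrants_nm(0.1, -0.01) == math.inf


@pytest.fixture(scope="module")
def report():
    ds, _ = simulate(SimConfig(n_pops=4, n_per_pop=25, n_loci=5,
                               alleles_per_locus=10, fst=0.02,
                               null_freq=0.1, seed=31))
    return ds, pairwise_report(ds, n_boot=100, seed=3, hwe_perms=200)


class TestPairwiseReport:
    def test_row_combinatorics(self, report):
        ds, rep = report
        assert len(rep) == 1 + 6  # global + C(4,2) pairs
        assert (rep.loc[rep.scope == "global", "k"] == 4).all()
        assert (rep.loc[rep.scope != "global", "k"] == 2).all()

    def test_nm_matrix_shape_and_symmetry(self, report):
        ds, rep = report
        mat = nm_matrix(rep, ds.populations)
        assert list(mat.index) == ds.populations
        assert (mat.values == mat.values.T).all()

    def test_cis_bracket_points(self, report):
        _, rep = report
        assert (rep.d_est_lo <= rep.d_est).all() and (rep.d_est <= rep.d_est_hi).all()
        assert (rep.fst_ena_lo <= rep.fst_ena).all()
        assert (rep.fst_ena <= rep.fst_ena_hi).all()

    def test_weak_migration_link_has_lowest_nm(self):
        hits = 0
        for i in range(10):
            ds, _ = simulate(SimConfig(n_pops=3, n_per_pop=40, n_loci=7,
                                       alleles_per_locus=10, fst=0.02, seed=500 + i))
            # make site_3 strongly diverged: amplify its frequency deviations
            from raftgen.data import Genotype, GenotypeDataset, Individual
            ds2, _ = simulate(SimConfig(n_pops=3, n_per_pop=40, n_loci=7,
                                        alleles_per_locus=10, fst=0.3, seed=900 + i))
            merged = [
                ind if ind.site_id != "site_3" else
                Individual(ind.individual_id, ind.site_id, ind.habitat,
                           ds2.individuals[j].genotypes)
                for j, ind in enumerate(ds.individuals)
            ]
            markers = [
                type(m)(m.name, tuple(sorted(set(m.allele_labels)
                                             | set(m2.allele_labels))))
                for m, m2 in zip(ds.markers, ds2.markers)
            ]
            ds3 = GenotypeDataset(merged, markers, ds.sites)
            rep = pairwise_report(ds3, n_boot=20, seed=i, hwe_perms=100)
            pairs = rep[rep.scope != "global"]
            worst = pairs.loc[pairs.n_m.idxmin(), "scope"]
            hits += "site_3" in worst
        assert hits >= 9  # the isolated population shows the lowest N_m
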