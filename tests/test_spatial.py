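"""Mantel tests, partial Mantel tests and SAShA."""

import itertools

import numpy as np
import pytest

from raftgen.data import SampleSite
from raftgen.distances import DistanceMatrix, great_circle_matrix
from raftgen.spatial import mantel, partial_mantel, pearson_matched, sasha
from raftgen.synthetic import SimConfig, simulate

from conftest import make_dataset


def random_distance_matrix(rng, labels, kind="geographic_km"):
    n = len(labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.random(len(iu[0]))
    return DistanceMatrix(labels, m + m.T, kind)


def mantel_exact_p(m_gen, m_x, alternative="greater"):
    """Oracle: exact permutation p over all n! relabellings of m_x."""
    n = len(m_gen.labels)
    iu = np.triu_indices(n, 1)
    g = m_gen.values[iu]

    def corr(x):
        return np.corrcoef(g, x)[0, 1]

    r_obs = corr(m_x.values[iu])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        idx = np.array(perm)
        r = corr(m_x.values[np.ix_(idx, idx)][iu])
        if alternative == "greater":
            count += r >= r_obs - 1e-12
        else:
            count += r <= r_obs + 1e-12
        total += 1
    return count / total


def partial_mantel_exact_p(m_gen, m_x, m_z):
    n = len(m_gen.labels)
    iu = np.triu_indices(n, 1)
    g, z = m_gen.values[iu], m_z.values[iu]

    def pr(x):
        r_xy = np.corrcoef(g, x)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(g, z)[0, 1]
        return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))

    r_obs = pr(m_x.values[iu])
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        idx = np.array(perm)
        hits += pr(m_x.values[np.ix_(idx, idx)][iu]) >= r_obs - 1e-12
        total += 1
    return hits / total


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        m = random_distance_matrix(rng, ["a", "b", "c", "d"])
        res = mantel(m, m, n_perm=500, seed=2)
        assert res.r == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        labels = ["a", "b", "c", "d"]
        for trial in range(5):
            g = random_distance_matrix(rng, labels)
            x = random_distance_matrix(rng, labels)
            exact = mantel_exact_p(g, x)
            res = mantel(g, x, n_perm=30000, seed=trial)
            # MC standard error at p ~ exact over 30k draws
            se = np.sqrt(exact * (1 - exact) / 30000)
            assert res.p_one_sided == pytest.approx(exact, abs=5 * se + 1e-3)

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c", "d"]
        flat = DistanceMatrix(labels, np.ones((4, 4)) - np.eye(4), "gap_indicator")
        rng = np.random.default_rng(0)
        g = random_distance_matrix(rng, labels)
        with pytest.raises(ValueError, match="constant"):
            mantel(g, flat, n_perm=10, seed=0)

    def test_reproducible_at_fixed_seed(self):
        rng = np.random.default_rng(3)
        g = random_distance_matrix(rng, list("abcde"))
        x = random_distance_matrix(rng, list("abcde"))
        r1 = mantel(g, x, n_perm=999, seed=11)
        r2 = mantel(g, x, n_perm=999, seed=11)
        assert r1.p_one_sided == r2.p_one_sided

    def test_label_alignment(self):
        rng = np.random.default_rng(4)
        g = random_distance_matrix(rng, ["a", "b", "c", "d"])
        x = random_distance_matrix(rng, ["a", "b", "c", "d"])
        x_shuffled = x.reorder(["d", "b", "a", "c"])
        assert mantel(g, x, 99, seed=0).r == pytest.approx(
            mantel(g, x_shuffled, 99, seed=0).r
        )


class TestPartialMantel:
    def test_uncorrelated_control_approximates_plain(self):
        rng = np.random.default_rng(5)
        labels = [f"p{i}" for i in range(8)]
        g = random_distance_matrix(rng, labels)
        x = random_distance_matrix(rng, labels)
        z = random_distance_matrix(rng, labels)
        plain = mantel(g, x, 99, seed=1).r
        part = partial_mantel(g, x, z, 99, seed=1)
        assert part.r_partial == pytest.approx(plain, abs=0.35)

    def test_degenerate_control_rejected(self):
        rng = np.random.default_rng(6)
        labels = ["a", "b", "c", "d"]
        g = random_distance_matrix(rng, labels)
        x = random_distance_matrix(rng, labels)
        with pytest.raises(ValueError):
            partial_mantel(g, x, x, n_perm=10, seed=0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        labels = ["a", "b", "c", "d"]
        g = random_distance_matrix(rng, labels)
        x = random_distance_matrix(rng, labels)
        z = random_distance_matrix(rng, labels)
        exact = partial_mantel_exact_p(g, x, z)
        res = partial_mantel(g, x, z, n_perm=30000, seed=9)
        se = np.sqrt(exact * (1 - exact) / 30000)
        assert res.p_one_sided == pytest.approx(exact, abs=5 * se + 1e-3)


class TestPearsonMatched:
    def test_perfect_anticorrelation(self):
        labels = ["a", "b", "c", "d"]
        rng = np.random.default_rng(9)
        m = random_distance_matrix(rng, labels)
        vals = m.values.max() - m.values
        np.fill_diagonal(vals, 0.0)
        flipped = DistanceMatrix(labels, vals, "genetic_DC")
        r, p = pearson_matched(m, flipped)
        assert r == pytest.approx(-1.0)


class TestSasha:
    def test_single_site_degenerate(self):
        ds = make_dataset({"A": [[(1, 2)], [(1, 1)]]})
        geo = DistanceMatrix(["A"], np.zeros((1, 1)), "geographic_km")
        res = sasha(ds, geo, n_perm=99, seed=0)
        assert res.om == 0.0 and res.em == 0.0 and res.p_two_sided == 1.0

    def test_three_instance_toy_by_enumeration(self):
        # allele X: 2 copies at A, 1 at B; allele Y: 1 copy at B; 100 km apart
        sites = [SampleSite("A", 0.0, 0.0), SampleSite("B", 0.9, 0.0)]
        geo = DistanceMatrix(["A", "B"], np.array([[0.0, 100.0], [100.0, 0.0]]),
                             "geographic_km")
        ds = make_dataset({"A": [[(1, 1)]], "B": [[(1, 2)]]}, sites=sites)
        res = sasha(ds, geo, n_perm=99, seed=0)
        # X pairs: {0, 100, 100} km -> OM = 200/3
        assert res.om == pytest.approx(200.0 / 3.0)

    def test_single_shared_allele_om_equals_em(self):
        sites = [SampleSite("A", 0.0, 0.0), SampleSite("B", 0.9, 0.0)]
        geo = great_circle_matrix(sites)
        ds = make_dataset({"A": [[(1, 1)], [(1, 1)]], "B": [[(1, 1)]]}, sites=sites)
        res = sasha(ds, geo, n_perm=99, seed=0)
        assert res.om == pytest.approx(res.em)

    def test_structure_shortens_co_occurrence_distances(self):
        # site-private alleles: same-allele pairs only within sites -> OM < EM
        sites = [SampleSite("A", 0.0, 0.0), SampleSite("B", 0.9, 0.0)]
        geo = great_circle_matrix(sites)
        ds = make_dataset(
            {"A": [[(1, 2)], [(1, 2)]], "B": [[(3, 4)], [(3, 4)]]}, sites=sites
        )
        res = sasha(ds, geo, n_perm=500, seed=1)
        assert res.om == 0.0
        assert res.om < res.em

    def test_om_bounded_by_max_distance(self, paper_like):
        ds, _ = paper_like
        geo = great_circle_matrix(ds.sites)
        res = sasha(ds, geo, n_perm=50, seed=3)
        assert 0 <= res.om <= geo.values.max()
        assert set(res.per_locus_om) <= {m.name for m in ds.markers}
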