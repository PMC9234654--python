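from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from amphigen.datatypes import DistanceMatrix
from amphigen.structure import (
    allele_mismatch_matrix,
    amova,
    aom_distance_matrix,
    fst_distance_matrix,
    fst_matrix,
    fst_permutation_test,
    mantel,
    partial_mantel,
    wc_fst_pair,
)
from amphigen.simulate import SimulationConfig, simulate_bundle

from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent Weir-Cockerham oracle: direct loop transcription of the
# per-allele variance components for r sampled populations


def wc_oracle_theta(pops: list[list[list[tuple[int, int]]]]) -> float:
    """pops[p][i] = list of per-locus genotype tuples for individual i."""
    n_loci = len(pops[0][0])
    sum_a = sum_abc = 0.0
    for locus in range(n_loci):
        samples = []
        alleles = set()
        for pop in pops:
            genos = [ind[locus] for ind in pop if ind[locus] is not None]
            samples.append(genos)
            for g in genos:
                alleles.update(g)
        if len(alleles) < 2 or any(len(s) < 2 for s in samples):
            continue
        r = len(samples)
        n_i = [len(s) for s in samples]
        n_bar = sum(n_i) / r
        n_c = (sum(n_i) - sum(v * v for v in n_i) / sum(n_i)) / (r - 1)
        for allele in sorted(alleles):
            p_i = []
            h_i = []
            for genos in samples:
                count = sum(int(g[0] == allele) + int(g[1] == allele) for g in genos)
                het = sum(1 for g in genos if (allele in g) and g[0] != g[1])
                p_i.append(count / (2 * len(genos)))
                h_i.append(het / len(genos))
            p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
            s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
            h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
            a = (n_bar / n_c) * (
                s2
                - (1 / (n_bar - 1))
                * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - ((r - 1) / r) * s2
                - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
            )
            c = h_bar / 2
            sum_a += a
            sum_abc += a + b + c
    return sum_a / sum_abc


def random_two_pop_dataset(rng, n_loci=2, n_per=8, n_alleles=4):
    sites = {}
    pops = []
    for site in ("P1", "P2"):
        rows = []
        for _ in range(n_per):
            row = []
            for _ in range(n_loci):
                if rng.random() < 0.05:
                    row.append(None)
                else:
                    a, b = (int(v) for v in rng.integers(1, n_alleles + 1, size=2))
                    row.append((min(a, b), max(a, b)))
            rows.append(row)
        sites[site] = rows
        pops.append(rows)
    return make_dataset(sites), pops


class TestWcFst:
    def test_fixed_differences_give_theta_one(self):
        ds = make_dataset(
            {"P1": [[(1, 1), (3, 3)]] * 6, "P2": [[(2, 2), (4, 4)]] * 6}
        )
        assert wc_fst_pair(ds, "P1", "P2") == pytest.approx(1.0)

    def test_identical_groups_theta_nonpositive(self):
        rows = [[(1, 2), (2, 3)], [(1, 1), (3, 3)], [(2, 2), (2, 3)], [(1, 2), (2, 2)]]
        ds = make_dataset({"P1": rows, "P2": [list(r) for r in rows]})
        assert wc_fst_pair(ds, "P1", "P2") <= 1e-12

    def test_matches_independent_oracle_on_random_datasets(self, rng):
        for _ in range(50):
            ds, pops = random_two_pop_dataset(rng)
            theta = wc_fst_pair(ds, "P1", "P2")
            if theta is None:
                continue
            assert theta == pytest.approx(wc_oracle_theta(pops), abs=1e-12)

    def test_symmetric_in_group_order(self, rng):
        ds, _ = random_two_pop_dataset(rng)
        assert wc_fst_pair(ds, "P1", "P2") == pytest.approx(
            wc_fst_pair(ds, "P2", "P1"), abs=1e-15
        )

    def test_no_usable_locus_returns_none(self):
        ds = make_dataset({"P1": [[(1, 1)]] * 3, "P2": [[(1, 1)]] * 3})
        assert wc_fst_pair(ds, "P1", "P2") is None


class TestFstMatrix:
    def test_three_sites_three_pairs(self):
        ds = make_dataset(
            {
                "A": [[(1, 2)], [(1, 1)], [(2, 2)]],
                "B": [[(2, 2)], [(2, 3)], [(3, 3)]],
                "C": [[(1, 3)], [(3, 3)], [(1, 1)]],
            }
        )
        pairs = fst_matrix(ds, "site")
        assert sorted(p.pair for p in pairs) == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_pairwise_matches_single_pair_computation(self, small_bundle):
        ds = small_bundle[0]
        pairs = fst_matrix(ds, "site")
        some = pairs[:3]
        for p in some:
            assert p.theta == pytest.approx(
                wc_fst_pair(ds, p.pair[0], p.pair[1]), abs=1e-12
            )

    def test_river_grouping_pools_sites(self, small_bundle):
        ds = small_bundle[0]
        rivers = sorted(set(ds.site_to_river.values()))
        pairs = fst_matrix(ds, "river")
        assert len(pairs) == len(rivers) * (len(rivers) - 1) // 2

    def test_small_groups_excluded(self):
        ds = make_dataset(
            {"A": [[(1, 2)], [(1, 1)], [(2, 2)]], "B": [[(2, 2)]]}
        )
        assert fst_matrix(ds, "site") == []

    def test_exclude_loci(self, small_bundle):
        ds = small_bundle[0]
        with_all = fst_matrix(ds, "site")
        without = fst_matrix(ds, "site", exclude_loci=[ds.loci[0]])
        assert any(
            not math.isclose(a.theta, b.theta)
            for a, b in zip(with_all, without)
            if a.theta is not None and b.theta is not None
        )


class TestFstPermutationTest:
    def test_identical_groups_give_large_p(self, rng):
        rows = [
            [tuple(sorted(rng.integers(1, 4, size=2))) for _ in range(4)]
            for _ in range(12)
        ]
        ds = make_dataset({"P1": rows[:6], "P2": rows[6:]})
        p = fst_permutation_test(ds, ("P1", "P2"), n_perm=200, seed=3)
        assert p > 0.05

    def test_fixed_differences_give_small_p(self):
        ds = make_dataset(
            {"P1": [[(1, 1), (3, 3)]] * 10, "P2": [[(2, 2), (4, 4)]] * 10}
        )
        p = fst_permutation_test(ds, ("P1", "P2"), n_perm=999, seed=3)
        assert p <= 0.005

    def test_add_one_estimator_never_zero(self):
        ds = make_dataset(
            {"P1": [[(1, 1)]] * 5, "P2": [[(2, 2)]] * 5}
        )
        p = fst_permutation_test(ds, ("P1", "P2"), n_perm=50, seed=1)
        assert p >= 1 / 51

    def test_deterministic_for_fixed_seed(self, rng):
        ds, _ = random_two_pop_dataset(rng)
        p1 = fst_permutation_test(ds, ("P1", "P2"), n_perm=100, seed=9)
        p2 = fst_permutation_test(ds, ("P1", "P2"), n_perm=100, seed=9)
        assert p1 == p2

    def test_zero_permutations_returns_none(self, rng):
        ds, _ = random_two_pop_dataset(rng)
        assert fst_permutation_test(ds, ("P1", "P2"), n_perm=0, seed=1) is None


# ---------------------------------------------------------------------------
# AMOVA


def amova_oracle_components(d2, sites, groups):
    """Direct sums-of-squares transcription for the 12-individual toy test."""
    n = len(sites)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(n)) / (2 * n)

    def ss_within(labels):
        tot = 0.0
        for lab in set(labels):
            idx = [i for i in range(n) if labels[i] == lab]
            tot += sum(d2[i, j] for i in idx for j in idx) / (2 * len(idx))
        return tot

    ss_ws = ss_within(sites)
    ss_wg = ss_within(groups)
    return ss_total - ss_wg, ss_wg - ss_ws, ss_ws


class TestAmova:
    def make_toy(self, rng):
        sites = {}
        site_river = {}
        for river, site_list in (("R1", ["A", "B"]), ("R2", ["C", "D"])):
            for s in site_list:
                sites[s] = [
                    [tuple(sorted(rng.integers(1, 5, size=2))) for _ in range(3)]
                    for _ in range(3)
                ]
                site_river[s] = river
        return make_dataset(sites, site_to_river=site_river,
                            river_to_catchment={"R1": "C1", "R2": "C1"})

    def test_sums_of_squares_match_oracle(self, rng):
        ds = self.make_toy(rng)
        res = amova(ds, n_perm=0)
        d2 = allele_mismatch_matrix(ds)
        sites = [ind.site_id for ind in ds.individuals]
        groups = [ds.site_to_river[s] for s in sites]
        ss_ag, ss_as, ss_ws = amova_oracle_components(d2, sites, groups)
        assert res.ss[0] == pytest.approx(ss_ag, abs=1e-10)
        assert res.ss[1] == pytest.approx(ss_as, abs=1e-10)
        assert res.ss[2] == pytest.approx(ss_ws, abs=1e-10)

    def test_components_sum_to_total_variance(self, rng):
        ds = self.make_toy(rng)
        res = amova(ds, n_perm=0)
        total = res.sigma_among + res.sigma_among_sites + res.sigma_within
        assert res.phi_st == pytest.approx(
            (res.sigma_among + res.sigma_among_sites) / total
        )

    def test_panmictic_pool_gives_small_components(self, rng):
        sites = {}
        site_river = {}
        for k, river in enumerate(["R1", "R1", "R2", "R2"]):
            sid = f"S{k}"
            sites[sid] = [
                [tuple(sorted(rng.integers(1, 6, size=2))) for _ in range(6)]
                for _ in range(10)
            ]
            site_river[sid] = river
        ds = make_dataset(sites, site_to_river=site_river,
                          river_to_catchment={"R1": "C", "R2": "C"})
        res = amova(ds, n_perm=99, seed=2)
        assert abs(res.phi_st) < 0.05
        assert res.p_values["phi_st"] > 0.05

    def test_diverged_rivers_dominant_among_component(self):
        cfg = SimulationConfig(
            n_catchments=1, rivers_per_catchment=2, sites_per_river=(2, 2),
            n_loci=6, generations=10, migration=0.2, ne_base=60,
            catchment_divergence_gens=0, river_divergence_gens=400, seed=21,
            min_individuals=10, max_individuals=12,
        )
        ds = simulate_bundle(cfg)[0]
        res = amova(ds, n_perm=49, seed=1)
        assert res.sigma_among > res.sigma_among_sites
        assert res.phi_ct > 0.05

    def test_degenerate_hierarchy_rejected(self, rng):
        ds = make_dataset(
            {"A": [[(1, 2)]] * 3, "B": [[(1, 2)]] * 3},
            site_to_river={"A": "R1", "B": "R2"},
            river_to_catchment={"R1": "C", "R2": "C"},
        )
        with pytest.raises(ValueError, match="degenerate"):
            amova(ds)


# ---------------------------------------------------------------------------
# distance matrices and Mantel


class TestAomDistanceMatrix:
    def test_equal_values_zero_matrix(self):
        dm = aom_distance_matrix({"a": 3.0, "b": 3.0, "c": 3.0})
        np.testing.assert_allclose(dm.values, 0.0)

    def test_log10_hand_values(self):
        dm = aom_distance_matrix({"a": 1.0, "b": 10.0, "c": 100.0}, transform="log10")
        np.testing.assert_allclose(
            dm.values, [[0, 1, 2], [1, 0, 1], [2, 1, 0]]
        )

    def test_undefined_scalar_dropped(self):
        dm = aom_distance_matrix({"a": 1.0, "b": None, "c": 100.0})
        assert dm.sites == ["a", "c"]

    def test_identity_transform(self):
        dm = aom_distance_matrix({"a": -2.0, "b": 1.0}, transform="identity")
        assert dm.values[0, 1] == pytest.approx(3.0)


def random_dm(rng, n, sites=None):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(sites or [f"s{i}" for i in range(n)], m)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        a = random_dm(rng, 5)
        b = DistanceMatrix(a.sites, a.values.copy())
        res = mantel(a, b, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_r_equals_lower_triangle_pearson(self, rng):
        a, b = random_dm(rng, 6), random_dm(rng, 6)
        res = mantel(a, b, n_perm=0)
        ia = a.values[np.tril_indices(6, -1)]
        ib = b.values[np.tril_indices(6, -1)]
        assert res.r == pytest.approx(np.corrcoef(ia, ib)[0, 1])

    def test_exhaustive_p_matches_direct_enumeration(self, rng):
        a, b = random_dm(rng, 4), random_dm(rng, 4)
        res = mantel(a, b, method="exhaustive")
        hits = 0
        perms = list(itertools.permutations(range(4)))
        vb = b.values[np.tril_indices(4, -1)]
        for perm in perms:
            ap = a.values[np.ix_(perm, perm)][np.tril_indices(4, -1)]
            if np.corrcoef(ap, vb)[0, 1] >= res.r - 1e-15:
                hits += 1
        assert res.p_value == pytest.approx(hits / 24)

    def test_monte_carlo_close_to_exhaustive(self, rng):
        a, b = random_dm(rng, 4), random_dm(rng, 4)
        exact = mantel(a, b, method="exhaustive").p_value
        mc = mantel(a, b, n_perm=4999, seed=5).p_value
        assert mc == pytest.approx(exact, abs=0.05)

    def test_relabeling_invariance(self, rng):
        a, b = random_dm(rng, 6), random_dm(rng, 6)
        perm = rng.permutation(6)
        ap = DistanceMatrix([a.sites[i] for i in perm], a.values[np.ix_(perm, perm)])
        bp = DistanceMatrix([b.sites[i] for i in perm], b.values[np.ix_(perm, perm)])
        assert mantel(a, b, n_perm=0).r == pytest.approx(mantel(ap, bp, n_perm=0).r)

    def test_too_few_sites_rejected(self, rng):
        a, b = random_dm(rng, 3), random_dm(rng, 3)
        with pytest.raises(ValueError):
            mantel(a, b)

    def test_mismatched_sites_rejected(self, rng):
        a = random_dm(rng, 5)
        b = random_dm(rng, 5, sites=[f"t{i}" for i in range(5)])
        with pytest.raises(ValueError):
            mantel(a, b)

    def test_zero_permutations_p_none(self, rng):
        res = mantel(random_dm(rng, 5), random_dm(rng, 5), n_perm=0)
        assert res.p_value is None


class TestPartialMantel:
    def test_b_equals_c_gives_near_zero_partial_r(self, rng):
        a = random_dm(rng, 8)
        b = random_dm(rng, 8)
        c = DistanceMatrix(b.sites, b.values.copy())
        res = partial_mantel(a, b, c, n_perm=0)
        assert abs(res.r) < 1e-10

    def test_uncorrelated_conditioning_keeps_simple_r(self, rng):
        # C independent of A and B: partial r approximately the simple r
        n = 12
        a, b, c = random_dm(rng, n), random_dm(rng, n), random_dm(rng, n)
        simple = mantel(a, b, n_perm=0).r
        part = partial_mantel(a, b, c, n_perm=0).r
        assert part == pytest.approx(simple, abs=0.25)

    def test_deterministic(self, rng):
        a, b, c = random_dm(rng, 6), random_dm(rng, 6), random_dm(rng, 6)
        r1 = partial_mantel(a, b, c, n_perm=99, seed=4)
        r2 = partial_mantel(a, b, c, n_perm=99, seed=4)
        assert (r1.r, r1.p_value) == (r2.r, r2.p_value)


class TestFstDistanceMatrix:
    def test_symmetric_zero_diagonal(self, small_bundle):
        dm = fst_distance_matrix(small_bundle[0], "site")
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert (dm.values >= 0).all()
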