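from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amphigen.diversity import (
    allele_counts,
    het_locus,
    het_stats,
    hwe_test,
    null_allele_freq,
    qc_filter,
    rarefaction_table,
    rarefied_allelic_richness,
    rarefied_private_alleles,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_ar(counts: Counter, g: int) -> float:
    """Mean number of distinct alleles over all C(N, g) gene subsamples."""
    genes = [a for allele, c in counts.items() for a in [allele] * c]
    subsets = list(itertools.combinations(range(len(genes)), g))
    total = sum(len({genes[i] for i in sub}) for sub in subsets)
    return total / len(subsets)


def brute_force_pa(counts_focal: Counter, others: list[Counter], g: int) -> float:
    """Mean count of alleles in the focal subsample absent from every other
    group's subsample, enumerating all subsample combinations."""
    def subsets(counts):
        genes = [a for allele, c in counts.items() for a in [allele] * c]
        return [
            {genes[i] for i in sub}
            for sub in itertools.combinations(range(len(genes)), g)
        ]

    focal_subs = subsets(counts_focal)
    other_subs = [subsets(c) for c in others]
    total = 0
    n_comb = 0
    for fs in focal_subs:
        for combo in itertools.product(*other_subs):
            present_elsewhere = set().union(*combo) if combo else set()
            total += len(fs - present_elsewhere)
            n_comb += 1
    return total / n_comb


class TestQcFilter:
    def test_individual_above_threshold_removed(self):
        rows = [[(1, 2)] * 12 + [None] * 4]  # 25% missing
        ds = make_dataset({"S1": rows + [[(1, 2)] * 16] * 3})
        filtered, report = qc_filter(ds)
        assert filtered.n_individuals == 3
        assert report.removed_individuals == ["S1_001"]

    def test_individual_at_1875_percent_retained(self):
        rows = [[(1, 2)] * 13 + [None] * 3]  # 18.75%
        ds = make_dataset({"S1": rows + [[(1, 2)] * 16] * 3})
        filtered, _ = qc_filter(ds)
        assert filtered.n_individuals == 4

    def test_locus_filter_applied_after_individuals(self):
        # 10 loci: each individual misses at most 1 locus (10% -> retained),
        # but the last locus is missing in 2/4 individuals (50% -> removed)
        full = [(1, 2)] * 9
        ds = make_dataset(
            {
                "S1": [
                    full + [None],
                    full + [None],
                    full + [(1, 1)],
                    full + [(2, 2)],
                ]
            }
        )
        filtered, report = qc_filter(ds)
        assert filtered.n_individuals == 4
        assert filtered.loci == [f"loc{j:02d}" for j in range(1, 10)]
        assert report.removed_loci == ["loc10"]

    def test_all_individuals_removed_is_error(self):
        ds = make_dataset({"S1": [[None, None], [None, None]]})
        with pytest.raises(ValueError):
            qc_filter(ds)


class TestHetStats:
    def test_textbook_example(self):
        # genotypes AA, AB, BB, AB: Ho=0.5, He=(4/3)(1-0.5-0.0625)
        lh = het_locus([(1, 1), (1, 2), (2, 2), (1, 2)])
        assert lh.h_obs == pytest.approx(0.5)
        assert lh.h_exp == pytest.approx((4 / 3) * (1 - 0.5 - 0.0625))
        assert lh.f_is == pytest.approx(1 - 0.5 / ((4 / 3) * 0.4375))

    def test_all_heterozygotes_negative_fis(self):
        lh = het_locus([(1, 2)] * 10)
        assert lh.h_obs == 1.0
        assert lh.f_is < 0

    def test_monomorphic_locus(self):
        lh = het_locus([(3, 3)] * 8)
        assert lh.h_obs == 0.0
        assert lh.h_exp == pytest.approx(0.0, abs=1e-12)
        assert lh.f_is is None

    def test_single_genotype_returns_none(self):
        assert het_locus([(1, 2)]) is None

    def test_unbiased_estimator_matches_plugin_at_large_n(self, rng):
        # the unbiased estimator converges to 1 - sum p_hat^2 on the sample
        p = np.array([0.4, 0.3, 0.2, 0.1])
        n = 10_000
        a = rng.choice(4, size=n, p=p) + 1
        b = rng.choice(4, size=n, p=p) + 1
        lh = het_locus(list(zip(a.tolist(), b.tolist())))
        genes = np.concatenate([a, b])
        p_hat = np.bincount(genes, minlength=5)[1:] / (2 * n)
        assert lh.h_exp == pytest.approx(1 - float((p_hat**2).sum()), abs=1e-3)

    def test_multilocus_fis_is_component_ratio(self):
        ds = make_dataset(
            {"S1": [[(1, 1), (1, 2)], [(1, 2), (1, 2)], [(2, 2), (1, 1)], [(1, 2), (2, 2)]]}
        )
        stats = het_stats(ds)["S1"]
        lh1 = het_locus([(1, 1), (1, 2), (2, 2), (1, 2)])
        lh2 = het_locus([(1, 2), (1, 2), (1, 1), (2, 2)])
        expected = 1 - (lh1.h_obs + lh2.h_obs) / (lh1.h_exp + lh2.h_exp)
        assert stats.f_is == pytest.approx(expected)


class TestRarefiedAllelicRichness:
    def test_two_by_two_example(self):
        # {A:2, B:2}, g=2 -> 2 * (1 - C(2,2)/C(4,2)) = 5/3
        assert rarefied_allelic_richness(Counter({1: 2, 2: 2}), 2) == pytest.approx(5 / 3)

    def test_matches_brute_force_enumeration(self):
        assert rarefied_allelic_richness(Counter({1: 2, 2: 2}), 2) == pytest.approx(
            brute_force_ar(Counter({1: 2, 2: 2}), 2)
        )

    def test_monomorphic_gives_one(self):
        for g in (1, 3, 6):
            assert rarefied_allelic_richness(Counter({5: 6}), g) == pytest.approx(1.0)

    def test_g_equal_n_gives_distinct_count(self):
        counts = Counter({1: 3, 2: 2, 3: 1})
        assert rarefied_allelic_richness(counts, 6) == pytest.approx(3.0)

    def test_g_too_large_rejected(self):
        with pytest.raises(ValueError):
            rarefied_allelic_richness(Counter({1: 2}), 3)

    @settings(max_examples=40, deadline=None)
    @given(
        counts=st.lists(st.integers(1, 4), min_size=1, max_size=4),
        g=st.integers(1, 12),
    )
    def test_brute_force_equivalence_small_n(self, counts, g):
        c = Counter({i + 1: v for i, v in enumerate(counts)})
        n = sum(c.values())
        if g > n:
            return
        assert rarefied_allelic_richness(c, g) == pytest.approx(brute_force_ar(c, g))

    def test_nondecreasing_in_g(self):
        c = Counter({1: 5, 2: 3, 3: 1, 4: 1})
        values = [rarefied_allelic_richness(c, g) for g in range(1, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] <= len(c)


class TestRarefiedPrivateAlleles:
    def test_two_population_example(self):
        # pop1 {A:2,B:2}, pop2 {A:4}, g=2 -> PA(pop1) = 5/6
        pa = rarefied_private_alleles({"p1": Counter({1: 2, 2: 2}), "p2": Counter({1: 4})}, 2)
        assert pa["p1"] == pytest.approx(5 / 6)
        assert pa["p2"] == pytest.approx(brute_force_pa(Counter({1: 4}), [Counter({1: 2, 2: 2})], 2))

    def test_matches_brute_force(self):
        groups = {"p1": Counter({1: 3, 2: 1}), "p2": Counter({1: 2, 3: 2})}
        pa = rarefied_private_alleles(groups, 2)
        assert pa["p1"] == pytest.approx(brute_force_pa(groups["p1"], [groups["p2"]], 2))
        assert pa["p2"] == pytest.approx(brute_force_pa(groups["p2"], [groups["p1"]], 2))

    def test_symmetric_when_groups_identical(self):
        groups = {"p1": Counter({1: 2, 2: 2}), "p2": Counter({1: 2, 2: 2})}
        pa = rarefied_private_alleles(groups, 2)
        assert pa["p1"] == pytest.approx(pa["p2"])

    def test_allele_absent_from_focal_group_contributes_zero(self):
        # allele 2 never occurs in p1, so only allele 1 can drive PA(p1);
        # with allele 1 fixed everywhere PA(p1) reduces to the chance that
        # p2's subsample misses allele 1 entirely: C(2,2)/C(4,2) = 1/6
        groups = {"p1": Counter({1: 4}), "p2": Counter({1: 2, 2: 2})}
        pa = rarefied_private_alleles(groups, 2)
        assert pa["p1"] == pytest.approx(1 / 6)
        assert pa["p1"] == pytest.approx(
            brute_force_pa(groups["p1"], [groups["p2"]], 2)
        )

    def test_pa_bounded_by_ar(self, small_bundle):
        ds = small_bundle[0]
        res = rarefaction_table(ds, grouping="river")
        for grp in res.ar:
            for locus in res.ar[grp]:
                assert res.pa[grp][locus] <= res.ar[grp][locus] + 1e-12


class TestRarefactionTable:
    def test_default_g_is_min_gene_count(self):
        ds = make_dataset(
            {
                "S1": [[(1, 2)], [(1, 1)], [(2, 2)]],
                "S2": [[(1, 2)], [(2, 3)]],
            }
        )
        res = rarefaction_table(ds)
        assert res.g["loc01"] == 4  # 2 genotypes * 2 in the smaller site

    def test_explicit_g_too_large_raises(self):
        ds = make_dataset({"S1": [[(1, 2)]], "S2": [[(1, 2)]]})
        with pytest.raises(ValueError, match="exceeds"):
            rarefaction_table(ds, g=4)


class TestHweTest:
    def test_pure_homozygote_excess_is_significant(self, rng):
        genos = [(1, 1)] * 25 + [(2, 2)] * 25
        p = hwe_test(genos, n_reps=999, seed=1)
        assert p < 0.01

    def test_too_few_genotypes_returns_none(self):
        assert hwe_test([(1, 2)] * 4, n_reps=100, seed=1) is None

    def test_zero_reps_returns_none(self):
        assert hwe_test([(1, 2)] * 10, n_reps=0, seed=1) is None

    def test_reproducible_for_fixed_seed(self):
        genos = [(1, 1)] * 10 + [(1, 2)] * 12 + [(2, 2)] * 8
        assert hwe_test(genos, 200, seed=7) == hwe_test(genos, 200, seed=7)

    def test_p_roughly_uniform_under_random_mating(self, rng):
        # under HWE the MC p-value should not be concentrated at small values
        hits = 0
        n_sets = 120
        for _ in range(n_sets):
            p_freq = rng.dirichlet([2.0, 2.0, 2.0])
            a = rng.choice(3, size=40, p=p_freq) + 1
            b = rng.choice(3, size=40, p=p_freq) + 1
            p = hwe_test(list(zip(a.tolist(), b.tolist())), n_reps=120,
                         seed=int(rng.integers(2**31)))
            if p <= 0.05:
                hits += 1
        assert hits / n_sets < 0.15
        assert hits / n_sets >= 0.0  # sanity


class TestNullAlleleFreq:
    def test_hand_values(self):
        he = (4 / 3) * 0.4375
        chak, brook = null_allele_freq(0.5, he)
        assert chak == pytest.approx((he - 0.5) / (he + 0.5))
        assert brook == pytest.approx((he - 0.5) / (1 + he))

    def test_equal_het_gives_zero(self):
        chak, brook = null_allele_freq(0.6, 0.6)
        assert chak == 0.0 and brook == 0.0

    def test_zero_observed_het_boundary(self):
        chak, _ = null_allele_freq(0.0, 0.5)
        assert chak == pytest.approx(1.0)

    def test_none_when_he_zero(self):
        assert null_allele_freq(0.0, 0.0) is None


class TestAlleleCounts:
    def test_counts_sum_to_twice_nonmissing(self):
        ds = make_dataset({"S1": [[(1, 2)], [(1, 1)], [None]]})
        counts = allele_counts(ds)["S1"]["loc01"]
        assert sum(counts.values()) == 4
        assert counts == Counter({1: 3, 2: 1})
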