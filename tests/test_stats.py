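"""Diversity, F_ST, G-test, HWE, heterozygosity, and assignment checks."""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from ucepop.simulate import DemographicParams, SimulationConfig, generate_dataset
from ucepop.stats import (
    _g_statistic,
    assign_individuals,
    divergence_stats,
    heterozygosity_summary,
    hwe_exact_test,
    nucleotide_diversity,
    permutation_differentiation_test,
    weir_cockerham_fst,
)

from conftest import make_locus_set


class TestDiversity:
    def test_identical_haplotypes_have_zero_pi(self):
        ls = make_locus_set([np.zeros((8, 0), dtype=np.int8)], lengths=[500])
        assert nucleotide_diversity(ls) == 0.0

    def test_single_snp_hand_value(self):
        """4 haplotypes, allele counts 2/2, length 1000: pi = (4 differing
        pairs of 6) / 1000 = 6.667e-4, matching the unbiased 2pq n/(n-1)."""
        haps = np.array([[0], [0], [1], [1]])
        ls = make_locus_set([haps], lengths=[1000], n_per_pop=1)
        assert nucleotide_diversity(ls) == pytest.approx((4 / 6) / 1000)

    def test_invariant_loci_extend_the_denominator(self):
        haps = np.array([[0], [0], [1], [1]])
        ls = make_locus_set([haps], lengths=[1000], n_per_pop=1)
        inv = make_locus_set(
            [haps, np.zeros((4, 0), dtype=np.int8)], lengths=[1000, 1000], n_per_pop=1
        )
        assert nucleotide_diversity(inv) == pytest.approx(nucleotide_diversity(ls) / 2)

    def test_identical_populations_make_dA_zero(self):
        haps = np.array([[0], [1], [0], [1], [0], [1], [0], [1]])
        ls = make_locus_set([haps], lengths=[100])
        d = divergence_stats(ls)
        assert d.dxy == pytest.approx(d.pi_by_pop["pop1"], rel=0.35)  # n/(n-1) bias only
        assert d.dA == pytest.approx(d.dxy - (d.pi_by_pop["pop1"] + d.pi_by_pop["pop2"]) / 2)

    def test_fixed_difference_hand_value(self):
        """Pops fixed for different alleles at 1 site of 100 bp:
        dxy = 0.01 and dA = 0.01 since within-pop diversity is zero."""
        haps = np.array([[0]] * 4 + [[1]] * 4)
        ls = make_locus_set([haps], lengths=[100])
        d = divergence_stats(ls)
        assert d.dxy == pytest.approx(0.01)
        assert d.dA == pytest.approx(0.01)

    def test_net_distance_identity_on_printed_inputs(self):
        """dA = dxy - (pi1 + pi2)/2 on the study's printed inputs gives
        2.2e-5 (printed as 2.0e-5 after rounding of its inputs)."""
        dA = 5.3e-4 - (5.23e-4 + 4.93e-4) / 2
        assert dA == pytest.approx(2.2e-5, abs=1e-7)

    def test_zero_length_errors(self):
        ls = make_locus_set([np.zeros((8, 0), dtype=np.int8)], lengths=[500])
        ls.loci = []
        with pytest.raises(ValueError, match="zero total"):
            nucleotide_diversity(ls)


def _wc_abc_oracle(g1, g2):
    """Independent transcription of the Weir & Cockerham (1984) variance
    components for a biallelic site, allele '1', two populations."""
    n1, n2 = len(g1), len(g2)
    p1 = sum(x.count(1) for x in g1) / (2 * n1)
    p2 = sum(x.count(1) for x in g2) / (2 * n2)
    h1 = sum(1 for x in g1 if x.count(1) == 1) / n1
    h2 = sum(1 for x in g2 if x.count(1) == 1) / n2
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestFst:
    def test_fixed_difference_gives_one(self):
        haps = np.array([[0]] * 8 + [[1]] * 8)
        ls = make_locus_set([haps], lengths=[100])
        assert weir_cockerham_fst(ls).overall == pytest.approx(1.0)

    def test_identical_composition_gives_nonpositive(self):
        haps = np.array([[0], [1]] * 4)  # same genotypes in both pops
        ls = make_locus_set([haps], lengths=[100])
        assert weir_cockerham_fst(ls).overall <= 0.0

    def test_hand_oracle_on_small_genotype_case(self):
        """2 pops x 2 diploids, pop1 {0/0, 0/1}, pop2 {1/1, 1/1}: matches
        an independently transcribed W&C 1984 a/b/c computation; the
        biallelic estimate is the per-allele sum by symmetry."""
        haps = np.array([[0], [0], [0], [1], [1], [1], [1], [1]])
        ls = make_locus_set([haps], lengths=[100])
        a, b, c = _wc_abc_oracle([(0, 0), (0, 1)], [(1, 1), (1, 1)])
        assert weir_cockerham_fst(ls).overall == pytest.approx(a / (a + b + c))

    def test_label_swap_invariance(self, sim_ls):
        swapped = sim_ls.subset(sim_ls.variable_loci()[:60])
        swapped.popmap = {
            s: ("pop2" if p == "pop1" else "pop1") for s, p in swapped.popmap.items()
        }
        base = sim_ls.subset(sim_ls.variable_loci()[:60])
        assert weir_cockerham_fst(swapped).overall == pytest.approx(
            weir_cockerham_fst(base).overall
        )

    def test_monomorphic_only_errors(self):
        ls = make_locus_set([np.zeros((8, 1), dtype=np.int8)], lengths=[100])
        with pytest.raises(ValueError, match="no polymorphic"):
            weir_cockerham_fst(ls)

    def test_deeper_split_gives_larger_fst(self):
        """F_ST increases stochastically with split time under no
        migration (rank test over replicates)."""
        wins = 0
        n_rep = 20
        for k in range(n_rep):
            vals = []
            for T in (0.2, 2.0):
                cfg = SimulationConfig(
                    model="split_nomig",
                    params=DemographicParams(nu1=1, nu2=1, T=T),
                    n_variable_loci_target=40,
                    n_invariant_loci=0,
                    seed=1000 + 7 * k + int(T * 10),
                )
                ls = generate_dataset(cfg).locus_set
                vals.append(weir_cockerham_fst(ls).overall)
            wins += vals[1] > vals[0]
        assert wins >= 16  # sign test: P(X >= 16 | p = .5) ~ 6e-3


class TestPermutationGTest:
    def test_identical_populations_are_undifferentiated(self):
        block = np.array([[0], [1], [0], [1]])
        haps = np.vstack([block, block])
        ls = make_locus_set([haps], lengths=[100])
        _, p = permutation_differentiation_test(ls, n_perm=200, rng=np.random.default_rng(0))
        assert p >= 0.5

    def test_fixed_differences_are_significant(self):
        # 12 + 12 individuals so the permutation space allows p < 0.01
        haps = np.concatenate(
            [np.zeros((24, 50), dtype=np.int8), np.ones((24, 50), dtype=np.int8)], axis=0
        )
        ls = make_locus_set([haps], lengths=[1000])
        _, p = permutation_differentiation_test(ls, n_perm=1000, rng=np.random.default_rng(1))
        assert p <= 0.01

    def test_matches_exhaustive_relabelling_oracle(self):
        """3+3 individuals, 2 SNPs: the permutation p-value agrees with
        exhaustive enumeration of all individual relabellings."""
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, size=(12, 2)).astype(np.int8)
        while len(np.unique(haps[:, 0])) < 2 or len(np.unique(haps[:, 1])) < 2:
            haps = rng.integers(0, 2, size=(12, 2)).astype(np.int8)
        ls = make_locus_set([haps], lengths=[100])
        obs = _g_statistic(ls, np.array([0, 0, 0, 1, 1, 1]))
        hits = total = 0
        for pos in itertools.combinations(range(6), 3):
            lab = np.ones(6, dtype=int)
            lab[list(pos)] = 0
            total += 1
            if _g_statistic(ls, lab) >= obs - 1e-12:
                hits += 1
        exact = hits / total
        _, p = permutation_differentiation_test(ls, n_perm=4000, rng=np.random.default_rng(6))
        # MC vs exhaustive: 3 binomial SEs plus the +1 correction
        se = math.sqrt(exact * (1 - exact) / 4000)
        assert abs(p - exact) < 3 * se + 1e-3

    def test_super_uniform_under_null(self):
        """Permutation p-values on panmictic data are super-uniform:
        fraction with p < 0.05 stays below 0.10 over 60 datasets."""
        n_sig = 0
        n_data = 60
        for k in range(n_data):
            cfg = SimulationConfig(
                model="neutral",
                params=DemographicParams(),
                n_variable_loci_target=25,
                n_invariant_loci=0,
                seed=5000 + k,
            )
            ls = generate_dataset(cfg).locus_set
            _, p = permutation_differentiation_test(
                ls, n_perm=200, rng=np.random.default_rng(k)
            )
            n_sig += p < 0.05
        assert n_sig / n_data <= 0.10


def _hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional heterozygote-count
    distribution (independent of the implementation's log-space path)."""
    n = n_AA + n_Aa + n_aa
    na = n_Aa + 2 * n_aa
    if n == 0 or na == 0 or na == 2 * n:
        return 1.0

    def prob(het):
        hom_a = (na - het) // 2
        hom_A = n - het - hom_a
        return Fraction(
            2**het * math.factorial(n) * math.factorial(na) * math.factorial(2 * n - na),
            math.factorial(hom_A) * math.factorial(het) * math.factorial(hom_a) * math.factorial(2 * n),
        )

    probs = {h: prob(h) for h in range(na % 2, min(na, 2 * n - na) + 1, 2)}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHWE:
    def test_monomorphic_convention(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    @pytest.mark.parametrize("config", [(25, 50, 25), (0, 8, 0), (3, 1, 4), (5, 0, 5)])
    def test_matches_oracle_on_named_configs(self, config):
        assert hwe_exact_test(*config) == pytest.approx(_hwe_oracle(*config), abs=1e-12)

    def test_matches_oracle_for_all_small_samples(self):
        """Every genotype configuration with n <= 10 diploids agrees with
        the exact-rational enumeration to 1e-12."""
        for n in range(1, 11):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                        _hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12
                    ), (n_AA, n_Aa, n_aa)


class TestHetSummary:
    def test_all_heterozygous_site(self):
        """All individuals heterozygous: Ho = 1 and He = 0.5 * 2n/(2n-1)
        with n = 2 diploids per population here."""
        haps = np.array([[0], [1]] * 4)
        ls = make_locus_set([haps, haps], lengths=[100, 100])
        het = heterozygosity_summary(ls)
        for pop in ("pop1", "pop2"):
            assert het.ho_by_pop[pop] == pytest.approx(1.0)
            assert het.he_by_pop[pop] == pytest.approx(0.5 * 4 / 3)

    def test_duplicate_population_gives_identical_summaries(self):
        """When pop2 is a copy of pop1 the per-population Ho and He
        coincide; identical per-locus distributions give Bartlett p = 1."""
        rng = np.random.default_rng(2)
        half = rng.integers(0, 2, size=(4, 3)).astype(np.int8)
        haps = np.vstack([half, half])  # pop2 duplicates pop1
        half2 = rng.integers(0, 2, size=(4, 4)).astype(np.int8)
        haps2 = np.vstack([half2, half2])
        ls = make_locus_set([haps, haps2], lengths=[100, 100])
        het = heterozygosity_summary(ls)
        assert het.ho_by_pop["pop1"] == pytest.approx(het.ho_by_pop["pop2"])
        assert het.he_by_pop["pop1"] == pytest.approx(het.he_by_pop["pop2"])
        same = make_locus_set([haps, haps.copy()], lengths=[100, 100])
        het_same = heterozygosity_summary(same)
        assert het_same.bartlett_p == pytest.approx(1.0)  # zero-variance guard

    def test_hand_computed_ho_he(self):
        """Small matrix against a spreadsheet-style recomputation."""
        # pop1: genotypes (0|0, 0|1); pop2: (1|1, 0|1) at a single site
        haps = np.array([[0], [0], [0], [1], [1], [1], [0], [1]])
        ls = make_locus_set([haps, haps.copy()], lengths=[100, 100])
        het = heterozygosity_summary(ls)
        assert het.ho_by_pop["pop1"] == pytest.approx(0.5)
        assert het.ho_by_pop["pop2"] == pytest.approx(0.5)
        # pop1: p = 3/4 -> He = 2 * .75 * .25 * 4/3 = 0.5
        assert het.he_by_pop["pop1"] == pytest.approx(0.5)
        assert het.he_by_pop["pop2"] == pytest.approx(0.5)
        # one allele private to neither: both alleles occur in both pops
        assert het.unique_alleles == {"pop1": 0, "pop2": 0}

    def test_reports_both_tail_p_values(self, sim_ls):
        het = heterozygosity_summary(sim_ls.subset(sim_ls.variable_loci()[:80]))
        assert het.paired_p_ho_greater + het.paired_p_ho_less == pytest.approx(1.0)
        assert 0 <= het.paired_p_two_sided <= 1


class TestAssignment:
    def test_fixed_differences_give_full_diagnosability(self):
        rng = np.random.default_rng(3)
        noise = rng.integers(0, 2, size=(16, 30)).astype(np.int8)
        fixed = np.concatenate(
            [np.zeros((8, 12), dtype=np.int8), np.ones((8, 12), dtype=np.int8)], axis=0
        )
        ls = make_locus_set([np.concatenate([noise, fixed], axis=1)], lengths=[2000])
        res = assign_individuals(ls, n_pcs=4)
        assert res.diagnosability == 1.0
        assert np.all(res.posteriors.to_numpy().max(axis=1) > 0.99)

    def test_overfitting_guard(self, sim_ls):
        with pytest.raises(ValueError, match="n_pcs"):
            assign_individuals(sim_ls, n_pcs=8)

    def test_null_assignment_is_chance_level(self):
        """Panmictic data: mean diagnosability over replicates is close to
        coin-flipping, far from the perfect separation seen with structure."""
        vals = []
        for k in range(15):
            cfg = SimulationConfig(
                model="neutral",
                params=DemographicParams(),
                n_variable_loci_target=60,
                n_invariant_loci=0,
                seed=7000 + k,
            )
            ls = generate_dataset(cfg).locus_set
            vals.append(assign_individuals(ls, n_pcs=4, cross_validated=True).diagnosability)
        # leave-one-out score: statistically indistinguishable from 0.5
        assert 0.2 <= np.mean(vals) <= 0.8

    def test_study_scale_simulation_is_fully_diagnosable(self, sim_ls):
        res = assign_individuals(sim_ls, n_pcs=4)
        assert res.diagnosability == 1.0
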