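"""Neutrality statistics: values against independent transcriptions of the
published formulas, Stirling/Ewens machinery against enumeration, and
null-simulation behavior."""

import itertools
import math

import numpy as np
import pytest

from helpers import make_alignment
from mtdemog.diversity import harmonic, nucleotide_diversity
from mtdemog.neutrality import (
    coalescent_pvalue,
    fs_probability_at_least,
    fu_li_star,
    fus_fs,
    log_unsigned_stirling_first,
    r2_statistic,
    simulate_null_statistics,
    tajimas_d,
)

# a fixed, hand-checkable n=5, L=10 alignment (S=4: two singleton sites,
# two parsimony-informative sites)
FIXTURE = make_alignment([
    "AAAAAAAAAA",
    "AAAAAAAAAT",
    "AAGAAAAAAA",
    "AACAATAAAA",
    "AACAATAAAA",
])


def seg_site_columns(aln):
    return [[s[j] for s in aln.sequences()]
            for j in range(aln.length)
            if len({s[j] for s in aln.sequences()}) > 1]


class TestTajimasD:
    def test_not_applicable_when_invariant(self):
        res = tajimas_d(make_alignment(["ACGT"] * 5))
        assert not res.applicable

    def test_matches_direct_formula(self):
        """Independent literal evaluation of the published coefficient chain."""
        res = tajimas_d(FIXTURE)
        n = 5
        cols = seg_site_columns(FIXTURE)
        S = len(cols)
        k = nucleotide_diversity(FIXTURE)[2]
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        expected = (k - S / a1) / math.sqrt(
            (c1 / a1) * S + (c2 / (a1 ** 2 + a2)) * S * (S - 1))
        assert res.value == pytest.approx(expected, rel=1e-12)

    def test_neutral_mean_near_zero(self):
        """Mean D under constant-size nulls lies in (-0.3, 0.1)."""
        nulls = simulate_null_statistics("D", 25, 1000, S=8, seed=11)
        mean = np.nanmean(nulls)
        assert -0.3 < mean < 0.1


class TestFuLiStar:
    def test_not_applicable_when_invariant(self):
        d, f = fu_li_star(make_alignment(["ACGT"] * 5))
        assert not d.applicable and not f.applicable

    def test_matches_direct_formula(self):
        """Independent transcription of the corrected starred coefficients."""
        d_res, f_res = fu_li_star(FIXTURE)
        n = 5
        cols = seg_site_columns(FIXTURE)
        eta = sum(len(set(c)) - 1 for c in cols)
        # singleton mutations: states seen exactly once (at most #states - 1
        # per column, since one state is ancestral)
        eta_s = sum(min(sum(1 for b in set(c) if c.count(b) == 1),
                        len(set(c)) - 1) for c in cols)
        k = nucleotide_diversity(FIXTURE)[2]
        an = sum(1 / i for i in range(1, n))
        bn = sum(1 / i ** 2 for i in range(1, n))
        an1 = an + 1 / n
        cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
        dn = cn + (n - 2) / (n - 1) ** 2 \
            + (2 / (n - 1)) * (3 / 2 - (2 * an1 - 3) / (n - 2) - 1 / n)
        vD = ((n / (n - 1)) ** 2 * bn + an ** 2 * dn
              - 2 * (n * an * (an + 1)) / (n - 1) ** 2) / (an ** 2 + bn)
        uD = (n / (n - 1)) * (an - n / (n - 1)) - vD
        d_expected = ((n / (n - 1)) * eta - an * eta_s) \
            / math.sqrt(uD * eta + vD * eta ** 2)
        vF = ((2 * n ** 3 + 110 * n ** 2 - 255 * n + 153) / (9 * n ** 2 * (n - 1))
              + 2 * (n - 1) * an / n ** 2 - 8 * bn / n) / (an ** 2 + bn)
        uF = ((4 * n ** 2 + 19 * n + 3 - 12 * (n + 1) * an1)
              / (3 * n * (n - 1))) / an - vF
        f_expected = (k - ((n - 1) / n) * eta_s) \
            / math.sqrt(uF * eta + vF * eta ** 2)
        assert d_res.value == pytest.approx(d_expected, rel=1e-12)
        assert f_res.value == pytest.approx(f_expected, rel=1e-12)

    def test_neutral_means_near_zero(self):
        for stat in ("D*", "F*"):
            nulls = simulate_null_statistics(stat, 20, 800, S=6, seed=13)
            assert abs(np.nanmean(nulls)) < 0.35


class TestFusFs:
    def test_stirling_against_permutation_enumeration(self):
        """|S(n,k)| equals the number of n-permutations with k cycles (n <= 7)."""
        def cycle_count(perm):
            seen = [False] * len(perm)
            c = 0
            for i in range(len(perm)):
                if not seen[i]:
                    c += 1
                    j = i
                    while not seen[j]:
                        seen[j] = True
                        j = perm[j]
            return c

        for n in range(2, 8):
            counts = np.zeros(n + 1)
            for perm in itertools.permutations(range(n)):
                counts[cycle_count(perm)] += 1
            logs = log_unsigned_stirling_first(n)
            for k in range(1, n + 1):
                assert np.exp(logs[k]) == pytest.approx(counts[k], rel=1e-10)

    def test_hand_example(self):
        # n=3, theta=1: P(K=k) proportional to |S(3,k)| = (2, 3, 1);
        # normalizer theta(theta+1)(theta+2) = 6 -> P(K=3) = 1/6
        sp = fs_probability_at_least(3, 3, 1.0)
        assert sp == pytest.approx(1 / 6, rel=1e-12)
        fs = math.log(sp / (1 - sp))
        assert fs == pytest.approx(math.log(0.2), rel=1e-12)

    def test_single_haplotype_sentinel(self):
        res = fus_fs(make_alignment(["ACGT"] * 6))
        assert res.value == math.inf and not res.applicable

    def test_ewens_tail_sums_to_one(self):
        assert fs_probability_at_least(10, 1, 2.3) == pytest.approx(1.0)

    def test_negative_under_haplotype_excess(self):
        """Many haplotypes for few pairwise differences push F_S negative."""
        aln = make_alignment(["AAAAA", "TAAAA", "ATAAA", "AATAA",
                              "AAATA", "AAAAT"])
        assert fus_fs(aln).value < 0


class TestR2:
    def test_not_applicable_when_invariant(self):
        assert not r2_statistic(make_alignment(["AC"] * 4)).applicable

    def test_matches_hand_computation(self):
        # singleton sites in FIXTURE: site 10 (T on s2), site 3? A,A,G,C,C has
        # G and C... G singleton among {A,A,G,C,C}: multistate handled by U
        aln = make_alignment(["AAT", "AAA", "ATA", "AAA"])
        # site2: T singleton on s3; site3: T singleton on s1
        res = r2_statistic(aln)
        k = nucleotide_diversity(aln)[2]
        U = np.array([1, 0, 1, 0])
        expected = math.sqrt(np.mean((U - k / 2) ** 2)) / 2
        assert res.value == pytest.approx(expected, rel=1e-12)

    def test_order_invariance(self):
        a = make_alignment(["AAT", "AAA", "ATA", "AAA"])
        b = make_alignment(["AAA", "ATA", "AAA", "AAT"])  # reorder sequences
        c = make_alignment(["TAA", "AAA", "AAT", "AAA"])  # reorder sites
        assert r2_statistic(a).value == pytest.approx(r2_statistic(b).value)
        assert r2_statistic(a).value == pytest.approx(r2_statistic(c).value)


class TestCoalescentPvalue:
    def test_median_observed_gives_half(self, study_dataset):
        """An observed value at the null median has p close to 0.5."""
        aln = study_dataset.alignment
        nulls = simulate_null_statistics("D", aln.n, 1000,
                                         S=study_dataset.true_sfs.S, seed=3)
        med = float(np.nanmedian(nulls))
        finite = nulls[~np.isnan(nulls)]
        p = np.mean(finite <= med)
        assert 0.4 < p < 0.6

    def test_growth_detected_by_fs(self):
        """F_S rejects constant size for most strongly growing populations."""
        from mtdemog.coalsim import drop_mutations, simulate_genealogy
        from mtdemog.neutrality import _stats_from_masks
        rng = np.random.default_rng(17)
        n = 100
        rejections = 0
        trials = 25
        null_cache = {}
        for _ in range(trials):
            gen = simulate_genealogy(n, model="exponential", growth_rate=30.0,
                                     seed=rng)
            ds = drop_mutations(gen, 6.0, 1000, seed=rng)
            S = ds.true_sfs.S
            if S == 0:
                continue
            res_val = fus_fs(ds.alignment).value
            if S not in null_cache:
                null_cache[S] = simulate_null_statistics(
                    "FS", n, 300, S=S, seed=1000 + S)
            finite = null_cache[S][~np.isnan(null_cache[S])]
            if np.mean(finite <= res_val) < 0.05:
                rejections += 1
        assert rejections / trials > 0.5

    def test_reps_floor(self, toy_alignment):
        aln = make_alignment(["AAAA", "AAAT", "AATT", "ATTT"])
        with pytest.raises(ValueError):
            coalescent_pvalue("D", aln, reps=10, seed=0)

    def test_result_carries_null_settings(self):
        aln = make_alignment(["AAAA", "AAAT", "AATT", "ATTT", "AAAA"])
        res = coalescent_pvalue("D", aln, reps=1000, seed=5)
        assert res.null_settings["reps"] == 1000
        assert res.null_settings["conditioning"] == "S"
        assert 0.0 <= res.p_value <= 1.0
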