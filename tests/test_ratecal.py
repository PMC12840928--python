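"""Corrected distances, between-group divergence, fossil-calibrated rates,
and Tajima's relative rate test."""

import math

import numpy as np
import pytest

from helpers import make_alignment
from mtdemog.ratecal import (
    DivergenceEstimate,
    corrected_distance,
    dxy_between_groups,
    rate_from_divergence,
    tajima_relative_rate,
)


class TestCorrectedDistance:
    def test_identical_zero_all_models(self):
        s = "ACGT" * 25
        for model in ("JC69", "K2P", "TN93"):
            assert corrected_distance(s, s, model) == 0.0

    def test_k2p_closed_form(self):
        # 100 sites, 10 transitions (A<->G), 0 transversions:
        # K2P = -1/2 ln(0.8) - 1/4 ln(1) = 0.1116
        s1 = "A" * 100
        s2 = "G" * 10 + "A" * 90
        d = corrected_distance(s1, s2, "K2P")
        assert d == pytest.approx(-0.5 * math.log(0.8), rel=1e-12)
        assert d == pytest.approx(0.1116, abs=5e-5)

    def test_k2p_equals_jc_when_ts_tv_balanced(self):
        # transitions and transversions each at p/2: K2P ~ JC69
        s1 = "A" * 200
        s2 = "G" * 10 + "C" * 10 + "A" * 180
        jc = corrected_distance(s1, s2, "JC69")
        k2p = corrected_distance(s1, s2, "K2P")
        assert k2p == pytest.approx(jc, rel=0.02)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = list(a)
        for i in rng.choice(300, size=30, replace=False):
            b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
        b = "".join(b)
        for model in ("JC69", "K2P", "TN93"):
            assert corrected_distance(a, b, model) == \
                pytest.approx(corrected_distance(b, a, model), rel=1e-12)

    def test_saturation_flagged(self):
        # maximally divergent pair: JC log argument <= 0
        s1 = "A" * 100
        s2 = "C" * 100
        assert math.isnan(corrected_distance(s1, s2, "JC69"))

    def test_pairwise_deletion(self):
        d_full = corrected_distance("AAAAAAAAAG", "AAAAAAAAAA", "JC69")
        d_miss = corrected_distance("AAAAAAAAAGNNNNN", "AAAAAAAAAANNNNN", "JC69")
        assert d_full == pytest.approx(d_miss)

    def test_tn93_close_to_k2p_on_balanced_composition(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), size=2000))
        # mutate ~5% of sites
        b = list(a)
        idx = rng.choice(2000, size=100, replace=False)
        for i in idx:
            b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
        d_tn = corrected_distance(a, "".join(b), "TN93")
        d_k2p = corrected_distance(a, "".join(b), "K2P")
        assert d_tn == pytest.approx(d_k2p, rel=0.05)


class TestDxyBetweenGroups:
    def test_identical_groups_zero(self):
        g = make_alignment(["ACGTACGT", "ACGTACGT"])
        est = dxy_between_groups(g, g, model="JC69", B=50, seed=1)
        assert est.d_xy == 0.0

    def test_two_singletons_reduce_to_pair_distance(self):
        g1 = make_alignment(["A" * 100], ids=["x"])
        g2 = make_alignment(["G" * 10 + "A" * 90], ids=["y"])
        est = dxy_between_groups(g1, g2, model="K2P", B=0)
        assert est.d_xy == pytest.approx(
            corrected_distance(g1.sequences()[0], g2.sequences()[0], "K2P"))

    def test_bootstrap_se_positive_and_stable(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), size=400))
        mutated = list(base)
        for i in rng.choice(400, size=30, replace=False):
            mutated[i] = rng.choice([c for c in "ACGT" if c != base[i]])
        g1 = make_alignment([base, base], ids=["a1", "a2"])
        g2 = make_alignment(["".join(mutated)], ids=["b1"])
        est1 = dxy_between_groups(g1, g2, model="K2P", B=400, seed=5)
        est2 = dxy_between_groups(g1, g2, model="K2P", B=400, seed=6)
        assert est1.se > 0
        # Monte-Carlo stability of the SE across seeds
        assert est1.se == pytest.approx(est2.se, rel=0.25)


class TestRateFromDivergence:
    def test_printed_point_and_intervals_648(self):
        """0.091 +/- 0.013 at T=4.6 Ma -> 0.99 %/Ma, CIs [0.72, 1.26] and
        (with the 4-5.2 Ma fossil window) [0.63, 1.45]."""
        d = DivergenceEstimate(0.091, 0.013, "TN93", 1000, None)
        est = rate_from_divergence(d, 4.6e6, (4.0e6, 5.2e6))
        assert est.pct_per_ma == pytest.approx(0.99, abs=0.005)
        lo, hi = est.ci_fixed_T_pct()
        assert lo == pytest.approx(0.72, abs=0.01)
        assert hi == pytest.approx(1.26, abs=0.01)
        flo, fhi = est.ci_full_pct()
        assert flo == pytest.approx(0.63, abs=0.01)
        assert fhi == pytest.approx(1.45, abs=0.01)

    def test_printed_point_and_intervals_340(self):
        """0.086 +/- 0.017 -> 0.93 %/Ma, CIs [0.58, 1.29] and [0.51, 1.49]."""
        d = DivergenceEstimate(0.086, 0.017, "K2P", 1000, None)
        est = rate_from_divergence(d, 4.6e6, (4.0e6, 5.2e6))
        assert est.pct_per_ma == pytest.approx(0.93, abs=0.005)
        lo, hi = est.ci_fixed_T_pct()
        assert lo == pytest.approx(0.58, abs=0.01)
        assert hi == pytest.approx(1.29, abs=0.01)
        flo, fhi = est.ci_full_pct()
        assert flo == pytest.approx(0.51, abs=0.01)
        assert fhi == pytest.approx(1.49, abs=0.01)

    def test_scaling_in_T(self):
        d = DivergenceEstimate(0.1, 0.0, "JC69", 0, None)
        assert rate_from_divergence(d, 2e6).mu == \
            pytest.approx(2 * rate_from_divergence(d, 4e6).mu)

    def test_degenerate_zero_width(self):
        d = DivergenceEstimate(0.1, 0.0, "JC69", 0, None)
        est = rate_from_divergence(d, 1e6, (1e6, 1e6))
        assert est.ci_fixed_T[0] == est.ci_fixed_T[1] == est.mu
        assert est.ci_full[0] == pytest.approx(est.ci_full[1])

    def test_full_ci_contains_fixed_ci(self):
        d = DivergenceEstimate(0.091, 0.013, "TN93", 1000, None)
        est = rate_from_divergence(d, 4.6e6, (4.0e6, 5.2e6))
        assert est.ci_full[0] <= est.ci_fixed_T[0]
        assert est.ci_full[1] >= est.ci_fixed_T[1]


class TestTajimaRelativeRate:
    def test_symmetric_counts_give_p_one(self):
        # A differs at site 1, B differs at site 2
        m1, m2, stat, p = tajima_relative_rate("GAAA", "AGAA", "AAAA")
        assert (m1, m2) == (1, 1)
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_chi_square(self):
        # m1=12, m2=4: chi2 = 64/16 = 4, p ~ 0.0455
        A = "G" * 12 + "A" * 4 + "A" * 20
        B = "A" * 12 + "G" * 4 + "A" * 20
        O = "A" * 36
        m1, m2, stat, p = tajima_relative_rate(A, B, O)
        assert (m1, m2) == (12, 4)
        assert stat == pytest.approx(4.0)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_no_informative_sites(self):
        _m1, _m2, _stat, p = tajima_relative_rate("AAAA", "AAAA", "AAAA")
        assert p == 1.0

    def test_calibration_under_equal_rates(self):
        """~5% rejection when both lineages evolve at the same rate."""
        from mtdemog.coalsim import _jc_evolve
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 400
        for _ in range(reps):
            root = "".join(rng.choice(list("ACGT"), size=500))
            a = _jc_evolve(root, 0.05, rng)
            b = _jc_evolve(root, 0.05, rng)
            o = _jc_evolve(root, 0.15, rng)
            _m1, _m2, _stat, p = tajima_relative_rate(a, b, o)
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.02 <= rate <= 0.08
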