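import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tasscat import evolution, simulate


class TestParsimony:
    def test_all_64_triples_follow_the_rule(self):
        for h, m, g in itertools.product("ACGT", repeat=3):
            got = evolution.parsimony_ancestor(h, m, g)
            if h == m:
                expected = h
            elif g in (h, m):
                expected = g
            else:
                expected = None
            assert got == expected, (h, m, g)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        H, M, G = (rng.integers(0, 4, 500).astype(np.uint8)
                   for _ in range(3))
        anc = evolution.parsimony_ancestor_array(H, M, G)
        nts = "ACGT"
        for i in range(500):
            scalar = evolution.parsimony_ancestor(nts[H[i]], nts[M[i]],
                                                  nts[G[i]])
            assert (scalar is None and anc[i] == -1) or \
                (scalar == nts[anc[i]])


class TestConsensusMap:
    def test_threshold_rule(self):
        rng = np.random.default_rng(1)
        seqs = simulate.draw_sites_from_pwm(simulate.donor_pwm_probs(),
                                            3000, rng)
        cmap = evolution.build_consensus_map(seqs, "donor",
                                             cn_threshold=0.35)
        # obligate GT positions are single-consensus
        assert cmap.cn[0].tolist() == [False, False, True, False]
        assert cmap.cn[1].tolist() == [False, False, False, True]
        # +4 is A-dominant (freq ~0.68)
        assert cmap.cn[3, 0]

    def test_lower_threshold_admits_more_consensus_bases(self):
        rng = np.random.default_rng(2)
        seqs = simulate.draw_sites_from_pwm(simulate.donor_pwm_probs(),
                                            3000, rng)
        strict = evolution.build_consensus_map(seqs, "donor",
                                               cn_threshold=0.35)
        loose = evolution.build_consensus_map(seqs, "donor",
                                              cn_threshold=0.15)
        assert loose.cn.sum() > strict.cn.sum()
        assert (loose.cn | ~strict.cn).all()   # strict Cn subset of loose

    def test_too_few_sequences(self):
        with pytest.raises(ValueError, match=">= 100"):
            evolution.build_consensus_map(["GTAAGT"] * 50, "donor")


class TestCountSubstitutions:
    def _map(self):
        # donor map with Cn = {A} at +3/+4, {G} at +5, {T} at +6
        pwm = simulate.donor_pwm_probs()
        cn = pwm >= 0.35
        return evolution.ConsensusMap("donor", pwm, cn, 0.35)

    def test_hand_computed_example(self):
        cmap = self._map()
        bg = evolution.BackgroundRates(
            counts=np.full(4, 1000.0),
            subs=np.full((4, 4), 10.0) - np.diag(np.full(4, 10.0)))
        # ancestor GT AAGT; marmoset substitutes +3 A->C (Cn->Nc),
        # galago matches human so parsimony gives the human base
        human, marmoset, galago = ["GTAAGT"], ["GTCAGT"], ["GTAAGT"]
        st_df = evolution.site_substitution_stats(human, marmoset, galago,
                                                  cmap, bg)
        row = st_df.iloc[0]
        assert row["canonical"]
        assert row["obs_cn2nc"] == 1
        assert row["opp_cn"] == 4          # A,A,G,T all consensus
        # expected: 4 opportunities x 3 non-consensus targets x rate 0.01
        assert row["exp_cn2nc"] == pytest.approx(4 * 3 * 0.01)
        assert row["opp_nc"] == 0

    def test_non_canonical_dinucleotide_excluded(self):
        cmap = self._map()
        bg = evolution.BackgroundRates(np.full(4, 100.0), np.ones((4, 4)))
        st_df = evolution.site_substitution_stats(
            ["GAAAGT"], ["GAAAGT"], ["GAAAGT"], cmap, bg)
        assert not st_df.iloc[0]["canonical"]
        assert math.isnan(st_df.iloc[0]["obs_cn2nc"])

    def test_ancestor_equals_derived_is_opportunity_only(self):
        cmap = self._map()
        bg = evolution.BackgroundRates(np.full(4, 100.0), np.ones((4, 4)))
        st_df = evolution.site_substitution_stats(
            ["GTAAGT"], ["GTAAGT"], ["GTAAGT"], cmap, bg)
        assert st_df.iloc[0]["obs_cn2nc"] == 0
        assert st_df.iloc[0]["opp_cn"] == 4


class TestOeRatioCi:
    def test_equal_proportions(self):
        oe, lo, hi = evolution.oe_ratio_ci(10, 100, 10, 100)
        assert oe == 1.0 and lo < 1.0 < hi

    def test_zero_numerator(self):
        oe, lo, hi = evolution.oe_ratio_ci(0, 100, 10, 100)
        assert oe == 0.0 and lo == 0.0 and hi > 0

    def test_zero_denominator_infinite_upper(self):
        oe, lo, hi = evolution.oe_ratio_ci(5, 100, 0, 100)
        assert math.isinf(hi)

    def test_matches_numeric_score_inversion(self):
        # brute-force: scan theta, keep where the score statistic is below
        # the chi-square critical value, compare the hull to the solver
        x1, n1, x2, n2 = 5, 50, 20, 100
        oe, lo, hi = evolution.oe_ratio_ci(x1, n1, x2, n2)
        crit = stats.chi2.ppf(0.95, 1)
        grid = np.linspace(1e-4, 3, 200_000)
        vals = np.array([evolution._koopman_chi2(t, x1, n1, x2, n2)
                         for t in grid])
        inside = grid[vals <= crit]
        assert oe == pytest.approx(0.5)
        assert lo == pytest.approx(inside.min(), abs=1e-4)
        assert hi == pytest.approx(inside.max(), abs=1e-4)

    def test_interval_shrinks_with_sample_size(self):
        widths = []
        for scale in (1, 4, 16):
            _, lo, hi = evolution.oe_ratio_ci(5 * scale, 50 * scale,
                                              20 * scale, 100 * scale)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_coverage_under_simulation(self):
        rng = np.random.default_rng(3)
        p1, p2, n1, n2 = 0.05, 0.05, 800, 800
        cover = 0
        for _ in range(300):
            x1 = rng.binomial(n1, p1)
            x2 = rng.binomial(n2, p2)
            if x1 == 0 or x2 == 0:
                cover += 1
                continue
            _, lo, hi = evolution.oe_ratio_ci(x1, n1, x2, n2)
            cover += lo <= 1.0 <= hi
        assert 0.92 <= cover / 300 <= 0.99


class TestMatchByStrength:
    def test_within_tolerance_matching(self):
        matched = evolution.match_by_strength([8.00], [8.005, 9.0], rng=0)
        assert matched[0] == 0

    def test_nearest_outside_tolerance_unmatched(self):
        matched = evolution.match_by_strength([8.00], [8.02], rng=0)
        assert matched[0] == -1

    def test_empty_pool(self):
        matched = evolution.match_by_strength([1.0, 2.0], [], rng=0)
        assert (matched == -1).all()

    def test_without_replacement(self):
        matched = evolution.match_by_strength([5.0, 5.0, 5.0],
                                              [5.0, 5.001], rng=1)
        used = matched[matched >= 0]
        assert len(set(used)) == len(used)
        assert (matched == -1).sum() == 1


class TestEstimateAlpha:
    def _sets(self, seed=0):
        rng = np.random.default_rng(seed)
        # positive: low substitution load; negative: neutral load
        pos_obs = rng.poisson(0.2, 4000).astype(float)
        neg_obs = rng.poisson(1.0, 4000).astype(float)
        exp = np.full(4000, 1.0)
        return pos_obs, exp, neg_obs, exp

    def test_pure_positive_sample_gives_low_alpha(self):
        po, pe, no, ne = self._sets()
        obs_oe = po[:2000].sum() / 2000
        est = evolution.estimate_alpha(obs_oe, po, pe, no, ne, k=2000,
                                       grid_step=0.02, B=60, rng=0)
        assert est.alpha_low <= 0.05

    def test_pure_negative_sample_gives_high_alpha(self):
        po, pe, no, ne = self._sets()
        obs_oe = no[:2000].sum() / 2000
        est = evolution.estimate_alpha(obs_oe, po, pe, no, ne, k=2000,
                                       grid_step=0.02, B=60, rng=0)
        assert est.alpha_high >= 0.95

    def test_interval_is_ordered(self):
        po, pe, no, ne = self._sets()
        est = evolution.estimate_alpha(0.6, po, pe, no, ne, k=2000,
                                       grid_step=0.02, B=60, rng=0)
        assert est.alpha_low <= est.alpha_median <= est.alpha_high

    def test_observed_outside_range_raises(self):
        po, pe, no, ne = self._sets()
        with pytest.raises(ValueError):
            evolution.estimate_alpha(25.0, po, pe, no, ne, k=2000,
                                     grid_step=0.05, B=20, rng=0)


class TestMaxAlleleFrequency:
    def test_max_in_window(self):
        af = evolution.max_allele_frequency(
            "donor", "+", 1000, [(990, 0.01), (1003, 0.3)])
        assert af == pytest.approx(0.3)

    def test_no_snps_missing(self):
        assert math.isnan(
            evolution.max_allele_frequency("donor", "+", 1000, []))

    def test_donor_window_excludes_far_exonic_snp(self):
        # 40 nt into the exon is outside [-35, +6]
        assert math.isnan(evolution.max_allele_frequency(
            "donor", "+", 1000, [(960, 0.2)]))
        assert evolution.max_allele_frequency(
            "donor", "+", 1000, [(970, 0.2)]) == pytest.approx(0.2)

    def test_minus_strand_orientation(self):
        # on the minus strand a genomic position above the site is
        # transcript-upstream (negative offset)
        assert evolution.max_allele_frequency(
            "acceptor", "-", 1000, [(1010, 0.4)]) == pytest.approx(0.4)
        assert math.isnan(evolution.max_allele_frequency(
            "acceptor", "-", 1000, [(1030, 0.4)]))
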