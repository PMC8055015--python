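import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tasscat import catalog


def _site(pos, sources=("expressed",), chrom="chr1", strand="+",
          kind="donor"):
    return catalog.SpliceSite(chrom, pos, strand, kind,
                              frozenset(sources))


class TestMergeSources:
    def test_single_source_and_union(self):
        cat = catalog.merge_sources(
            annotated=[("chr1", 100, "+", "donor")],
            expressed=[("chr1", 100, "+", "donor"),
                       ("chr1", 200, "+", "donor")],
            cryptic=[("chr1", 300, "+", "donor")],
            cryptic_scores={("chr1", 300, "+", "donor"): 0.4})
        assert cat[("chr1", 100, "+", "donor")].sources == {
            "annotated", "expressed"}
        assert cat[("chr1", 200, "+", "donor")].sources == {"expressed"}
        assert cat[("chr1", 300, "+", "donor")].cryptic_score == 0.4

    def test_cryptic_flag_dropped_when_annotated_or_expressed(self):
        # a site with expression or annotation evidence is not cryptic
        key = ("chr1", 100, "+", "donor")
        cat = catalog.merge_sources([key], [key], [key])
        assert cat[key].sources == {"annotated", "expressed"}

    def test_empty_inputs(self):
        assert catalog.merge_sources([], [], []) == {}

    def test_conflicting_kind_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="conflicting"):
            cat = catalog.merge_sources(
                [("chr1", 100, "+", "donor")],
                [("chr1", 100, "+", "acceptor")], [])
        assert list(cat) == [("chr1", 100, "+", "donor")]


class TestCallExpressed:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "sample_id",
                                           "tissue", "reads", "entropy"])

    def test_two_tissue_rule(self):
        df = self._df([("x", "a", "liver", 3, 2.0),
                       ("x", "b", "lung", 4, 2.0),
                       ("y", "a", "liver", 10, 2.0),
                       ("z", "a", "liver", 3, 2.0),
                       ("z", "c", "liver", 3, 2.0)])
        assert catalog.call_expressed(df) == {"x"}

    def test_entropy_filter_excludes_low_complexity_junctions(self):
        df = self._df([("x", "a", "liver", 5, 2.0),
                       ("x", "b", "lung", 5, 1.0)])
        assert catalog.call_expressed(df) == set()
        assert catalog.call_expressed(df, entropy_min=0.5) == {"x"}

    def test_missing_entropy_is_passthrough_with_warning(self):
        df = self._df([("x", "a", "liver", 5, 0.0),
                       ("x", "b", "lung", 5, 0.0)])[
            ["site_id", "sample_id", "tissue", "reads"]]
        with pytest.warns(UserWarning, match="pass-through"):
            assert catalog.call_expressed(df) == {"x"}

    def test_negative_counts_raise(self):
        df = self._df([("x", "a", "liver", -1, 2.0)])
        with pytest.raises(ValueError):
            catalog.call_expressed(df)

    def test_monotone_in_reads(self):
        # adding reads never un-expresses a site
        base = [("x", "a", "liver", 3, 2.0), ("x", "b", "lung", 3, 2.0)]
        assert catalog.call_expressed(self._df(base)) == {"x"}
        more = base + [("x", "c", "heart", 50, 2.0)]
        assert catalog.call_expressed(self._df(more)) == {"x"}


class TestPolymorphicArtifactFilter:
    @pytest.mark.parametrize("expr,carriers,removed", [
        ({"s1", "s2"}, {"s1", "s2", "s3"}, True),   # subset -> artifact
        ({"s1", "s4"}, {"s1"}, False),              # expressed beyond carriers
        ({"s1"}, set(), False),                      # no variants near site
    ])
    def test_subset_rule(self, expr, carriers, removed):
        kept, dropped = catalog.filter_polymorphic_artifacts(
            ["x"], {"x": expr}, {"x": carriers})
        assert (dropped == ["x"]) is removed


class TestClustering:
    def test_chaining_and_gap(self):
        cat = {s.key: s for s in [_site(100), _site(120), _site(145),
                                  _site(300), _site(340)]}
        clusters, standalone = catalog.cluster(cat)
        assert len(clusters) == 1 and clusters[0].size == 3
        assert clusters[0].positions == [100, 120, 145]
        assert sorted(s.pos for s in standalone) == [300, 340]

    def test_different_kinds_never_cluster(self):
        cat = {s.key: s for s in [_site(100, kind="donor"),
                                  _site(110, kind="acceptor")]}
        clusters, standalone = catalog.cluster(cat)
        assert not clusters and len(standalone) == 2

    def test_size_and_expression_filters_flag_not_delete(self):
        big = [_site(100 + 10 * i) for i in range(6)]
        cat = {s.key: s for s in big}
        clusters, _ = catalog.cluster(cat, max_size=5)
        assert len(clusters) == 1 and not clusters[0].passes_filters
        silent = [_site(100, sources=("annotated",)),
                  _site(110, sources=("cryptic",))]
        clusters, _ = catalog.cluster({s.key: s for s in silent})
        assert not clusters[0].passes_filters

    def test_reclustering_is_idempotent(self):
        rng = np.random.default_rng(5)
        pos = np.unique(rng.integers(0, 5000, size=200))
        cat = {s.key: s for s in map(_site, pos)}
        clusters1, standalone1 = catalog.cluster(cat)
        flat = {s.key: s for c in clusters1 for s in c.members}
        flat.update({s.key: s for s in standalone1})
        clusters2, standalone2 = catalog.cluster(flat)
        assert [c.positions for c in clusters1] == \
            [c.positions for c in clusters2]
        # partition: every site in exactly one cluster or standalone
        n = sum(c.size for c in clusters1) + len(standalone1)
        assert n == len(cat)


class TestRanking:
    def _cluster(self, positions, strand="+"):
        members = [_site(p, strand=strand) for p in positions]
        return catalog.TassCluster("c", "chr1", strand, "donor", members)

    def test_descending_counts(self):
        cl = self._cluster([10, 40, 70])
        counts = {("chr1", 10, "+", "donor"): 1000,
                  ("chr1", 40, "+", "donor"): 30,
                  ("chr1", 70, "+", "donor"): 5}
        ranks = catalog.rank_sites(cl, counts)
        assert [ranks[s.key] for s in cl.members] == [1, 2, 3]

    @pytest.mark.parametrize("strand,winner_pos", [("+", 10), ("-", 40)])
    def test_tie_goes_to_transcript_upstream_site(self, strand, winner_pos):
        cl = self._cluster([10, 40], strand=strand)
        counts = {("chr1", 10, strand, "donor"): 50,
                  ("chr1", 40, strand, "donor"): 50}
        ranks = catalog.rank_sites(cl, counts)
        assert ranks[("chr1", winner_pos, strand, "donor")] == 1

    def test_all_zero_cluster_excluded(self):
        cl = self._cluster([10, 40])
        assert catalog.rank_sites(cl, {}) is None

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(0)
        pos = sorted(rng.choice(1000, size=5, replace=False))
        cl = self._cluster(pos)
        counts = {s.key: int(rng.integers(1, 100)) for s in cl.members}
        ranks = catalog.rank_sites(cl, counts)
        assert sorted(ranks.values()) == [1, 2, 3, 4, 5]


class TestShiftAndFrame:
    @pytest.mark.parametrize(
        "pos_miss,pos_mass,kind,strand,shift,frame,side", [
            (104, 100, "donor", "+", 4, False, "intronic"),
            (103, 100, "acceptor", "-", -3, True, "intronic"),
            (106, 100, "donor", "+", 6, True, "intronic"),
            (97, 100, "donor", "+", -3, True, "exonic"),
            (109, 100, "acceptor", "+", 9, True, "exonic"),
        ])
    def test_examples(self, pos_miss, pos_mass, kind, strand, shift,
                      frame, side):
        assert catalog.shift_and_frame(pos_miss, pos_mass, kind, strand) \
            == (shift, frame, side)

    def test_zero_shift_raises(self):
        with pytest.raises(ValueError):
            catalog.shift_and_frame(100, 100, "donor", "+")

    @given(st.integers(-30, 30).filter(bool),
           st.sampled_from(["donor", "acceptor"]))
    @settings(deadline=None, max_examples=60)
    def test_strand_mirror_symmetry(self, genomic_shift, kind):
        # the same transcript-level event on opposite strands agrees
        pos_mass = 1000
        s_plus = catalog.shift_and_frame(pos_mass + genomic_shift, pos_mass,
                                         kind, "+")
        s_minus = catalog.shift_and_frame(pos_mass - genomic_shift, pos_mass,
                                          kind, "-")
        assert s_plus == s_minus


class TestPhiAndSupports:
    def test_phi_worked_example(self):
        assert catalog.compute_phi(3, 4) == pytest.approx(3 / 7, abs=1e-15)

    def test_phi_edges(self):
        assert catalog.compute_phi(0, 50) == 0
        assert math.isnan(catalog.compute_phi(0, 0))
        with pytest.raises(ValueError):
            catalog.compute_phi(-1, 5)

    def test_phi_complement(self):
        r1, r2 = 13, 29
        assert catalog.compute_phi(r1, r2) + catalog.compute_phi(r2, r1) \
            == pytest.approx(1.0)

    def test_nmd_response(self):
        r = catalog.nmd_response("m", 0.3, 0.1, 100)
        assert r.delta == pytest.approx(0.2)
        assert catalog.nmd_response("m", 0.1, 0.1, 5) is None

    def test_riboseq_support(self):
        assert catalog.riboseq_support(10, 30) == 0.25
        assert catalog.riboseq_support(0, 5) == 0
        assert math.isnan(catalog.riboseq_support(0, 0))


class TestPwmStrength:
    def test_consensus_is_maximal_and_uniform_scores_zero(self):
        pwm = catalog.build_pwm(["GTAAGT"] * 8 + ["GTGAGT"] * 2)
        consensus = "GTAAGT"
        best = catalog.pwm_strength(consensus, pwm)
        for other in ["GTGAGT", "GTAAGA"]:
            if (pwm > 0).all():
                assert catalog.pwm_strength(other, pwm) <= best
        uniform = np.full((6, 4), 0.25)
        assert catalog.pwm_strength("GTAAGT", uniform) == pytest.approx(0)

    def test_single_mismatch_additivity(self):
        pwm = np.tile(np.array([[0.5, 0.3, 0.1, 0.1]]), (4, 1))
        base = catalog.pwm_strength("AAAA", pwm)
        one_off = catalog.pwm_strength("CAAA", pwm)
        assert base - one_off == pytest.approx(
            np.log2(0.5 / 0.25) - np.log2(0.3 / 0.25))
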