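"""Conservation classifier: replicate consensus, boundary/domain taxonomy,
co-linearity, breakpoints and the Table-1 report arithmetic."""

import numpy as np
import pytest

from tadevol.classify import (
    Breakpoint,
    SyntenyBlock,
    build_table1,
    classify_boundaries,
    classify_domain,
    classify_domains,
    colinearity,
    count_categories,
    count_statuses,
    derive_breakpoints,
    replicate_consensus,
    round_pct,
    shuffle_expected_colinear,
)
from tadevol.core import ChromSizes, ConfigurationError, FeatureSet, GenomicInterval

from conftest import make_map


def iv(c, s, e):
    return GenomicInterval(c, s, e)


def fs(name, triples, names=None):
    return FeatureSet(name, [iv(*t) for t in triples], names)


class TestReplicateConsensus:
    def test_boundaries_overlap_one_bp(self):
        r1 = fs("r1", [("c", 0, 5000), ("c", 20_000, 25_000)], ["a", "b"])
        r2 = fs("r2", [("c", 4_999, 9_000), ("c", 50_000, 55_000)], ["x", "y"])
        high, low = replicate_consensus(r1, r2, "boundary")
        assert high.feature_names() == ["a"]  # 1 bp overlap suffices
        assert (high.intervals[0].start, high.intervals[0].end) == (0, 9_000)
        assert sorted(low.feature_names()) == ["b", "y"]

    def test_domains_endpoint_tolerance(self):
        r1 = fs("r1", [("c", 0, 100_000)], ["d1"])
        r2 = fs("r2", [("c", 4_000, 104_000)], ["e1"])
        high, low = replicate_consensus(r1, r2, "domain", domain_tol=5_000)
        assert high.feature_names() == ["d1"]
        r3 = fs("r3", [("c", 6_000, 106_000)], ["e1"])
        high2, low2 = replicate_consensus(r1, r3, "domain", domain_tol=5_000)
        assert len(high2) == 0
        assert len(low2) == 2


class TestClassifyBoundaries:
    def test_identity_is_orthologous_distance_zero(self, identity_map):
        src = fs("b", [("chrA", 100_000, 105_000)], ["b1"])
        tgt = fs("t", [("chrA", 100_000, 105_000)])
        (s,) = classify_boundaries(src, identity_map, tgt)
        assert s.status == "orthologous"
        assert s.distance == 0

    @pytest.mark.parametrize("gap, status", [(4_999, "orthologous"),
                                             (5_000, "lineage_specific")])
    def test_strict_distance_threshold(self, identity_map, gap, status):
        src = fs("b", [("chrA", 100_000, 105_000)], ["b1"])
        tgt = fs("t", [("chrA", 105_000 + gap, 110_000 + gap)])
        (s,) = classify_boundaries(src, identity_map, tgt)
        assert s.status == status

    def test_unmapped_boundary_is_missing(self):
        m = make_map([(("s", 0, 1_000), ("t", 0, 1_000), "+")],
                     {"s": 1_000_000}, {"t": 1_000_000})
        src = fs("b", [("s", 500_000, 505_000)], ["b1"])
        (s,) = classify_boundaries(src, m, fs("t", [("t", 0, 5_000)]))
        assert s.status == "missing"


class TestClassifyDomain:
    def test_identity_orthologous_with_shared_boundaries(self):
        region = [iv("t", 0, 100_000)]
        tgt = fs("d", [("t", 0, 100_000)])
        share = fs("b", [("t", 0, 2_000), ("t", 98_000, 100_000)])
        cat = classify_domain("d1", region, "mapped", tgt, fs("ls", []),
                              tgt_share_boundaries=share)
        assert cat.category == "orthologous"
        assert cat.shared_boundaries
        assert cat.frac_region == 1.0 and cat.frac_target == 1.0

    def test_overlap_arithmetic_truncated_expanded(self):
        # 100 kb region inside a 112 kb target: fractions 1.0 and 0.893
        region = [iv("t", 0, 100_000)]
        tgt = fs("d", [("t", 0, 112_000)])
        cat = classify_domain("d1", region, "mapped", tgt, fs("ls", []))
        assert cat.category == "truncated_expanded"
        assert cat.frac_region == 1.0
        assert cat.frac_target == pytest.approx(100 / 112, abs=1e-6)

    def test_multi_chromosome_regions_split_by_rearrangement(self):
        regions = [iv("t1", 0, 50_000), iv("t2", 0, 40_000)]
        cat = classify_domain("d1", regions, "mapped", fs("d", []), fs("ls", []))
        assert cat.category == "split_by_rearrangement"

    def test_lineage_specific_boundary_inside_splits(self):
        region = [iv("t", 0, 100_000)]
        tgt = fs("d", [("t", 0, 48_000), ("t", 52_000, 100_000)])
        ls = fs("ls", [("t", 48_000, 52_000)])
        cat = classify_domain("d1", region, "mapped", tgt, ls)
        assert cat.category == "split_by_boundary"

    def test_edge_boundary_does_not_split(self):
        # a lineage-specific boundary within 5 kb of the region endpoint is
        # not "strictly inside"; the residual category applies
        region = [iv("t", 0, 100_000)]
        tgt = fs("d", [("t", 0, 112_000)])
        ls = fs("ls", [("t", 99_000, 104_000)])
        cat = classify_domain("d1", region, "mapped", tgt, ls)
        assert cat.category == "truncated_expanded"

    def test_missing(self):
        cat = classify_domain("d1", [], "missing", fs("d", []), fs("ls", []))
        assert cat.category == "missing"

    def test_decision_order_rearrangement_wins(self):
        # two regions AND an internal lineage-specific boundary: the
        # multi-region evidence takes precedence
        regions = [iv("t", 0, 40_000), iv("t", 80_000, 120_000)]
        ls = fs("ls", [("t", 20_000, 25_000)])
        cat = classify_domain("d1", regions, "mapped", fs("d", []), ls)
        assert cat.category == "split_by_rearrangement"


class TestColinearity:
    BLOCKS = [SyntenyBlock(iv("c", 0, 100_000), iv("t", 0, 100_000)),
              SyntenyBlock(iv("c", 100_000, 250_000), iv("t", 200_000, 350_000))]

    def test_contained_feature(self):
        flags = colinearity(fs("f", [("c", 10_000, 50_000)]), self.BLOCKS)
        assert flags == [True]

    def test_straddling_junction(self):
        flags = colinearity(fs("f", [("c", 90_000, 110_000)]), self.BLOCKS)
        assert flags == [False]

    def test_chromosome_without_blocks(self):
        flags = colinearity(fs("f", [("cX", 0, 1_000)]), self.BLOCKS)
        assert flags == [False]


class TestShuffleExpected:
    def test_full_coverage_gives_total(self):
        blocks = [SyntenyBlock(iv("c", 0, 1_000_000), iv("t", 0, 1_000_000))]
        feats = fs("f", [("c", i * 1_000, i * 1_000 + 100) for i in range(20)])
        mean, counts = shuffle_expected_colinear(
            feats, blocks, ChromSizes({"c": 1_000_000}), n_shuffles=10, seed=0)
        assert mean == 20.0
        assert all(c == 20 for c in counts)

    def test_half_coverage_binomial_expectation(self):
        blocks = [SyntenyBlock(iv("c", 0, 500_000), iv("t", 0, 500_000))]
        feats = fs("f", [("c", 0, 1) for _ in range(100)])
        mean, _ = shuffle_expected_colinear(
            feats, blocks, ChromSizes({"c": 1_000_000}), n_shuffles=100, seed=1)
        # each point feature falls in the block with p = 1/2
        assert abs(mean - 50) < 3 * np.sqrt(100 * 0.25)

    def test_single_shuffle_deterministic(self):
        blocks = [SyntenyBlock(iv("c", 0, 500_000), iv("t", 0, 500_000))]
        feats = fs("f", [("c", 0, 10_000) for _ in range(10)])
        m1, c1 = shuffle_expected_colinear(feats, blocks,
                                           ChromSizes({"c": 1_000_000}), 1, seed=3)
        m2, c2 = shuffle_expected_colinear(feats, blocks,
                                           ChromSizes({"c": 1_000_000}), 1, seed=3)
        assert c1 == c2 and m1 == m2

    def test_feature_longer_than_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            shuffle_expected_colinear(fs("f", [("c", 0, 2_000_000)]), [],
                                      ChromSizes({"c": 1_000_000}), 1, 0)


class TestDeriveBreakpoints:
    def test_junction_between_adjacent_blocks(self):
        blocks = [SyntenyBlock(iv("c", 0, 100_000), iv("t", 0, 100_000)),
                  SyntenyBlock(iv("c", 100_000, 200_000), iv("t", 300_000, 400_000))]
        bks = derive_breakpoints(blocks, fs("b", []), fs("d", []))
        assert [(b.chrom, b.pos) for b in bks] == [("c", 100_000)]

    def test_single_block_no_breakpoints(self):
        blocks = [SyntenyBlock(iv("c", 0, 100_000), iv("t", 0, 100_000))]
        assert derive_breakpoints(blocks, fs("b", []), fs("d", [])) == []

    @pytest.mark.parametrize("gap, intra", [(5_001, True), (5_000, False)])
    def test_strict_intra_tad_distance(self, gap, intra):
        pos = 100_000
        blocks = [SyntenyBlock(iv("c", 0, pos), iv("t", 0, pos)),
                  SyntenyBlock(iv("c", pos, 200_000), iv("t", 300_000, 400_000))]
        boundary_end = pos - gap
        bnd = fs("b", [("c", boundary_end - 5_000, boundary_end)])
        dom = fs("d", [("c", boundary_end, 190_000)])
        (b,) = derive_breakpoints(blocks, bnd, dom, bt_dist=5_000)
        assert b.intra_tad is intra


class TestBuildTable1:
    def test_partition_enforced(self):
        # an unrecognised status breaks the partition and is rejected
        with pytest.raises(ConfigurationError):
            build_table1({"orthologous": 5, "unknown": 2, "missing": 1},
                         {"orthologous": 4, "missing": 0})
        with pytest.raises(ConfigurationError):
            build_table1({"orthologous": 5, "lineage_specific": 1, "missing": 1},
                         {"orthologous": 1, "mystery_category": 3, "missing": 0})

    def test_all_orthologous_toy(self):
        t = build_table1(
            {"orthologous": 10, "lineage_specific": 0, "missing": 0},
            {"orthologous": 5, "truncated_expanded": 0, "split_by_boundary": 0,
             "split_by_rearrangement": 0, "missing": 0})
        assert t["boundaries"]["orthologous"]["pct"] == 100
        assert t["domains"]["non_orthologous"]["pct"] == 0

    def test_rounding_half_away_from_zero(self):
        assert round_pct(544, 552) == 99   # 98.55 -> 99
        assert round_pct(1, 200) == 1      # 0.5 -> 1
        assert round_pct(473, 654) == 72


def test_status_category_partition(noiseless_pair):
    """Classification statuses and categories partition the input sets."""
    from tadevol.pipeline import (PipelineConfig, consensus_calls,
                                  lineage_specific_boundaries, classify_direction)
    from tadevol.chain import invert_map

    cfg = PipelineConfig()
    ca = consensus_calls(noiseless_pair.species_a)
    cb = consensus_calls(noiseless_pair.species_b)
    ls_b = lineage_specific_boundaries(cb["boundaries_high"],
                                       invert_map(noiseless_pair.chain),
                                       ca["boundaries_all"], cfg)
    res = classify_direction(ca, cb, noiseless_pair.chain, ls_b, cfg)
    sc = count_statuses(res["boundary_statuses"])
    assert sum(sc.values()) == len(ca["boundaries_high"])
    cc = count_categories(res["domain_categories"])
    assert sum(cc.values()) == len(ca["domains_high"])
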