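"""Liftover engine: chain I/O, interval lifting, merging, inversion.

The central check is per-base agreement between ``lift_interval`` and an
independent brute-force position lookup implemented here directly from the
alignment-block semantics.
"""

import numpy as np
import pytest

from tadevol.chain import (
    AlignmentBlock,
    ChainFormatError,
    OrthologyMap,
    invert_map,
    lift_and_merge,
    lift_interval,
    merge_lifted,
    read_chain,
    write_chain,
)
from tadevol.core import ChromSizes, CoordinateError, GenomicInterval

from conftest import make_map


def brute_force_map(m: OrthologyMap, chrom: str, pos: int):
    """Independent per-base lookup straight from block semantics."""
    for b in m.blocks:
        if b.src.chrom == chrom and b.src.start <= pos < b.src.end:
            off = pos - b.src.start
            if b.orientation == "+":
                return b.tgt.chrom, b.tgt.start + off
            return b.tgt.chrom, b.tgt.start + (len(b.src) - 1 - off)
    return None


def lifted_base_set(feature):
    """Set of (chrom, pos) covered by the raw lifted segments."""
    out = set()
    for seg in feature.raw_segments:
        for x in range(seg.start, seg.end):
            out.add((seg.chrom, x))
    return out


class TestChainIO:
    def test_identity_chain_round_trip(self, identity_map, tmp_path):
        path = tmp_path / "id.chain"
        write_chain(identity_map, path)
        m2 = read_chain(path)
        assert len(m2.blocks) == 1
        assert m2.blocks[0].orientation == "+"
        assert m2.blocks[0].src == identity_map.blocks[0].src
        # writer output is stable under a read/write cycle
        path2 = tmp_path / "id2.chain"
        write_chain(m2, path2)
        assert path.read_text() == path2.read_text()

    def test_minus_strand_coordinates_normalized(self, tmp_path):
        # one chain: src [100, 200) aligned to the reverse strand of a
        # 1000 bp target, reverse-strand coords [300, 400)
        # -> forward interval [600, 700)
        text = ("chain 100 srcC 1000 + 100 200 tgtC 1000 - 300 400 1\n"
                "100\n\n")
        path = tmp_path / "inv.chain"
        path.write_text(text)
        m = read_chain(path)
        (b,) = m.blocks
        assert b.orientation == "-"
        assert (b.tgt.start, b.tgt.end) == (600, 700)
        # hand-computed per-base: src 100 -> forward 699, src 199 -> 600
        assert brute_force_map(m, "srcC", 100) == ("tgtC", 699)
        assert brute_force_map(m, "srcC", 199) == ("tgtC", 600)
        out = tmp_path / "roundtrip.chain"
        write_chain(m, out)
        assert read_chain(out).blocks == m.blocks

    def test_overlapping_target_blocks_rejected(self):
        with pytest.raises(ChainFormatError):
            make_map(
                [(("s", 0, 100), ("t", 0, 100), "+"),
                 (("s", 200, 300), ("t", 50, 150), "+")],
                {"s": 1000}, {"t": 1000},
            )

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.chain"
        path.write_text("chain oops\n")
        with pytest.raises(ChainFormatError, match="line 1"):
            read_chain(path)


class TestLiftInterval:
    def test_identity(self, identity_map):
        lifted = lift_interval(identity_map, GenomicInterval("chrA", 100, 200))
        assert lifted.status == "mapped"
        assert [(s.start, s.end) for s in lifted.raw_segments] == [(100, 200)]

    def test_query_spanning_inversion_junction(self, inversion_map):
        q = GenomicInterval("chrA", 250_000, 350_000)
        lifted = lift_interval(inversion_map, q)
        assert len(lifted.raw_segments) >= 2
        assert any(s.strand == "-" for s in lifted.raw_segments)
        expected = {brute_force_map(inversion_map, "chrA", x)
                    for x in range(q.start, q.end)}
        assert lifted_base_set(lifted) == expected

    def test_query_in_chain_gap_is_missing(self):
        m = make_map([(("s", 0, 100), ("t", 0, 100), "+"),
                      (("s", 500, 600), ("t", 500, 600), "+")],
                     {"s": 1000}, {"t": 1000})
        lifted = lift_interval(m, GenomicInterval("s", 200, 300))
        assert lifted.status == "missing"
        assert lifted.raw_segments == []

    def test_unknown_chromosome_raises(self, identity_map):
        with pytest.raises(CoordinateError):
            lift_interval(identity_map, GenomicInterval("chrZ", 0, 10))


class TestMergeLifted:
    def test_domain_parameters_merge_small_gap(self):
        m = make_map([(("s", 0, 10_000), ("t", 0, 10_000), "+"),
                      (("s", 10_000, 25_000), ("t", 25_000, 40_000), "+")],
                     {"s": 100_000}, {"t": 100_000})
        lifted = lift_and_merge(m, GenomicInterval("s", 0, 25_000),
                                merge_gap=20_000, min_size=5_000)
        assert [(r.start, r.end) for r in lifted.merged_regions] == [(0, 40_000)]

    def test_boundary_parameters_drop_small_fragment(self, identity_map):
        lifted = lift_interval(identity_map, GenomicInterval("chrA", 100, 500))
        merged = merge_lifted(lifted, merge_gap=5_000, min_size=500)
        assert merged.status == "missing"
        assert merged.merged_regions == []

    def test_single_large_segment_unchanged(self, identity_map):
        lifted = lift_and_merge(identity_map, GenomicInterval("chrA", 0, 10_000),
                                merge_gap=5_000, min_size=500)
        assert [(r.start, r.end) for r in lifted.merged_regions] == [(0, 10_000)]


class TestInvertMap:
    def test_involution(self, inversion_map):
        back = invert_map(invert_map(inversion_map))
        assert back.blocks == inversion_map.blocks

    def test_identity_fixed_point(self, identity_map):
        assert invert_map(identity_map).blocks == identity_map.blocks

    def test_round_trip_of_mapped_bases(self, inversion_map):
        inv = invert_map(inversion_map)
        rng = np.random.default_rng(5)
        for pos in rng.integers(0, 1_000_000, size=200):
            img = brute_force_map(inversion_map, "chrA", int(pos))
            assert img is not None
            back = brute_force_map(inv, img[0], img[1])
            assert back == ("chrA", int(pos))

    def test_total_mapped_length_conserved(self, inversion_map):
        assert (invert_map(inversion_map).total_mapped_length()
                == inversion_map.total_mapped_length())


def random_small_map(rng) -> OrthologyMap:
    """A random gappy map of a 2000 bp chromosome with inversions."""
    blocks = []
    src = tgt = 0
    while src < 1800:
        size = int(rng.integers(20, 200))
        orient = "-" if rng.random() < 0.3 else "+"
        blocks.append(AlignmentBlock(
            GenomicInterval("s", src, src + size),
            GenomicInterval("t", tgt, tgt + size), orient))
        src += size + int(rng.integers(0, 100))
        tgt += size + int(rng.integers(0, 100))
    return OrthologyMap(blocks, ChromSizes({"s": 4000}), ChromSizes({"t": 4000}))


def test_per_base_oracle_on_random_maps():
    """lift_interval agrees base-by-base with brute force on random gappy
    maps containing inversions; source order of segments is respected."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        m = random_small_map(rng)
        for _ in range(10):
            a = int(rng.integers(0, 1900))
            b = a + int(rng.integers(1, 400))
            lifted = lift_interval(m, GenomicInterval("s", a, b))
            expected = {brute_force_map(m, "s", x) for x in range(a, b)}
            expected.discard(None)
            assert lifted_base_set(lifted) == expected


def test_monotonic_segment_order_on_colinear_map():
    rng = np.random.default_rng(9)
    blocks = []
    src = tgt = 0
    for _ in range(8):
        size = int(rng.integers(20, 100))
        blocks.append(AlignmentBlock(GenomicInterval("s", src, src + size),
                                     GenomicInterval("t", tgt, tgt + size), "+"))
        src += size + 30
        tgt += size + 30
    m = OrthologyMap(blocks, ChromSizes({"s": 2000}), ChromSizes({"t": 2000}))
    lifted = lift_interval(m, GenomicInterval("s", 0, src))
    starts = [s.start for s in lifted.raw_segments]
    assert starts == sorted(starts)
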