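"""Interval liftover through a UCSC chain orthology map.

The orthology map is an ordered set of equal-length, strand-aware alignment
blocks linking the source genome to the target genome.  Lifting an interval
reports the images of all covered sub-intervals, split at every alignment
gap — mirroring the behaviour of coordinate-liftover tools that report
contiguous liftover coordinates as separate features around indels.  A
separate merge/filter step (per-chromosome, orientation-blind) reassembles
the biologically contiguous regions.

Chain dialect: standard UCSC chain.  Target-strand ("qStrand") ``-`` blocks
have their chain coordinates expressed from the reverse-complement start and
are converted to forward-strand intervals on read, with the orientation
retained on the block.  The writer always emits normalized chains, and the
reader/writer round-trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .core import (
    ChromSizes,
    CoordinateError,
    FeatureSet,
    GenomicInterval,
    merge_intervals,
)


class ChainFormatError(ValueError):
    """Malformed chain file or invariant violation, naming the offending line."""


@dataclass(frozen=True)
class AlignmentBlock:
    """An ungapped alignment block: equal-length source and target intervals.

    ``orientation`` is ``+`` when source and target run in the same
    direction, ``-`` for an inverted block.  Both intervals are stored on
    the forward strand.  For a ``-`` block, source base ``src.start + i``
    maps to target base ``tgt.start + len - 1 - i``.
    """

    src: GenomicInterval
    tgt: GenomicInterval
    orientation: str = "+"

    def __post_init__(self) -> None:
        if len(self.src) != len(self.tgt):
            raise CoordinateError(
                f"alignment block length mismatch: {self.src} vs {self.tgt}"
            )
        if self.orientation not in ("+", "-"):
            raise CoordinateError(f"invalid orientation {self.orientation!r}")

    def map_offset(self, i: int) -> int:
        """Target forward-strand position of source base ``src.start + i``."""
        if self.orientation == "+":
            return self.tgt.start + i
        return self.tgt.start + len(self.src) - 1 - i


@dataclass
class OrthologyMap:
    """Ordered alignment blocks plus the chromosome sizes of both genomes."""

    blocks: list[AlignmentBlock]
    src_sizes: ChromSizes
    tgt_sizes: ChromSizes

    def __post_init__(self) -> None:
        self.blocks = sorted(
            self.blocks, key=lambda b: (b.src.chrom, b.src.start, b.src.end)
        )
        self._validate()
        self._by_src_chrom: dict[str, list[AlignmentBlock]] = {}
        for b in self.blocks:
            self._by_src_chrom.setdefault(b.src.chrom, []).append(b)

    def _validate(self) -> None:
        for b in self.blocks:
            self.src_sizes.validate(b.src)
            self.tgt_sizes.validate(b.tgt)
        prev: Optional[AlignmentBlock] = None
        for b in self.blocks:
            if prev is not None and prev.src.chrom == b.src.chrom and b.src.start < prev.src.end:
                raise ChainFormatError(
                    f"blocks overlap on source: {prev.src} and {b.src}"
                )
            prev = b
        by_tgt = sorted(self.blocks, key=lambda b: (b.tgt.chrom, b.tgt.start))
        prev = None
        for b in by_tgt:
            if prev is not None and prev.tgt.chrom == b.tgt.chrom and b.tgt.start < prev.tgt.end:
                raise ChainFormatError(
                    f"blocks overlap on target: {prev.tgt} and {b.tgt}"
                )
            prev = b

    def total_mapped_length(self) -> int:
        return sum(len(b.src) for b in self.blocks)

    def blocks_on(self, chrom: str) -> list[AlignmentBlock]:
        return self._by_src_chrom.get(chrom, [])


@dataclass
class LiftedFeature:
    """Result of lifting one source interval through an orthology map."""

    source: GenomicInterval
    raw_segments: list[GenomicInterval] = field(default_factory=list)
    merged_regions: list[GenomicInterval] = field(default_factory=list)
    status: str = "missing"  # "mapped" | "missing"


# ---------------------------------------------------------------------------
# chain I/O


def read_chain(path: str | Path) -> OrthologyMap:
    """Parse a UCSC chain file into an :class:`OrthologyMap`.

    Minus-strand target coordinates (expressed from the reverse-complement
    start in the file) are converted to forward-strand intervals with the
    block orientation recorded.
    """
    blocks: list[AlignmentBlock] = []
    src_sizes: dict[str, int] = {}
    tgt_sizes: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()

    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] != "chain" or len(parts) < 12:
            raise ChainFormatError(f"line {i}: expected chain header, got {line!r}")
        try:
            (t_name, t_size, t_strand, t_start, t_end,
             q_name, q_size, q_strand, q_start, q_end) = (
                parts[2], int(parts[3]), parts[4], int(parts[5]), int(parts[6]),
                parts[7], int(parts[8]), parts[9], int(parts[10]), int(parts[11]),
            )
        except ValueError as exc:
            raise ChainFormatError(f"line {i}: bad chain header: {exc}") from exc
        if t_strand != "+":
            raise ChainFormatError(f"line {i}: source strand must be '+'")
        if q_strand not in ("+", "-"):
            raise ChainFormatError(f"line {i}: bad target strand {q_strand!r}")
        src_sizes.setdefault(t_name, t_size)
        tgt_sizes.setdefault(q_name, q_size)

        t_pos, q_pos = t_start, q_start
        done = False
        while i < n and not done:
            dline = lines[i].strip()
            i += 1
            if not dline:
                continue
            fields = dline.split()
            try:
                nums = [int(x) for x in fields]
            except ValueError as exc:
                raise ChainFormatError(f"line {i}: bad alignment line: {exc}") from exc
            if len(nums) == 1:
                size, dt, dq = nums[0], 0, 0
                done = True
            elif len(nums) == 3:
                size, dt, dq = nums
            else:
                raise ChainFormatError(f"line {i}: expected 1 or 3 integers")
            src_iv = GenomicInterval(t_name, t_pos, t_pos + size)
            if q_strand == "+":
                tgt_iv = GenomicInterval(q_name, q_pos, q_pos + size)
            else:
                tgt_iv = GenomicInterval(q_name, q_size - (q_pos + size), q_size - q_pos)
            blocks.append(AlignmentBlock(src_iv, tgt_iv, q_strand))
            t_pos += size + dt
            q_pos += size + dq
        if not done:
            raise ChainFormatError(f"line {i}: chain truncated before final block")
        if t_pos - dt != t_end or q_pos - dq != q_end:
            raise ChainFormatError(
                f"line {i}: chain block sum does not reach declared end coordinates"
            )
    return OrthologyMap(blocks, ChromSizes(src_sizes), ChromSizes(tgt_sizes))


def _chain_runs(m: OrthologyMap) -> list[list[AlignmentBlock]]:
    """Group source-sorted blocks into maximal co-linear single-chain runs."""
    runs: list[list[AlignmentBlock]] = []
    for b in m.blocks:
        cur = runs[-1] if runs else None
        if cur:
            p = cur[-1]
            ok = (
                p.src.chrom == b.src.chrom
                and p.tgt.chrom == b.tgt.chrom
                and p.orientation == b.orientation
                and b.src.start >= p.src.end
            )
            if ok and b.orientation == "+":
                ok = b.tgt.start >= p.tgt.end
            elif ok:
                ok = b.tgt.end <= p.tgt.start
            if ok:
                cur.append(b)
                continue
        runs.append([b])
    return runs


def write_chain(m: OrthologyMap, path: str | Path) -> None:
    """Write the map as a UCSC chain file (one chain per co-linear run)."""
    with open(path, "w") as fh:
        for chain_id, run in enumerate(_chain_runs(m), start=1):
            first, last = run[0], run[-1]
            t_name = first.src.chrom
            t_size = m.src_sizes[t_name]
            q_name = first.tgt.chrom
            q_size = m.tgt_sizes[q_name]
            orient = first.orientation
            t_start, t_end = first.src.start, last.src.end
            if orient == "+":
                q_start, q_end = first.tgt.start, last.tgt.end
            else:
                q_start = q_size - first.tgt.end
                q_end = q_size - last.tgt.start
            score = sum(len(b.src) for b in run)
            fh.write(
                f"chain {score} {t_name} {t_size} + {t_start} {t_end} "
                f"{q_name} {q_size} {orient} {q_start} {q_end} {chain_id}\n"
            )
            for b, nxt in zip(run, run[1:]):
                dt = nxt.src.start - b.src.end
                if orient == "+":
                    dq = nxt.tgt.start - b.tgt.end
                else:
                    dq = b.tgt.start - nxt.tgt.end
                fh.write(f"{len(b.src)}\t{dt}\t{dq}\n")
            fh.write(f"{len(last.src)}\n\n")


# ---------------------------------------------------------------------------
# lifting


def lift_interval(m: OrthologyMap, query: GenomicInterval) -> LiftedFeature:
    """Map ``query`` through the chain, splitting at every alignment gap.

    Raw segments are reported in source order, each on the target forward
    strand with its orientation in ``strand``.  Positions falling in chain
    gaps are unmapped; a query with no mapped base has status ``missing``.
    """
    if query.chrom not in m.src_sizes:
        raise CoordinateError(f"query chromosome {query.chrom!r} absent from map")
    segments: list[GenomicInterval] = []
    for b in m.blocks_on(query.chrom):
        a = max(query.start, b.src.start)
        z = min(query.end, b.src.end)
        if a >= z:
            continue
        if b.orientation == "+":
            t0 = b.tgt.start + (a - b.src.start)
            segments.append(GenomicInterval(b.tgt.chrom, t0, t0 + (z - a), "+"))
        else:
            t0 = b.tgt.start + (b.src.end - z)
            segments.append(GenomicInterval(b.tgt.chrom, t0, t0 + (z - a), "-"))
    status = "mapped" if segments else "missing"
    return LiftedFeature(source=query, raw_segments=segments, status=status)


def merge_lifted(feature: LiftedFeature, merge_gap: int, min_size: int) -> LiftedFeature:
    """Merge raw segments per target chromosome and drop undersized regions.

    Segments separated by less than ``merge_gap`` bp on the same target
    chromosome are unioned regardless of orientation (internal inversions
    are allowed within one region); merged regions shorter than ``min_size``
    are excluded.  A feature whose regions are all removed becomes
    ``missing``.
    """
    if feature.status == "missing":
        return LiftedFeature(feature.source, list(feature.raw_segments), [], "missing")
    fs = FeatureSet(
        "lifted",
        [GenomicInterval(s.chrom, s.start, s.end) for s in feature.raw_segments],
    )
    merged = [iv for iv in merge_intervals(fs, merge_gap) if len(iv) >= min_size]
    status = "mapped" if merged else "missing"
    return LiftedFeature(feature.source, list(feature.raw_segments), merged, status)


def lift_and_merge(
    m: OrthologyMap, query: GenomicInterval, merge_gap: int, min_size: int
) -> LiftedFeature:
    return merge_lifted(lift_interval(m, query), merge_gap, min_size)


def invert_map(m: OrthologyMap) -> OrthologyMap:
    """Swap source and target genomes; orientation is preserved."""
    return OrthologyMap(
        [AlignmentBlock(b.tgt, b.src, b.orientation) for b in m.blocks],
        ChromSizes(m.tgt_sizes),
        ChromSizes(m.src_sizes),
    )


def map_position(m: OrthologyMap, chrom: str, pos: int) -> Optional[tuple[str, int]]:
    """Image of a single source base, or ``None`` when unmapped."""
    if chrom not in m.src_sizes:
        raise CoordinateError(f"chromosome {chrom!r} absent from map")
    for b in m.blocks_on(chrom):
        if b.src.start <= pos < b.src.end:
            return b.tgt.chrom, b.map_offset(pos - b.src.start)
    return None
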