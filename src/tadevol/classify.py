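"""Conservation taxonomy of boundaries and domains between two genomes.

Source-species high-confidence features are lifted through the orthology
map, merged/filtered, and classified:

* boundaries: *orthologous* when the lifted region lies less than
  ``dist_thresh`` (5 kb) from any high- or low-confidence boundary of the
  target species, *lineage_specific* otherwise, *missing* when nothing
  survives the liftover;
* domains: decision order (1) missing, (2) more than one merged region
  (different chromosomes or a same-chromosome gap at or above the merge
  gap) -> split_by_rearrangement, (3) reciprocal overlap of at least
  ``overlap_frac`` (0.90) with the best target domain -> orthologous,
  (4) a target-lineage-specific boundary strictly inside the region ->
  split_by_boundary, (5) residual -> truncated_expanded.

The non-orthologous decision order is a package design choice (a
multi-region lift is unambiguous evidence of rearrangement; truncated or
expanded domains are the residual that merely fails the reciprocal-overlap
criterion through indel-driven size asymmetry).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chain import OrthologyMap, lift_and_merge
from .core import (
    ConfigurationError,
    FeatureSet,
    ChromSizes,
    GenomicInterval,
    interval_overlap,
)

# liftover merge/filter parameters (bp): domains join across indel gaps
# below 20 kb and drop fragments under 5 kb; boundaries use 5 kb / 500 bp
DOMAIN_MERGE_GAP = 20_000
DOMAIN_MIN_SIZE = 5_000
BOUNDARY_MERGE_GAP = 5_000
BOUNDARY_MIN_SIZE = 500
DIST_THRESH = 5_000

DOMAIN_CATEGORIES = (
    "orthologous", "truncated_expanded", "split_by_boundary",
    "split_by_rearrangement", "missing",
)
BOUNDARY_STATUSES = ("orthologous", "lineage_specific", "missing")


@dataclass
class BoundaryStatus:
    name: str
    status: str  # orthologous | lineage_specific | missing
    distance: Optional[int] = None  # gap to nearest target boundary when mapped
    regions: Optional[list[GenomicInterval]] = None


@dataclass
class DomainCategory:
    name: str
    category: str
    shared_boundaries: bool = False
    frac_region: float = float("nan")  # overlap / len(lifted region)
    frac_target: float = float("nan")  # overlap / len(best target domain)
    n_regions: int = 0
    regions: Optional[list[GenomicInterval]] = None


@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal co-linear region between the two genomes."""

    src: GenomicInterval
    tgt: GenomicInterval
    orientation: str = "+"


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int
    klass: str = "interspecies"  # interspecies | polymorphic
    intra_tad: bool = False


# ---------------------------------------------------------------------------
# replicate consensus


def replicate_consensus(
    rep1: FeatureSet, rep2: FeatureSet, kind: str, domain_tol: int = 5_000
) -> tuple[FeatureSet, FeatureSet]:
    """Split replicate calls into high- and low-confidence sets.

    Boundaries are matched when they overlap by at least one base pair in
    both replicates; domains when their start and end coordinates agree
    within ``domain_tol`` bp.  Matched calls become high confidence (the
    union hull of the matched pair); calls seen in only one replicate are
    low confidence.
    """
    if kind not in ("boundary", "domain"):
        raise ConfigurationError(f"unknown call kind {kind!r}")
    high_iv, high_names = [], []
    low_iv, low_names = [], []
    used2: set[int] = set()
    n1 = rep1.feature_names()
    n2 = rep2.feature_names()
    for iv, nm in zip(rep1.intervals, n1):
        best_j, best_ov = None, -1
        for j, jv in enumerate(rep2.intervals):
            if j in used2 or jv.chrom != iv.chrom:
                continue
            if kind == "boundary":
                ov = interval_overlap(iv, jv)
                if ov > 0 and ov > best_ov:
                    best_j, best_ov = j, ov
            else:
                if abs(jv.start - iv.start) <= domain_tol and abs(jv.end - iv.end) <= domain_tol:
                    ov = interval_overlap(iv, jv)
                    if ov > best_ov:
                        best_j, best_ov = j, ov
        if best_j is not None:
            used2.add(best_j)
            jv = rep2.intervals[best_j]
            high_iv.append(GenomicInterval(iv.chrom, min(iv.start, jv.start),
                                           max(iv.end, jv.end)))
            high_names.append(nm)
        else:
            low_iv.append(iv)
            low_names.append(nm)
    for j, (jv, nm) in enumerate(zip(rep2.intervals, n2)):
        if j not in used2:
            low_iv.append(jv)
            low_names.append(nm)
    return (
        FeatureSet(f"{rep1.name}_high", high_iv, high_names).normalized(),
        FeatureSet(f"{rep1.name}_low", low_iv, low_names).normalized(),
    )


# ---------------------------------------------------------------------------
# boundary classification


class _NearestIndex:
    """Per-chromosome sorted interval index for nearest-gap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for c, pairs in tmp.items():
            pairs.sort()
            self.by_chrom[c] = (
                np.array([p[0] for p in pairs]),
                np.array([p[1] for p in pairs]),
            )

    def nearest_gap(self, iv: GenomicInterval) -> Optional[int]:
        if iv.chrom not in self.by_chrom:
            return None
        starts, ends = self.by_chrom[iv.chrom]
        i = int(np.searchsorted(starts, iv.end))
        best = None
        for j in range(max(0, i - 3), min(len(starts), i + 3)):
            gap = max(0, max(starts[j], iv.start) - min(ends[j], iv.end))
            if best is None or gap < best:
                best = int(gap)
        return best


def classify_boundaries(
    src_high: FeatureSet,
    omap: OrthologyMap,
    tgt_boundaries: FeatureSet,
    dist_thresh: int = DIST_THRESH,
    merge_gap: int = BOUNDARY_MERGE_GAP,
    min_size: int = BOUNDARY_MIN_SIZE,
) -> list[BoundaryStatus]:
    """Lift source high-confidence boundaries and classify each against the
    target species' high+low confidence boundary set."""
    index = _NearestIndex(tgt_boundaries.intervals)
    out: list[BoundaryStatus] = []
    for iv, name in zip(src_high.intervals, src_high.feature_names()):
        lifted = lift_and_merge(omap, iv, merge_gap, min_size)
        if lifted.status == "missing":
            out.append(BoundaryStatus(name, "missing"))
            continue
        dists = [index.nearest_gap(r) for r in lifted.merged_regions]
        dists = [d for d in dists if d is not None]
        dist = min(dists) if dists else None
        status = "orthologous" if dist is not None and dist < dist_thresh else "lineage_specific"
        out.append(BoundaryStatus(name, status, dist, lifted.merged_regions))
    return out


# ---------------------------------------------------------------------------
# domain classification


def _point_to_interval_gap(pos: int, iv: GenomicInterval) -> int:
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - iv.end + 1
    return 0


def classify_domain(
    name: str,
    lifted_regions: list[GenomicInterval],
    status: str,
    tgt_domains: FeatureSet,
    tgt_lineage_boundaries: FeatureSet,
    overlap_frac: float = 0.90,
    boundary_share_thresh: int = DIST_THRESH,
    tgt_share_boundaries: Optional[FeatureSet] = None,
) -> DomainCategory:
    """Classify one lifted+merged source domain (see module docstring for
    the decision order)."""
    if status == "missing" or not lifted_regions:
        return DomainCategory(name, "missing", n_regions=0)
    if len(lifted_regions) > 1:
        return DomainCategory(name, "split_by_rearrangement",
                              n_regions=len(lifted_regions), regions=lifted_regions)
    region = lifted_regions[0]
    # best target domain by overlap; ties to the smaller, then leftmost target
    best, best_key = None, None
    for t in tgt_domains.intervals:
        ov = interval_overlap(region, t)
        if ov <= 0:
            continue
        key = (-ov, len(t), t.chrom, t.start)
        if best_key is None or key < best_key:
            best, best_key = t, key
    if best is not None:
        ov = interval_overlap(region, best)
        f1 = ov / len(region)
        f2 = ov / len(best)
        if f1 >= overlap_frac and f2 >= overlap_frac:
            share = tgt_share_boundaries if tgt_share_boundaries is not None else None
            shared = False
            if share is not None:
                ds = [min((_point_to_interval_gap(pos, b) for b in share.intervals
                           if b.chrom == region.chrom), default=None)
                      for pos in (region.start, region.end)]
                shared = all(d is not None and d < boundary_share_thresh for d in ds)
            return DomainCategory(name, "orthologous", shared, f1, f2, 1, lifted_regions)
    else:
        f1 = f2 = 0.0
    if best is not None:
        ovb = interval_overlap(region, best)
        f1, f2 = ovb / len(region), ovb / len(best)
    # lineage-specific target boundary strictly inside the region?
    for b in tgt_lineage_boundaries.intervals:
        if interval_overlap(b, region) <= 0:
            continue
        d_start = _point_to_interval_gap(region.start, b)
        d_end = _point_to_interval_gap(region.end, b)
        if d_start >= boundary_share_thresh and d_end >= boundary_share_thresh:
            return DomainCategory(name, "split_by_boundary", False, f1, f2, 1, lifted_regions)
    return DomainCategory(name, "truncated_expanded", False, f1, f2, 1, lifted_regions)


def classify_domains(
    src_high: FeatureSet,
    omap: OrthologyMap,
    tgt_domains: FeatureSet,
    tgt_lineage_boundaries: FeatureSet,
    overlap_frac: float = 0.90,
    merge_gap: int = DOMAIN_MERGE_GAP,
    min_size: int = DOMAIN_MIN_SIZE,
    boundary_share_thresh: int = DIST_THRESH,
    tgt_share_boundaries: Optional[FeatureSet] = None,
) -> list[DomainCategory]:
    out = []
    for iv, name in zip(src_high.intervals, src_high.feature_names()):
        lifted = lift_and_merge(omap, iv, merge_gap, min_size)
        out.append(classify_domain(
            name, lifted.merged_regions, lifted.status, tgt_domains,
            tgt_lineage_boundaries, overlap_frac, boundary_share_thresh,
            tgt_share_boundaries,
        ))
    return out


# ---------------------------------------------------------------------------
# co-linearity


def colinearity(features: FeatureSet, blocks: Sequence[SyntenyBlock]) -> list[bool]:
    """Per-feature flag: entirely contained in a single synteny block."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.src.chrom, []).append((b.src.start, b.src.end))
    for v in by_chrom.values():
        v.sort()
    flags = []
    for iv in features.intervals:
        ok = False
        for s, e in by_chrom.get(iv.chrom, ()):
            if s <= iv.start and iv.end <= e:
                ok = True
                break
            if s > iv.start:
                break
        flags.append(ok)
    return flags


def shuffle_expected_colinear(
    features: FeatureSet,
    blocks: Sequence[SyntenyBlock],
    chrom_sizes: ChromSizes,
    n_shuffles: int = 100,
    seed: int = 0,
) -> tuple[float, list[int]]:
    """Expected number of co-linear features under uniform per-chromosome
    placement (length preserved, overlaps among shuffled features allowed)."""
    if n_shuffles < 1:
        raise ConfigurationError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    for iv in features.intervals:
        if len(iv) > chrom_sizes[iv.chrom]:
            raise ConfigurationError(f"feature {iv} longer than its chromosome")
    counts = []
    for _ in range(n_shuffles):
        shuffled = []
        for iv in features.intervals:
            hi = chrom_sizes[iv.chrom] - len(iv)
            s = int(rng.integers(0, hi + 1))
            shuffled.append(GenomicInterval(iv.chrom, s, s + len(iv)))
        counts.append(sum(colinearity(FeatureSet("shuf", shuffled), blocks)))
    return float(np.mean(counts)), counts


# ---------------------------------------------------------------------------
# breakpoints


def derive_breakpoints(
    blocks: Sequence[SyntenyBlock],
    boundaries: FeatureSet,
    domains: FeatureSet,
    bt_dist: int = DIST_THRESH,
) -> list[Breakpoint]:
    """One breakpoint per internal junction between consecutive synteny
    blocks on the source genome (chromosome ends excluded).  ``intra_tad``
    marks junctions inside a high-confidence domain and more than
    ``bt_dist`` from every boundary."""
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.src.chrom, []).append(b)
    bindex = _NearestIndex(boundaries.intervals)
    out = []
    for chrom, bl in sorted(by_chrom.items()):
        bl.sort(key=lambda b: b.src.start)
        for left, right in zip(bl, bl[1:]):
            pos = left.src.end
            point = GenomicInterval(chrom, pos, pos + 1)
            inside = any(d.chrom == chrom and d.start <= pos < d.end
                         for d in domains.intervals)
            gap = bindex.nearest_gap(point)
            intra = bool(inside and (gap is None or gap > bt_dist))
            out.append(Breakpoint(chrom, pos, "interspecies", intra))
    return out


# ---------------------------------------------------------------------------
# Table-1-style report


def round_pct(numer: int, denom: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if denom == 0:
        return 0
    x = 100.0 * numer / denom
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_table1(
    boundary_counts: dict[str, int],
    domain_counts: dict[str, int],
    n_shared_boundary_orthologous: Optional[int] = None,
) -> dict:
    """Assemble the conservation summary (counts and printed percentages).

    ``boundary_counts`` maps boundary statuses to counts, ``domain_counts``
    maps domain categories to counts.  "Unique lifted-over" is total minus
    missing; subcategory percentages are taken out of unique lifted-over,
    liftover success out of the total, all rounded half away from zero.
    """
    b_total = sum(boundary_counts.values())
    b_missing = boundary_counts.get("missing", 0)
    b_unique = b_total - b_missing
    b_orth = boundary_counts.get("orthologous", 0)
    b_non = boundary_counts.get("lineage_specific", 0)
    if b_orth + b_non != b_unique:
        raise ConfigurationError("boundary statuses do not partition the input")

    d_total = sum(domain_counts.values())
    d_missing = domain_counts.get("missing", 0)
    d_unique = d_total - d_missing
    d_orth = domain_counts.get("orthologous", 0)
    d_trunc = domain_counts.get("truncated_expanded", 0)
    d_split_b = domain_counts.get("split_by_boundary", 0)
    d_split_r = domain_counts.get("split_by_rearrangement", 0)
    d_non = d_trunc + d_split_b + d_split_r
    if d_orth + d_non != d_unique:
        raise ConfigurationError("domain categories do not partition the input")

    report = {
        "boundaries": {
            "total": b_total,
            "unique_lifted_over": {"n": b_unique, "pct": round_pct(b_unique, b_total)},
            "orthologous": {"n": b_orth, "pct": round_pct(b_orth, b_unique)},
            "non_orthologous": {"n": b_non, "pct": round_pct(b_non, b_unique)},
            "missing": {"n": b_missing},
        },
        "domains": {
            "total": d_total,
            "unique_lifted_over": {"n": d_unique, "pct": round_pct(d_unique, d_total)},
            "orthologous": {"n": d_orth, "pct": round_pct(d_orth, d_unique)},
            "non_orthologous": {"n": d_non, "pct": round_pct(d_non, d_unique)},
            "truncated_expanded": {"n": d_trunc, "pct": round_pct(d_trunc, d_unique)},
            "split_by_boundary": {"n": d_split_b, "pct": round_pct(d_split_b, d_unique)},
            "split_by_rearrangement": {"n": d_split_r, "pct": round_pct(d_split_r, d_unique)},
            "missing": {"n": d_missing},
        },
    }
    if n_shared_boundary_orthologous is not None:
        report["domains"]["orthologous_with_shared_boundaries"] = {
            "n": n_shared_boundary_orthologous,
            "pct": round_pct(n_shared_boundary_orthologous, d_orth),
        }
    return report


def count_statuses(statuses: Sequence[BoundaryStatus]) -> dict[str, int]:
    c = Counter(s.status for s in statuses)
    return {k: c.get(k, 0) for k in BOUNDARY_STATUSES}


def count_categories(cats: Sequence[DomainCategory]) -> dict[str, int]:
    c = Counter(s.category for s in cats)
    return {k: c.get(k, 0) for k in DOMAIN_CATEGORIES}
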