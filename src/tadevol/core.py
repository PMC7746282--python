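"""Shared coordinate conventions, interval types and interval algebra.

All coordinates are 0-based half-open (BED convention).  Distances are gaps
between half-open intervals: overlapping or abutting intervals are at
distance 0, and distances across different chromosomes are *incomparable*
(returned as ``None``).  Every "< X kb" threshold downstream is a strict
inequality on these gap distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd


class CoordinateError(ValueError):
    """An interval violates the coordinate conventions."""


class ConfigurationError(ValueError):
    """Inconsistent inputs or infeasible parameters."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


class ChromSizes(dict):
    """Mapping chromosome label -> length in bp."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(sizes)
        for name, length in self.items():
            if length <= 0:
                raise CoordinateError(f"chromosome {name} has non-positive length")

    def validate(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise CoordinateError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self[interval.chrom]:
            raise CoordinateError(
                f"{interval} extends past end of {interval.chrom} "
                f"({self[interval.chrom]} bp)"
            )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(zip(df["chrom"].astype(str), df["length"].astype(int)))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.items():
                fh.write(f"{name}\t{length}\n")


@dataclass
class FeatureSet:
    """A named, ordered collection of intervals with optional attributes.

    ``names`` aligns one-to-one with ``intervals``; ``attrs`` is an optional
    sidecar DataFrame indexed like ``names``.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    names: Optional[list[str]] = None
    attrs: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.names is not None and len(self.names) != len(self.intervals):
            raise ConfigurationError("names do not align with intervals")
        if self.attrs is not None and len(self.attrs) != len(self.intervals):
            raise ConfigurationError("attribute records do not align with intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def feature_names(self) -> list[str]:
        if self.names is not None:
            return list(self.names)
        return [f"{self.name}_{i}" for i in range(len(self.intervals))]

    def normalized(self) -> "FeatureSet":
        """Sorted by (chrom, start, end); attributes follow their intervals."""
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (
                self.intervals[i].chrom,
                self.intervals[i].start,
                self.intervals[i].end,
            ),
        )
        names = [self.names[i] for i in order] if self.names is not None else None
        attrs = self.attrs.iloc[order].reset_index(drop=True) if self.attrs is not None else None
        return FeatureSet(self.name, [self.intervals[i] for i in order], names, attrs)

    # -- BED I/O --------------------------------------------------------

    @classmethod
    def read_bed(cls, path: str | Path, name: Optional[str] = None) -> "FeatureSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        intervals: list[GenomicInterval] = []
        names: Optional[list[str]] = [] if df.shape[1] >= 4 else None
        for row in df.itertuples(index=False):
            strand = row[5] if len(row) >= 6 and row[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
            if names is not None:
                names.append(str(row[3]))
        return cls(name or path.stem, intervals, names)

    def write_bed(self, path: str | Path) -> None:
        names = self.feature_names()
        with open(path, "w") as fh:
            for iv, nm in zip(self.intervals, names):
                if iv.strand == ".":
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{nm}\n")
                else:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{nm}\t0\t{iv.strand}\n")


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Gap in bp between two intervals.

    Overlapping or abutting intervals are at distance 0.  Returns ``None``
    (incomparable) when the intervals lie on different chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def merge_intervals(features: FeatureSet, max_gap: int = 0) -> FeatureSet:
    """Union same-chromosome intervals whose gap is strictly below ``max_gap``.

    Overlapping intervals (negative signed gap) always merge; abutting ones
    merge only when ``max_gap > 0``.  The result is normalized and the
    operation is idempotent.
    """
    if max_gap < 0:
        raise ConfigurationError("max_gap must be >= 0")
    norm = features.normalized()
    merged: list[GenomicInterval] = []
    for iv in norm.intervals:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end < max(max_gap, 0):
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return FeatureSet(features.name, merged)


def midpoint(iv: GenomicInterval) -> int:
    return (iv.start + iv.end) // 2


def nearest_distance(
    query: GenomicInterval, targets: Sequence[GenomicInterval]
) -> Optional[int]:
    """Smallest gap from ``query`` to any target on the same chromosome."""
    best: Optional[int] = None
    for t in targets:
        d = interval_distance(query, t)
        if d is not None and (best is None or d < best):
            best = d
            if best == 0:
                break
    return best
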