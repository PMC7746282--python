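"""Diamond insulation scoring and insulation-based group comparisons.

The score implemented here is a simplified diamond insulation statistic:
for bin *i* and window *w* (in bins), the mean contact frequency between
the *w* bins upstream and the *w* bins downstream of *i*; scores are
averaged over the requested window sizes and z-scored per chromosome.
Lower scores mean stronger insulation (the sign convention of TAD
separation scores).  Real insulation tracks read from bedGraph are the
primary input path for the comparative analyses; the matrix-based score
exists so that simulated or toy contact maps can be scored directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, FeatureSet, GenomicInterval
from .stats import rank_sum_test


class MatrixFormatError(ValueError):
    """Contact matrix violates its invariants."""


@dataclass
class ContactMatrix:
    """Dense symmetric contact matrix for one chromosome."""

    matrix: np.ndarray
    bin_size: int = 5_000
    chrom: str = "chr"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise MatrixFormatError("contact matrix must be square")
        if (m < 0).any():
            raise MatrixFormatError("contact matrix must be non-negative")
        scale = max(np.abs(m).max(), 1.0)
        if np.abs(m - m.T).max() > 1e-6 * scale:
            raise MatrixFormatError("contact matrix is asymmetric beyond tolerance")
        self.matrix = m

    @classmethod
    def read_tsv(cls, path: str | Path, bin_size: int = 5_000, chrom: str = "chr"):
        m = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        return cls(m, bin_size, chrom)


@dataclass
class InsulationTrack:
    """Per-bin insulation scores; undefined margins are NaN."""

    score: np.ndarray          # z-scored
    raw: np.ndarray            # window-averaged, before z-scoring
    bin_size: int = 5_000
    chrom: str = "chr"

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(len(self.score)) * self.bin_size
        return pd.DataFrame({"chrom": self.chrom, "start": starts,
                             "end": starts + self.bin_size, "score": self.score})


def diamond_insulation(
    cm: ContactMatrix, window_sizes: Sequence[int] = (2,)
) -> InsulationTrack:
    """Simplified diamond insulation score (see module docstring).

    Bins closer than the largest window to either matrix edge are
    undefined.  A constant matrix yields all-equal raw scores (z-score 0).
    """
    m = cm.matrix
    n = m.shape[0]
    wmax = max(window_sizes)
    if wmax > n // 2:
        raise ConfigurationError("window larger than half the matrix")
    per_window = []
    for w in window_sizes:
        s = np.full(n, np.nan)
        for i in range(w, n - w + 1):  # bin i needs w bins on each side
            s[i] = m[i - w : i, i : i + w].mean()
        per_window.append(s)
    stack = np.vstack(per_window)
    counts = (~np.isnan(stack)).sum(axis=0)
    raw = np.where(counts > 0, np.nansum(stack, axis=0) / np.maximum(counts, 1),
                   np.nan)
    raw[:wmax] = np.nan
    if wmax > 1:
        raw[n - wmax + 1 :] = np.nan
    defined = ~np.isnan(raw)
    z = np.full(n, np.nan)
    if defined.sum() >= 2 and np.nanstd(raw) > 0:
        z[defined] = (raw[defined] - np.nanmean(raw)) / np.nanstd(raw)
    elif defined.sum() >= 1:
        z[defined] = 0.0
    return InsulationTrack(z, raw, cm.bin_size, cm.chrom)


def spearman_replicates(track_1: Sequence[float], track_2: Sequence[float]) -> float:
    """Spearman rank correlation between replicate score tracks; undefined
    bins (NaN) are dropped pairwise."""
    from scipy.stats import spearmanr

    a = np.asarray(track_1, dtype=float)
    b = np.asarray(track_2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must share the same bin grid")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared defined bins")
    rho = spearmanr(a[ok], b[ok]).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# group comparisons on a genome-wide bedGraph track


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "score"])


def scores_at_features(
    track: pd.DataFrame, features: Sequence[GenomicInterval] | Sequence[tuple[str, int]]
) -> np.ndarray:
    """Score of the bin containing each feature's midpoint (points allowed)."""
    out = []
    by_chrom = {c: g.sort_values("start").reset_index(drop=True)
                for c, g in track.groupby("chrom")}
    for f in features:
        if isinstance(f, GenomicInterval):
            chrom, pos = f.chrom, (f.start + f.end) // 2
        else:
            chrom, pos = f
        g = by_chrom.get(chrom)
        if g is None:
            continue
        i = int(np.searchsorted(g["start"].to_numpy(), pos, side="right")) - 1
        if 0 <= i < len(g) and g.loc[i, "start"] <= pos < g.loc[i, "end"]:
            out.append(float(g.loc[i, "score"]))
    return np.array(out)


def insulation_group_comparison(
    track: pd.DataFrame, groups: dict[str, Sequence]
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum comparisons of bin scores across feature
    groups (boundaries, intra-TAD breakpoints, all intra-TAD bins, ...).

    Each feature maps to the 5 kb bin containing its midpoint; lower score
    means more insulation.
    """
    scored = {}
    for name, feats in groups.items():
        s = (np.asarray(feats, dtype=float)
             if len(feats) and np.isscalar(feats[0]) else scores_at_features(track, feats))
        if len(s) == 0:
            raise ValueError(f"group {name!r} has no scored features")
        scored[name] = s
    names = list(scored)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = rank_sum_test(scored[a], scored[b])
            rows.append({
                "group_1": a, "group_2": b,
                "n_1": len(scored[a]), "n_2": len(scored[b]),
                "median_1": float(np.median(scored[a])),
                "median_2": float(np.median(scored[b])),
                "p_value": res.p_value,
                "more_insulated": a if res.direction == "less"
                                  else (b if res.direction == "greater" else "neither"),
            })
    return pd.DataFrame(rows)


def intra_tad_bins(
    track: pd.DataFrame, domains: FeatureSet, boundaries: FeatureSet,
    bt_dist: int = 5_000,
) -> list[tuple[str, int]]:
    """Midpoints of all bins lying inside a domain and more than ``bt_dist``
    from every boundary."""
    out = []
    bnd_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in boundaries.intervals:
        bnd_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    dom_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in domains.intervals:
        dom_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, g in track.groupby("chrom"):
        doms = dom_by_chrom.get(chrom, [])
        bnds = bnd_by_chrom.get(chrom, [])
        bs = np.array([b[0] for b in bnds]) if bnds else np.empty(0)
        be = np.array([b[1] for b in bnds]) if bnds else np.empty(0)
        for start, end in zip(g["start"], g["end"]):
            mid = (start + end) // 2
            if not any(s <= mid < e for s, e in doms):
                continue
            if len(bs):
                gap = np.maximum(0, np.maximum(bs, mid) - np.minimum(be, mid + 1))
                if gap.min() <= bt_dist:
                    continue
            out.append((chrom, mid))
    return out
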