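"""Chromatin-state assignment and enrichment / association statistics.

Exact tests are delegated to scipy.stats behind a stable interface; the
test suite cross-checks them against brute-force enumeration.  Permutation
and shuffle machinery relocates features uniformly at random on their own
chromosome, preserving lengths, with no masking and no overlap constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss

from .core import (
    ChromSizes,
    ConfigurationError,
    FeatureSet,
    GenomicInterval,
    interval_overlap,
)

CHROMATIN_STATES = ("BLACK", "BLUE", "GREEN", "RED", "YELLOW")


@dataclass
class ProximityTestResult:
    observed: int
    expected: float
    population: int
    draws: int
    p_value: float
    test: str

    def observed_pct(self) -> float:
        return round(100.0 * self.observed / self.draws, 1)

    def expected_pct(self) -> float:
        return round(100.0 * self.expected / self.draws, 1)


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    direction: str = ""
    extra: Optional[dict] = None


# ---------------------------------------------------------------------------
# chromatin-state assignment


def assign_chromatin_state(
    gene: GenomicInterval, segments: FeatureSet
) -> str:
    """State covering the largest share of the gene body (introns included);
    ``unassigned`` when no annotated segment overlaps the gene."""
    cover: dict[str, int] = {}
    states = segments.attrs["state"] if segments.attrs is not None else None
    if states is None:
        raise ConfigurationError("segments need a 'state' attribute column")
    for iv, st in zip(segments.intervals, states):
        ov = interval_overlap(gene, iv)
        if ov > 0:
            cover[st] = cover.get(st, 0) + ov
    if not cover:
        return "unassigned"
    return max(sorted(cover), key=lambda s: cover[s])


def assign_states_to_genes(genes: pd.DataFrame, segments: FeatureSet) -> pd.Series:
    """Vectorised per-gene state assignment over a gene table."""
    out = []
    states = segments.attrs["state"].to_numpy()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in genes["chrom"].unique():
        idx = [i for i, iv in enumerate(segments.intervals) if iv.chrom == c]
        by_chrom[c] = (
            np.array([segments.intervals[i].start for i in idx]),
            np.array([segments.intervals[i].end for i in idx]),
            states[idx],
        )
    for row in genes.itertuples(index=False):
        starts, ends, seg_states = by_chrom.get(row.chrom, (None, None, None))
        if starts is None or len(starts) == 0:
            out.append("unassigned")
            continue
        cov = np.minimum(ends, row.end) - np.maximum(starts, row.start)
        cov = np.where(cov > 0, cov, 0)
        if cov.sum() == 0:
            out.append("unassigned")
            continue
        totals: dict[str, int] = {}
        for c_, s_ in zip(cov, seg_states):
            if c_ > 0:
                totals[s_] = totals.get(s_, 0) + int(c_)
        out.append(max(sorted(totals), key=lambda s: totals[s]))
    return pd.Series(out, index=genes.index, name="state")


# ---------------------------------------------------------------------------
# exact tests


def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The odds ratio is the sample ratio (a*d)/(b*c), with 0/inf conventions
    for empty margins; a degenerate all-zero table gives p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    a, b, c, d = t.ravel()
    if t.sum() == 0:
        return TestResult("fisher_exact", float("nan"), 1.0)
    orat, p = ss.fisher_exact(t.astype(int), alternative="two-sided")
    return TestResult("fisher_exact", float(orat), float(p))


def hypergeom_upper(N: int, K: int, n: int, x: int) -> tuple[float, float]:
    """Exact upper tail P(X >= x) of Hypergeometric(N, K, n) and the
    expectation n*K/N."""
    if not (0 <= K <= N and 0 <= x <= n <= N):
        raise ValueError(f"infeasible hypergeometric arguments N={N} K={K} n={n} x={x}")
    if N == 0:  # empty population: X is identically 0
        return 1.0, 0.0
    p = float(ss.hypergeom.sf(x - 1, N, K, n))
    return min(p, 1.0), n * K / N


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with group medians."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = ss.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    direction = "less" if np.median(x) < np.median(y) else "greater"
    if np.median(x) == np.median(y):
        direction = "equal"
    return TestResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue),
                      direction,
                      {"median_x": float(np.median(x)), "median_y": float(np.median(y)),
                       "n_x": len(x), "n_y": len(y)})


def signed_rank_test(diffs: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences; zero
    differences are dropped.  All-zero input is reported as no signal
    (p = 1)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, "equal")
    res = ss.wilcoxon(d, alternative="two-sided", zero_method="wilcox")
    direction = "greater" if d.sum() > 0 else "less"
    return TestResult("wilcoxon_signed_rank", float(res.statistic),
                      float(res.pvalue), direction, {"n_nonzero": len(d)})


# ---------------------------------------------------------------------------
# proximity enrichment


def _genes_near_features(
    genes: pd.DataFrame, features: Sequence[GenomicInterval], window: int
) -> np.ndarray:
    """Boolean mask: gene interval within ``window`` (strict gap) of any
    feature; overlap counts as distance 0."""
    near = np.zeros(len(genes), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in features:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs])
        ends = np.array([p[1] for p in pairs])
        sel = (genes["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        gs = genes.loc[sel, "start"].to_numpy()
        ge = genes.loc[sel, "end"].to_numpy()
        # gap(g, f) < window  <=>  f.end > g.start - window + ... using
        # half-open arithmetic: gap = max(0, max(starts) - min(ends))
        hit = np.zeros(sel.sum(), dtype=bool)
        for s, e in zip(starts, ends):
            gap = np.maximum(0, np.maximum(gs, s) - np.minimum(ge, e))
            hit |= gap < window
        near[sel] = hit
    return near


def de_proximity_enrichment(
    genes: pd.DataFrame,
    features: FeatureSet,
    window: int = 10_000,
    exclude_features_overlapping: Optional[FeatureSet] = None,
) -> ProximityTestResult:
    """Hypergeometric test: are differentially-expressed genes enriched
    within ``window`` bp of the given features?

    Population = all genes; successes = genes near a retained feature;
    draws = DE genes; observed = DE genes near a feature.  Features
    overlapping any interval of ``exclude_features_overlapping`` are
    dropped before testing (used to exclude breakpoints that coincide with
    TAD boundaries).
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    feats = list(features.intervals)
    if exclude_features_overlapping is not None:
        keep = []
        for f in feats:
            if all(interval_overlap(f, b) == 0
                   for b in exclude_features_overlapping.intervals):
                keep.append(f)
        feats = keep
    near = _genes_near_features(genes, feats, window)
    de = genes["de_flag"].to_numpy().astype(bool)
    N = len(genes)
    K = int(near.sum())
    n = int(de.sum())
    x = int((near & de).sum())
    p, expected = hypergeom_upper(N, K, n, x)
    return ProximityTestResult(x, expected, N, n, p, "de_proximity_hypergeometric")


# ---------------------------------------------------------------------------
# permutation proximity


def _min_gaps_to_refs(queries: list[GenomicInterval],
                      ref_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]):
    gaps = []
    for q in queries:
        if q.chrom not in ref_by_chrom:
            gaps.append(np.inf)
            continue
        starts, ends = ref_by_chrom[q.chrom]
        g = np.maximum(0, np.maximum(starts, q.start) - np.minimum(ends, q.end))
        gaps.append(float(g.min()) if len(g) else np.inf)
    return np.array(gaps)


def permutation_proximity(
    query_features: FeatureSet,
    reference_features: FeatureSet,
    chrom_sizes: ChromSizes,
    statistic: str = "overlap_count",
    n_perm: int = 1_000,
    seed: int = 0,
) -> TestResult:
    """Permutation test of spatial association between two feature sets.

    Each permutation relocates every query feature uniformly at random on
    its own chromosome (length preserved).  ``overlap_count`` counts query
    features overlapping any reference (extreme = as large or larger);
    ``median_distance`` is the median gap to the nearest reference (extreme
    = as small or smaller).  p uses the add-one correction
    (1 + #extreme) / (1 + n_perm).
    """
    if statistic not in ("overlap_count", "median_distance"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ref_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in reference_features.intervals:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for c, pairs in tmp.items():
        pairs.sort()
        ref_by_chrom[c] = (np.array([p[0] for p in pairs]),
                           np.array([p[1] for p in pairs]))

    def stat(queries: list[GenomicInterval]) -> float:
        gaps = _min_gaps_to_refs(queries, ref_by_chrom)
        if statistic == "overlap_count":
            return float((gaps == 0).sum())
        finite = gaps[np.isfinite(gaps)]
        return float(np.median(finite)) if len(finite) else np.inf

    observed = stat(list(query_features.intervals))
    null = np.empty(n_perm)
    qlens = [(iv.chrom, len(iv)) for iv in query_features.intervals]
    for i in range(n_perm):
        shuffled = []
        for chrom, L in qlens:
            s = int(rng.integers(0, chrom_sizes[chrom] - L + 1))
            shuffled.append(GenomicInterval(chrom, s, s + L))
        null[i] = stat(shuffled)
    if statistic == "overlap_count":
        extreme = int((null >= observed).sum())
        direction = "enriched" if observed > np.median(null) else "not_enriched"
    else:
        extreme = int((null <= observed).sum())
        direction = "closer" if observed < np.median(null) else "not_closer"
    p = (1 + extreme) / (1 + n_perm)
    return TestResult(f"permutation_{statistic}", observed, p, direction,
                      {"null_mean": float(null.mean()), "n_perm": n_perm,
                       "null": null.tolist()})


# ---------------------------------------------------------------------------
# per-state comparisons


def state_enrichment(
    genes_a: pd.DataFrame, genes_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-chromatin-state 2x2 Fisher tests comparing two gene groups.

    Genes with unassigned state must be dropped by the caller.  Direction
    is relative to group A ("enriched" = over-represented in A).
    """
    rows = []
    ca = genes_a["state"].value_counts()
    cb = genes_b["state"].value_counts()
    na, nb = len(genes_a), len(genes_b)
    for st in CHROMATIN_STATES:
        a = int(ca.get(st, 0))
        c = int(cb.get(st, 0))
        res = fisher_exact_2x2([[a, na - a], [c, nb - c]])
        frac_a = a / na if na else 0.0
        frac_b = c / nb if nb else 0.0
        rows.append({
            "state": st, "n_a": a, "n_b": c,
            "frac_a": frac_a, "frac_b": frac_b,
            "odds_ratio": res.statistic, "p_value": res.p_value,
            "direction": "enriched" if frac_a > frac_b else
                         ("depleted" if frac_a < frac_b else "equal"),
        })
    return pd.DataFrame(rows)


def state_at_point(segments: FeatureSet, chrom: str, pos: int) -> str:
    states = segments.attrs["state"]
    for iv, st in zip(segments.intervals, states):
        if iv.contains_point(chrom, pos):
            return st
    return "unassigned"


def breakpoint_state_comparison(
    interspecies: Sequence[tuple[str, int]],
    polymorphic: Sequence[tuple[str, int]],
    segments: FeatureSet,
) -> pd.DataFrame:
    """Per-state Fisher comparison of interspecies (fixed) versus
    polymorphic breakpoint chromatin-state spectra.

    Each breakpoint takes the state of the segment containing its junction
    coordinate (point lookup); unannotated breakpoints are dropped.
    """
    s_inter = [state_at_point(segments, c, p) for c, p in interspecies]
    s_poly = [state_at_point(segments, c, p) for c, p in polymorphic]
    s_inter = [s for s in s_inter if s != "unassigned"]
    s_poly = [s for s in s_poly if s != "unassigned"]
    rows = []
    ni, np_ = len(s_inter), len(s_poly)
    for st in CHROMATIN_STATES:
        a = sum(1 for s in s_inter if s == st)
        c = sum(1 for s in s_poly if s == st)
        res = fisher_exact_2x2([[a, ni - a], [c, np_ - c]])
        fa = a / ni if ni else 0.0
        fb = c / np_ if np_ else 0.0
        rows.append({
            "state": st, "n_interspecies": a, "n_polymorphic": c,
            "frac_interspecies": fa, "frac_polymorphic": fb,
            "odds_ratio": res.statistic, "p_value": res.p_value,
            "direction": "enriched" if fa > fb else ("depleted" if fa < fb else "equal"),
        })
    return pd.DataFrame(rows)


def expression_comparison(
    genes_a: pd.DataFrame, genes_b: pd.DataFrame
) -> dict[str, TestResult]:
    """Expression-level and DE-direction comparisons between two gene groups.

    Returns the two-sided rank-sum test on expression plus the Fisher
    variant on up- versus down-regulated counts among DE genes.
    """
    if len(genes_a) == 0 or len(genes_b) == 0:
        raise ValueError("both gene groups must be non-empty")
    out = {
        "expression_rank_sum": rank_sum_test(
            genes_a["expression"], genes_b["expression"]),
    }
    de_a = genes_a[genes_a["de_flag"].astype(bool)]
    de_b = genes_b[genes_b["de_flag"].astype(bool)]
    up_a = int((de_a["direction"] == "up").sum())
    up_b = int((de_b["direction"] == "up").sum())
    table = [[up_a, len(de_a) - up_a], [up_b, len(de_b) - up_b]]
    fr = fisher_exact_2x2(table)
    fr.extra = {"up_frac_a": up_a / len(de_a) if len(de_a) else float("nan"),
                "up_frac_b": up_b / len(de_b) if len(de_b) else float("nan")}
    out["up_fraction_fisher"] = fr
    return out


def gene_domain_membership(
    genes: pd.DataFrame, domains: FeatureSet
) -> pd.Series:
    """Index of the domain covering the largest part of each gene (-1 when
    no domain overlaps); ties go to the leftmost domain."""
    out = np.full(len(genes), -1, dtype=int)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(domains.intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    for c in by_chrom:
        by_chrom[c].sort()
    for gi, row in enumerate(genes.itertuples(index=False)):
        best_ov, best_i = 0, -1
        for s, e, i in by_chrom.get(row.chrom, ()):
            if s >= row.end:
                break
            ov = min(e, row.end) - max(s, row.start)
            if ov > best_ov:
                best_ov, best_i = ov, i
        out[gi] = best_i
    return pd.Series(out, index=genes.index, name="domain_index")
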