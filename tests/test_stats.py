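"""Enrichment statistics versus independent enumeration/summation oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tadevol.core import ChromSizes, FeatureSet, GenomicInterval
from tadevol.stats import (
    assign_chromatin_state,
    breakpoint_state_comparison,
    de_proximity_enrichment,
    expression_comparison,
    fisher_exact_2x2,
    gene_domain_membership,
    hypergeom_upper,
    permutation_proximity,
    rank_sum_test,
    signed_rank_test,
    state_enrichment,
)


# ---------------------------------------------------------------------------
# oracles


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of the hypergeometric support."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-12))


def hypergeom_oracle(N, K, n, x):
    """Upper-tail P(X >= x) by direct summation."""
    return sum(math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
               for k in range(x, min(K, n) + 1))


def rank_sum_oracle(x, y):
    """Two-sided rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:nx].sum()
    total = 0
    extreme = 0
    mu = ranks.sum() * nx / len(pooled)
    for comb in itertools.combinations(range(len(pooled)), nx):
        s = ranks[list(comb)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-9:
            extreme += 1
    return extreme / total


def signed_rank_oracle(diffs):
    """Two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_plus = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    total = extreme = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mu) >= abs(w_plus - mu) - 1e-9:
            extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------
# exact tests


class TestFisher:
    def test_no_association(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_perfect_association_enumeration(self):
        res = fisher_exact_2x2([[10, 0], [0, 10]])
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert res.p_value == pytest.approx(fisher_oracle(10, 0, 0, 10), rel=1e-9)

    def test_degenerate_empty_table(self):
        assert fisher_exact_2x2([[0, 0], [0, 0]]).p_value == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 15, size=4)
            res = fisher_exact_2x2([[a, b], [c, d]])
            assert res.p_value == pytest.approx(
                fisher_oracle(int(a), int(b), int(c), int(d)), rel=1e-8, abs=1e-12)


class TestHypergeom:
    def test_zero_observed_is_one(self):
        p, _ = hypergeom_upper(100, 20, 10, 0)
        assert p == 1.0

    def test_saturated_population(self):
        p, _ = hypergeom_upper(50, 50, 10, 7)
        assert p == pytest.approx(1.0)

    def test_published_shape_example(self):
        # the observed/expected arithmetic of a DE-proximity test:
        # population 1000, 176 near-feature genes, 100 DE draws, 24 hits
        p, expected = hypergeom_upper(1000, 176, 100, 24)
        assert expected == pytest.approx(17.6)
        assert p == pytest.approx(hypergeom_oracle(1000, 176, 100, 24), rel=1e-9)

    def test_infeasible_arguments(self):
        with pytest.raises(ValueError):
            hypergeom_upper(10, 20, 5, 1)
        with pytest.raises(ValueError):
            hypergeom_upper(10, 5, 11, 1)


class TestRankTests:
    def test_identical_groups_p_one(self):
        res = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)
        assert res.direction == "equal"

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 500)
        y = rng.normal(0.5, 1, 500)
        assert rank_sum_test(x, y).p_value < 0.01

    def test_exact_rank_sum_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(3, 7)))
            y = rng.normal(size=int(rng.integers(3, 7)))
            assert rank_sum_test(x, y).p_value == pytest.approx(
                rank_sum_oracle(x, y), rel=1e-9)

    def test_exact_signed_rank_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = rng.normal(size=int(rng.integers(5, 9)))
            assert signed_rank_test(d).p_value == pytest.approx(
                signed_rank_oracle(d), rel=1e-9)

    def test_all_zero_differences_is_no_signal(self):
        res = signed_rank_test([0.0, 0.0, 0.0])
        assert res.p_value == 1.0

    def test_signed_rank_antisymmetric(self):
        d = [1.0, -2.0, 3.0, 4.0, -0.5]
        r1 = signed_rank_test(d)
        r2 = signed_rank_test([-v for v in d])
        assert r1.p_value == pytest.approx(r2.p_value)
        assert {r1.direction, r2.direction} == {"greater", "less"}


# ---------------------------------------------------------------------------
# proximity tests


def gene_table(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end",
                                       "state", "expression", "de_flag",
                                       "direction"])


class TestDEProximity:
    def test_empty_neighborhood(self):
        genes = gene_table([(f"g{i}", "c", i * 50_000, i * 50_000 + 1_000,
                             "BLACK", 1.0, i < 3, "up" if i < 3 else "none")
                            for i in range(10)])
        feats = FeatureSet("f", [GenomicInterval("c", 900_000, 900_100)])
        res = de_proximity_enrichment(genes, feats, window=10_000)
        assert res.observed == 0
        assert res.p_value == 1.0

    def test_window_is_strict_gap(self):
        genes = gene_table([("g0", "c", 0, 1_000, "BLACK", 1.0, True, "up"),
                            ("g1", "c", 50_000, 51_000, "BLACK", 1.0, True, "up")])
        feats = FeatureSet("f", [GenomicInterval("c", 10_999, 11_100)])
        res = de_proximity_enrichment(genes, feats, window=10_000)
        assert res.observed == 1  # gap 9999 < 10000; g1 far away
        feats2 = FeatureSet("f", [GenomicInterval("c", 11_000, 11_100)])
        res2 = de_proximity_enrichment(genes, feats2, window=10_000)
        assert res2.observed == 0  # gap exactly 10000 does not count

    def test_percentage_reporting_one_decimal(self):
        from tadevol.stats import ProximityTestResult
        r = ProximityTestResult(231, 170.0, 10_000, 964, 1e-8, "x")
        assert r.observed_pct() == 24.0
        assert ProximityTestResult(335, 217.0, 10_000, 964, 1e-8, "x").observed_pct() == 34.8
        assert ProximityTestResult(217, 217.0, 10_000, 964, 1e-8, "x").observed_pct() == 22.5

    def test_exclusion_of_features_overlapping(self):
        genes = gene_table([("g0", "c", 0, 1_000, "BLACK", 1.0, True, "up")])
        feats = FeatureSet("f", [GenomicInterval("c", 2_000, 2_100)])
        mask = FeatureSet("m", [GenomicInterval("c", 2_050, 2_060)])
        res = de_proximity_enrichment(genes, feats, 10_000,
                                      exclude_features_overlapping=mask)
        assert res.observed == 0  # the only feature was excluded

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            de_proximity_enrichment(gene_table([]), FeatureSet("f", []), 10_000)


class TestPermutationProximity:
    def test_saturated_reference_p_one(self):
        sizes = ChromSizes({"c": 100_000})
        refs = FeatureSet("r", [GenomicInterval("c", 0, 100_000)])
        queries = FeatureSet("q", [GenomicInterval("c", i * 1_000, i * 1_000 + 100)
                                   for i in range(5)])
        res = permutation_proximity(queries, refs, sizes, "overlap_count",
                                    n_perm=50, seed=0)
        assert res.p_value == 1.0

    def test_minimum_attainable_p(self):
        # planted perfect clustering: queries identical to references
        sizes = ChromSizes({"c": 10_000_000})
        refs = FeatureSet("r", [GenomicInterval("c", i * 500_000, i * 500_000 + 100)
                                for i in range(10)])
        res = permutation_proximity(refs, refs, sizes, "overlap_count",
                                    n_perm=1_000, seed=1)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_deterministic_given_seed(self):
        sizes = ChromSizes({"c": 1_000_000})
        refs = FeatureSet("r", [GenomicInterval("c", 0, 10_000)])
        queries = FeatureSet("q", [GenomicInterval("c", 500_000, 501_000)])
        r1 = permutation_proximity(queries, refs, sizes, "median_distance",
                                   n_perm=99, seed=5)
        r2 = permutation_proximity(queries, refs, sizes, "median_distance",
                                   n_perm=99, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.extra["null"] == r2.extra["null"]


# ---------------------------------------------------------------------------
# state assignment and per-state comparisons


def segments(triples):
    return FeatureSet("seg", [GenomicInterval(c, s, e) for c, s, e, _ in triples],
                      attrs=pd.DataFrame({"state": [t[3] for t in triples]}))


class TestChromatinState:
    def test_full_containment(self):
        seg = segments([("c", 0, 50_000, "YELLOW")])
        assert assign_chromatin_state(GenomicInterval("c", 10_000, 20_000), seg) == "YELLOW"

    def test_majority_coverage(self):
        seg = segments([("c", 0, 6_000, "YELLOW"), ("c", 6_000, 10_000, "BLACK")])
        assert assign_chromatin_state(GenomicInterval("c", 0, 10_000), seg) == "YELLOW"

    def test_no_coverage_unassigned(self):
        seg = segments([("c", 0, 1_000, "RED")])
        assert assign_chromatin_state(GenomicInterval("c", 50_000, 60_000), seg) == "unassigned"

    def test_coverage_never_exceeds_gene_length(self):
        seg = segments([("c", 0, 5_000, "RED"), ("c", 5_000, 9_000, "BLUE"),
                        ("c", 9_000, 20_000, "GREEN")])
        gene = GenomicInterval("c", 2_000, 12_000)
        from tadevol.core import interval_overlap
        total = sum(interval_overlap(gene, iv) for iv in seg.intervals)
        assert total <= len(gene)


class TestGroupComparisons:
    def test_identical_composition_null(self):
        g = gene_table([(f"g{i}", "c", i, i + 10, s, 1.0, False, "none")
                        for i, s in enumerate(["BLACK", "BLUE", "GREEN",
                                               "RED", "YELLOW"] * 4)])
        df = state_enrichment(g, g.copy())
        assert (df["p_value"] == 1.0).all()

    def test_breakpoint_state_null(self):
        seg = segments([("c", 0, 100_000, "YELLOW"), ("c", 100_000, 200_000, "BLACK")])
        pts = [("c", 50_000), ("c", 150_000)] * 10
        df = breakpoint_state_comparison(pts, list(pts), seg)
        assert (df["p_value"] == 1.0).all()

    def test_expression_comparison_identical_null(self):
        g = gene_table([(f"g{i}", "c", i, i + 10, "BLACK", float(i + 1),
                         i % 2 == 0, "up" if i % 2 == 0 else "none")
                        for i in range(20)])
        out = expression_comparison(g, g.copy())
        assert out["expression_rank_sum"].p_value == pytest.approx(1.0)
        assert out["up_fraction_fisher"].p_value == pytest.approx(1.0)

    def test_shifted_expression_detected(self):
        rng = np.random.default_rng(4)
        rows_a = [(f"a{i}", "c", i, i + 10, "BLACK", float(v), False, "none")
                  for i, v in enumerate(rng.lognormal(1.0, 0.5, 500))]
        rows_b = [(f"b{i}", "c", i, i + 10, "BLACK", float(v), False, "none")
                  for i, v in enumerate(rng.lognormal(1.6, 0.5, 500))]
        out = expression_comparison(gene_table(rows_a), gene_table(rows_b))
        assert out["expression_rank_sum"].p_value < 0.01
        assert out["expression_rank_sum"].direction == "less"


def test_gene_domain_membership_largest_overlap_leftmost_ties():
    genes = pd.DataFrame({"id": ["g"], "chrom": ["c"], "start": [40_000],
                          "end": [60_000]})
    domains = FeatureSet("d", [GenomicInterval("c", 0, 50_000),
                               GenomicInterval("c", 50_000, 100_000)])
    # exactly 10 kb in each -> leftmost wins
    assert gene_domain_membership(genes, domains).iloc[0] == 0
    genes2 = pd.DataFrame({"id": ["g"], "chrom": ["c"], "start": [45_000],
                           "end": [60_000]})
    assert gene_domain_membership(genes2, domains).iloc[0] == 1
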