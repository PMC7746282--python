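"""Synthetic-data generator: geometry, determinism, planted-event truth,
chain consistency and dataset round-trips."""

import json

import numpy as np
import pytest

from tadevol.chain import read_chain
from tadevol.core import ConfigurationError
from tadevol.simulate import (
    EvolutionParams,
    TruthSet,
    evolve_pair,
    generate_ancestor,
    read_dataset,
    simulate_pair,
    write_dataset,
)

from conftest import noiseless_params


def small_params(**kw) -> EvolutionParams:
    base = dict(n_chromosomes=2, chromosome_length=5_000_000, n_domains=40,
                domain_length_mean=80_000, domain_length_sd=15_000,
                domains_per_run_mean=1e9,  # one run per chromosome
                n_inversions=0, n_translocations=0, n_indels=0,
                p_boundary_gain=0.0, p_boundary_loss=0.0,
                p_missing_boundary=0.0, p_missing_domain=0.0,
                p_replicate_drop=0.0, jitter_sd=0.0, n_genes=200,
                n_polymorphic_breakpoints=0)
    base.update(kw)
    return EvolutionParams(**base)


class TestGenerateAncestor:
    def test_domain_and_boundary_counts(self):
        anc = generate_ancestor(small_params(), seed=1)
        assert len(anc.domains) == 40
        assert 38 <= len(anc.boundaries) <= 42
        # invariants: domains tile between boundaries, inside the chromosome
        for d in anc.domains:
            assert 0 <= d.start < d.end <= anc.chrom_sizes[d.chrom]
        starts = {(b.chrom, b.end) for b in anc.boundaries}
        for d in anc.domains:
            assert (d.chrom, d.start) in starts  # every domain starts at a boundary

    def test_single_domain_per_chromosome_no_internal_boundaries(self):
        anc = generate_ancestor(small_params(n_domains=2), seed=1)
        assert len(anc.domains) == 2
        assert sum(1 for b in anc.boundaries if b.internal) == 0

    def test_determinism(self):
        p = small_params()
        a1 = generate_ancestor(p, seed=7)
        a2 = generate_ancestor(small_params(), seed=7)
        assert [(d.chrom, d.start, d.end, d.state) for d in a1.domains] == \
               [(d.chrom, d.start, d.end, d.state) for d in a2.domains]
        assert a1.genes.equals(a2.genes)

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ConfigurationError):
            generate_ancestor(small_params(chromosome_length=1_000_000,
                                           n_domains=40), seed=1)

    def test_insulation_dips_at_boundaries(self):
        anc = generate_ancestor(small_params(), seed=3)
        track = anc.insulation
        bins = {(c, s // 5_000) for c, s in
                zip(track["chrom"], track["start"])}
        by_bin = {(c, s // 5_000): v for c, s, v in
                  zip(track["chrom"], track["start"], track["score"])}
        boundary_scores = []
        for b in anc.boundaries:
            key = (b.chrom, b.start // 5_000)
            if key in bins:
                boundary_scores.append(by_bin[key])
        other = [v for k, v in by_bin.items()
                 if k not in {(b.chrom, b.start // 5_000) for b in anc.boundaries}]
        assert np.median(boundary_scores) < np.median(other) - 1.0


class TestEvolvePair:
    def test_null_evolution_identity(self):
        anc = generate_ancestor(small_params(), seed=2)
        pair = evolve_pair(anc, seed=3)
        # species coordinates identical, chain is the identity
        assert pair.species_a.chrom_sizes == pair.species_b.chrom_sizes
        assert all(b.src == b.tgt and b.orientation == "+"
                   for b in pair.chain.blocks)
        a = pair.species_a.boundaries
        b = pair.species_b.boundaries
        assert [(i.chrom, i.start, i.end) for i in a] == \
               [(i.chrom, i.start, i.end) for i in b]
        assert all(c == "orthologous"
                   for c in pair.truth.domain_category_ab.values())
        assert all(s == "orthologous"
                   for s in pair.truth.boundary_status_a.values())

    def test_cross_domain_inversions_split_two_domains_each(self):
        p = small_params(n_inversions=5, restrict_breakpoints_to_domains=True,
                        n_domains=60, domain_length_mean=80_000)
        anc = generate_ancestor(p, seed=5)
        pair = evolve_pair(anc, seed=6)
        split = [n for n, c in pair.truth.domain_category_ab.items()
                 if c == "split_by_rearrangement"]
        # each inversion has both cut points strictly inside distinct
        # domains, so it splits exactly two of them
        assert len(split) == 10
        cut_domains = {j.domain for j in pair.truth.junctions if j.splits}
        assert len(cut_domains) == 10

    def test_default_scale_matches_study_conditions(self):
        pair = simulate_pair(EvolutionParams(), seed=4)
        sizes = [len(b.src) for b in pair.synteny]
        assert 800 <= len(pair.synteny) <= 1300
        assert 5e4 <= np.mean(sizes) <= 2.5e5
        assert 500 <= len(pair.species_a.domains) <= 700
        assert 600 <= len(pair.species_a.boundaries) <= 820

    def test_chain_per_base_bijection_on_covered_positions(self, noiseless_pair):
        """Mapping through the chain is a bijection on covered bases."""
        rng = np.random.default_rng(0)
        seen = set()
        blocks = noiseless_pair.chain.blocks
        for bi in rng.choice(len(blocks), size=min(60, len(blocks)), replace=False):
            b = blocks[bi]
            for off in (0, len(b.src) // 2, len(b.src) - 1):
                img = (b.tgt.chrom, b.map_offset(off))
                assert img not in seen
                seen.add(img)

    def test_de_planting_enriches_near_disruptions(self):
        p = small_params(n_inversions=6, n_indels=4, n_genes=4_000,
                        restrict_breakpoints_to_domains=False,
                        domains_per_run_mean=4, n_domains=60,
                        p_de_background=0.08, de_near_factor=2.0)
        anc = generate_ancestor(p, seed=8)
        pair = evolve_pair(anc, seed=9)
        g = pair.genes
        near = g[g.near_disruption]
        far = g[~g.near_disruption]
        assert len(near) >= 50
        rate_near = near.de_flag.mean()
        rate_far = far.de_flag.mean()
        # 2x enrichment within binomial error
        se = np.sqrt(0.16 * 0.84 / len(near) + 0.08 * 0.92 / len(far))
        assert abs((rate_near - 2 * rate_far)) < 4 * se + 0.08 * 0.2

    def test_determinism_byte_identical(self, tmp_path):
        p = small_params(n_inversions=3, n_indels=2, p_boundary_gain=0.1,
                        domains_per_run_mean=3)
        out1, out2 = tmp_path / "d1", tmp_path / "d2"
        for out in (out1, out2):
            anc = generate_ancestor(small_params(
                n_inversions=3, n_indels=2, p_boundary_gain=0.1,
                domains_per_run_mean=3), seed=13)
            write_dataset(evolve_pair(anc, seed=14), out, seed=13)
        for f in sorted(out1.iterdir()):
            assert (out2 / f.name).read_bytes() == f.read_bytes()


class TestWriteDataset:
    def test_round_trip(self, tmp_path, noiseless_pair):
        manifest = write_dataset(noiseless_pair, tmp_path / "ds", seed=11)
        assert manifest["seed"] == 11
        back = read_dataset(tmp_path / "ds")
        assert back["manifest"]["seed"] == 11
        # chain file validates under the liftover reader and matches
        chain2 = back["chain"]
        assert chain2.blocks == noiseless_pair.chain.blocks
        # feature sets survive the BED round trip
        a = noiseless_pair.species_a.boundaries
        a2 = back["A_boundaries"]
        assert [(i.chrom, i.start, i.end) for i in a] == \
               [(i.chrom, i.start, i.end) for i in a2]
        assert a.feature_names() == a2.feature_names()
        # truth survives JSON
        t2 = back["truth"]
        assert t2.domain_category_ab == noiseless_pair.truth.domain_category_ab
        assert len(t2.junctions) == len(noiseless_pair.truth.junctions)

    def test_truth_json_round_trip(self, tmp_path, noiseless_pair):
        path = tmp_path / "truth.json"
        noiseless_pair.truth.to_json(path)
        t2 = TruthSet.from_json(path)
        assert t2.boundary_status_a == noiseless_pair.truth.boundary_status_a
        assert t2.gains == noiseless_pair.truth.gains


def test_replicate_noise_rates():
    """Replicate drop probability shapes the both-replicate agreement rate."""
    p = small_params(p_replicate_drop=0.15, jitter_sd=1000.0,
                    domains_per_run_mean=4, n_domains=80,
                    domain_length_mean=60_000)
    anc = generate_ancestor(p, seed=31)
    pair = evolve_pair(anc, seed=32)
    n = len(pair.species_a.boundaries)
    kept = len(pair.species_a.replicate_boundaries[1])
    assert abs(kept / n - 0.85) < 0.12
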