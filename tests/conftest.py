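"""Shared fixtures: hand-built orthology maps and seeded simulations."""

from __future__ import annotations

import pytest

from tadevol.chain import AlignmentBlock, OrthologyMap
from tadevol.core import ChromSizes, GenomicInterval
from tadevol.simulate import EvolutionParams, generate_ancestor, evolve_pair


def make_map(blocks, src_sizes, tgt_sizes):
    return OrthologyMap(
        [AlignmentBlock(GenomicInterval(*s), GenomicInterval(*t), o)
         for s, t, o in blocks],
        ChromSizes(src_sizes), ChromSizes(tgt_sizes),
    )


@pytest.fixture
def identity_map():
    """One chromosome, 1 Mb, identity alignment."""
    return make_map([(("chrA", 0, 1_000_000), ("chrA", 0, 1_000_000), "+")],
                    {"chrA": 1_000_000}, {"chrA": 1_000_000})


@pytest.fixture
def inversion_map():
    """1 Mb chromosome with an inverted middle third.

    Source [0, 300k) -> target [0, 300k) forward; source [300k, 600k) ->
    target [300k, 600k) inverted; source [600k, 1M) forward.
    """
    return make_map(
        [(("chrA", 0, 300_000), ("chrA", 0, 300_000), "+"),
         (("chrA", 300_000, 600_000), ("chrA", 300_000, 600_000), "-"),
         (("chrA", 600_000, 1_000_000), ("chrA", 600_000, 1_000_000), "+")],
        {"chrA": 1_000_000}, {"chrA": 1_000_000},
    )


def noiseless_params(**overrides) -> EvolutionParams:
    """Zero-replicate-noise simulation at the controlled recovery scale:
    3 chromosomes x 5 Mb, ~120 domains, 10 domain-splitting inversions,
    8 planted boundary gains, 5 large indels."""
    base = dict(
        n_chromosomes=3, chromosome_length=5_000_000, n_domains=120,
        domain_length_mean=80_000, domain_length_sd=15_000,
        n_inversions=10, n_translocations=0, n_indels=5,
        n_boundary_gains=8, n_boundary_losses=0,
        p_missing_boundary=0.0, p_missing_domain=0.0,
        restrict_breakpoints_to_domains=True,
        p_replicate_drop=0.0, jitter_sd=0.0,
        n_genes=500, n_polymorphic_breakpoints=50,
    )
    base.update(overrides)
    return EvolutionParams(**base)


@pytest.fixture(scope="session")
def noiseless_pair():
    params = noiseless_params()
    anc = generate_ancestor(params, seed=11)
    return evolve_pair(anc, seed=12)


@pytest.fixture(scope="session")
def noisy_pair():
    """Small noisy simulation exercising every event type and replicates."""
    params = EvolutionParams(
        n_chromosomes=2, chromosome_length=6_000_000, n_domains=80,
        domain_length_mean=70_000, domain_length_sd=15_000,
        n_inversions=8, n_translocations=3, n_indels=4,
        n_genes=1_500, n_polymorphic_breakpoints=80,
        with_sequence=True,
    )
    anc = generate_ancestor(params, seed=21)
    return evolve_pair(anc, seed=22)
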