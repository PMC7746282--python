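"""Synthetic comparative-genome generator with full ground truth.

Generates an ancestral genome organised into TAD runs separated by
unorganised gaps, then evolves two descendant species from it:

* species A keeps the ancestral coordinate system and acquires only
  boundary gains/losses;
* species B additionally acquires coordinate-changing mutations
  (inversions, intra-chromosomal translocations, large indels), applied as
  segment surgery so that the exact alignment chain between the two
  genomes is known by construction.

Because divergence between the two species is all any comparative analysis
can see, placing the coordinate-changing mutations on one lineage loses no
generality while keeping the planted truth exact.

Every planted event is sampled with exclusion margins (at least the domain
merge gap, and a fixed fraction of the domain length, away from domain
edges; pairwise-disjoint footprints; at most one event per domain) chosen
so that the true conservation category of every domain and boundary is
determined by construction and equals what the downstream classifier must
report in the absence of replicate noise.

The generator's defaults emulate the study conditions of a two-Drosophila
comparison: ~116 Mb over five Muller-element chromosomes, ~560 domains of
a few tens of kb organised in runs (~710 boundaries), and enough
rearrangements to yield on the order of a thousand synteny blocks with
mean length ~10^5 bp.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .chain import (
    AlignmentBlock,
    OrthologyMap,
    lift_interval,
    map_position,
    read_chain,
    write_chain,
)
from .classify import SyntenyBlock
from .core import (
    ChromSizes,
    ConfigurationError,
    FeatureSet,
    GenomicInterval,
    merge_intervals,
)

CHROMATIN_STATES = ("BLACK", "BLUE", "GREEN", "RED", "YELLOW")

MULLER_NAMES = ("MullerA", "MullerB", "MullerC", "MullerD", "MullerE", "MullerF")

#: Insulator-protein binding motif consensus sequences planted at boundaries.
DEFAULT_MOTIFS = {"BEAF-32": "TCGATA", "M1BP": "GGTCACACT"}


@dataclass
class EvolutionParams:
    """All knobs of the two-species simulation.

    Defaults are the emulated study conditions; rates the source study does
    not pin down (boundary gain/loss probability, replicate drop rate,
    jitter) are free parameters documented in the methods note.
    """

    # ancestral geometry
    n_chromosomes: int = 5
    chromosome_length: int = 23_200_000
    n_domains: int = 560
    domain_length_mean: int = 42_000
    domain_length_sd: int = 12_000
    domain_min_length: int = 15_000
    boundary_width: int = 5_000  # one 5 kb Hi-C bin
    domains_per_run_mean: float = 3.75
    min_gap_length: int = 10_000
    # chromatin
    state_freqs: dict = field(
        default_factory=lambda: {
            "BLACK": 0.40, "BLUE": 0.08, "GREEN": 0.15, "RED": 0.12, "YELLOW": 0.25,
        }
    )
    breakpoint_state_weights: dict = field(
        default_factory=lambda: {
            "BLACK": 1.0, "BLUE": 1.0, "GREEN": 1.0, "RED": 1.0, "YELLOW": 3.0,
        }
    )
    # coordinate-changing mutations (lineage B)
    n_inversions: int = 343
    n_translocations: int = 100
    n_indels: int = 40
    indel_size_mean: int = 30_000
    indel_size_sd: int = 4_000
    indel_size_min: int = 25_000
    translocation_chunk_min: int = 25_000
    translocation_chunk_max: int = 40_000
    inversion_span_mean: int = 150_000
    inversion_span_sd: int = 60_000
    inversion_span_min: int = 60_000
    restrict_breakpoints_to_domains: bool = False
    event_margin: int = 20_000
    margin_frac: float = 0.12
    # boundary turnover (both lineages); the realized lineage-specific
    # fraction is lower than the nominal rate because turnover is only
    # planted where the ground truth stays unambiguous (see methods note)
    p_boundary_loss: float = 0.35
    p_boundary_gain: float = 0.35
    # exact event counts override the probabilities when set
    n_boundary_gains: Optional[int] = None
    n_boundary_losses: Optional[int] = None
    # unalignable regions: features whose orthologous sequence cannot be
    # lifted over (alignment holes), yielding "missing" classifications
    p_missing_boundary: float = 0.35
    p_missing_domain: float = 0.06
    unalignable_pad: int = 3_000
    # polymorphic (within-species) comparator breakpoints
    n_polymorphic_breakpoints: int = 200
    # genes / expression
    n_genes: int = 8_000
    gene_length_min: int = 1_000
    gene_length_max: int = 10_000
    p_de_background: float = 0.07
    de_near_factor: float = 2.0
    de_window: int = 10_000
    de_log2fc_mean: float = 1.5
    de_log2fc_sd: float = 0.5
    # replicate noise
    p_replicate_drop: float = 0.15
    jitter_sd: float = 1_000.0
    jitter_max: int = 2_000
    # insulation track
    insulation_bin: int = 5_000
    boundary_dip: float = 2.5
    preinsulation_dip: float = 1.0
    insulation_noise_sd: float = 0.25
    # replicate tracks share the biological signal; only measurement noise
    # differs, giving the high between-replicate rank correlation of real
    # TAD separation scores
    replicate_track_noise_sd: float = 0.015
    # sequence / motifs
    with_sequence: bool = False
    motifs: dict = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    motifs_per_boundary_mean: float = 3.0
    # synteny-block derivation
    synteny_join_gap: int = 10_000

    def validate(self) -> None:
        for name in ("p_boundary_loss", "p_boundary_gain", "p_de_background",
                     "p_replicate_drop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("n_chromosomes", "n_domains", "n_inversions",
                     "n_translocations", "n_indels", "n_genes",
                     "n_polymorphic_breakpoints"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        w = [self.breakpoint_state_weights.get(s, 0.0) for s in CHROMATIN_STATES]
        if any(x < 0 for x in w) or not any(x > 0 for x in w):
            raise ConfigurationError("state weights must be non-negative, not all zero")
        if abs(sum(self.state_freqs.get(s, 0.0) for s in CHROMATIN_STATES) - 1.0) > 1e-6:
            raise ConfigurationError("state frequencies must sum to 1")


# ---------------------------------------------------------------------------
# ancestral genome


@dataclass
class Domain:
    id: int
    chrom: str
    start: int
    end: int
    state: str
    run_id: int
    used: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class Boundary:
    id: int
    chrom: str
    start: int
    end: int
    internal: bool  # between two domains of the same run
    left_domain: Optional[int]
    right_domain: Optional[int]

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class Ancestor:
    chrom_sizes: ChromSizes
    domains: list[Domain]
    boundaries: list[Boundary]
    gap_states: list[tuple[str, int, int, str]]  # chrom, start, end, state of gaps
    genes: pd.DataFrame
    insulation: pd.DataFrame
    sequence: Optional[dict[str, np.ndarray]]
    params: EvolutionParams

    def state_segments(self) -> FeatureSet:
        """Non-overlapping 5-state chromatin segmentation of the genome."""
        rows = []
        for d in self.domains:
            rows.append((d.chrom, d.start, d.end, d.state))
        for chrom, start, end, state in self.gap_states:
            rows.append((chrom, start, end, state))
        for b in self.boundaries:
            # boundary bins take the state of the left neighbouring unit
            rows.append((b.chrom, b.start, b.end, self._state_left_of(b)))
        rows.sort()
        merged: list[list] = []
        for chrom, start, end, state in rows:
            if merged and merged[-1][0] == chrom and merged[-1][2] == start and merged[-1][3] == state:
                merged[-1][2] = end
            else:
                merged.append([chrom, start, end, state])
        fs = FeatureSet(
            "chromatin_states",
            [GenomicInterval(c, s, e) for c, s, e, _ in merged],
            attrs=pd.DataFrame({"state": [st for *_, st in merged]}),
        )
        return fs

    def _state_left_of(self, b: Boundary) -> str:
        if b.left_domain is not None:
            return self.domains[b.left_domain].state
        return self.domains[b.right_domain].state


def _draw_state(rng: np.random.Generator, freqs: dict) -> str:
    p = np.array([freqs.get(s, 0.0) for s in CHROMATIN_STATES], dtype=float)
    return CHROMATIN_STATES[rng.choice(len(CHROMATIN_STATES), p=p / p.sum())]


def generate_ancestor(params: EvolutionParams, seed: int = 0) -> Ancestor:
    """Build the ancestral genome bundle.

    Domains are laid out in runs (``[B][D][B][D]...[B]``) separated by
    unorganised gaps; every domain and gap carries one of the five
    chromatin states; genes receive state-coupled expression levels; the
    insulation track has dips at boundaries.  Deterministic given ``seed``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    names = list(MULLER_NAMES[: params.n_chromosomes])
    if params.n_chromosomes > len(MULLER_NAMES):
        names += [f"chr{i}" for i in range(len(MULLER_NAMES), params.n_chromosomes)]
    chrom_sizes = ChromSizes({n: params.chromosome_length for n in names})

    domains: list[Domain] = []
    boundaries: list[Boundary] = []
    gap_states: list[tuple[str, int, int, str]] = []
    bw = params.boundary_width
    run_counter = 0

    base = params.n_domains // params.n_chromosomes
    rem = params.n_domains % params.n_chromosomes
    for ci, chrom in enumerate(names):
        k = base + (1 if ci < rem else 0)
        if k == 0:
            gap_states.append((chrom, 0, params.chromosome_length, _draw_state(rng, params.state_freqs)))
            continue
        lengths = rng.normal(params.domain_length_mean, params.domain_length_sd, size=k)
        lengths = np.maximum(lengths, params.domain_min_length).round().astype(int)
        # split the k domains into runs
        if params.domains_per_run_mean >= k:
            runs = [k]
        else:
            runs = []
            left = k
            p_geo = 1.0 / max(params.domains_per_run_mean, 1.0)
            while left > 0:
                r = int(min(rng.geometric(p_geo), left))
                runs.append(r)
                left -= r
        n_runs = len(runs)
        occupied = int(lengths.sum()) + (k + n_runs) * bw
        free = params.chromosome_length - occupied
        if free < (n_runs + 1) * params.min_gap_length:
            raise ConfigurationError(
                f"domains cannot fit on {chrom}: need {occupied} bp plus gaps, "
                f"have {params.chromosome_length}"
            )
        weights = rng.uniform(0.5, 1.5, size=n_runs + 1)
        gaps = np.floor(free * weights / weights.sum()).astype(int)
        gaps[-1] = free - int(gaps[:-1].sum())

        pos = 0
        li = 0
        for ri, r in enumerate(runs):
            gstate = _draw_state(rng, params.state_freqs)
            gap_states.append((chrom, pos, pos + int(gaps[ri]), gstate))
            pos += int(gaps[ri])
            left_dom: Optional[int] = None
            for j in range(r):
                bid = len(boundaries)
                boundaries.append(
                    Boundary(bid, chrom, pos, pos + bw, internal=j > 0,
                             left_domain=left_dom, right_domain=len(domains))
                )
                pos += bw
                did = len(domains)
                domains.append(
                    Domain(did, chrom, pos, pos + int(lengths[li]),
                           _draw_state(rng, params.state_freqs), run_counter)
                )
                pos += int(lengths[li])
                left_dom = did
                li += 1
            bid = len(boundaries)
            boundaries.append(
                Boundary(bid, chrom, pos, pos + bw, internal=False,
                         left_domain=left_dom, right_domain=None)
            )
            pos += bw
            run_counter += 1
        gstate = _draw_state(rng, params.state_freqs)
        gap_states.append((chrom, pos, pos + int(gaps[-1]), gstate))

    anc = Ancestor(chrom_sizes, domains, boundaries, gap_states,
                   genes=pd.DataFrame(), insulation=pd.DataFrame(),
                   sequence=None, params=params)
    anc.genes = _place_genes(anc, rng)
    anc.insulation = _insulation_track(
        chrom_sizes, [b.interval() for b in boundaries], [], params, rng
    )
    if params.with_sequence:
        anc.sequence = _ancestral_sequence(anc, rng)
    return anc


def _place_genes(anc: Ancestor, rng: np.random.Generator) -> pd.DataFrame:
    p = anc.params
    segments = anc.state_segments()
    states = segments.attrs["state"].to_numpy()
    chroms = list(anc.chrom_sizes)
    lens = np.array([anc.chrom_sizes[c] for c in chroms], dtype=float)
    rows = []
    # expression regimes: active states are expressed higher
    expr_mu = {"YELLOW": 4.5, "RED": 4.0, "BLACK": 1.2, "BLUE": 1.0, "GREEN": 0.8}
    seg_bounds: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in chroms:
        idx = [i for i, iv in enumerate(segments.intervals) if iv.chrom == c]
        seg_bounds[c] = (
            np.array([segments.intervals[i].start for i in idx]),
            np.array([segments.intervals[i].end for i in idx]),
            states[idx],
        )
    for gi in range(p.n_genes):
        c = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
        glen = int(rng.integers(p.gene_length_min, p.gene_length_max + 1))
        start = int(rng.integers(0, anc.chrom_sizes[c] - glen))
        end = start + glen
        starts, ends, seg_states = seg_bounds[c]
        cover = np.minimum(ends, end) - np.maximum(starts, start)
        cover = np.where(cover > 0, cover, 0)
        state = seg_states[int(cover.argmax())] if cover.sum() > 0 else "unassigned"
        expr = float(rng.lognormal(expr_mu.get(state, 1.0), 1.0))
        rows.append((f"gene{gi:05d}", c, start, end, state, expr))
    df = pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "state", "expression"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _insulation_track(
    chrom_sizes: ChromSizes,
    boundary_intervals: list[GenomicInterval],
    preinsulated_points: list[tuple[str, int]],
    params: EvolutionParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Smooth noise baseline with dips (lower = more insulated) planted at
    boundaries and, more shallowly, at pre-insulated ancestral sites."""
    binsz = params.insulation_bin
    frames = []
    for chrom, clen in chrom_sizes.items():
        n = clen // binsz
        noise = rng.normal(0.0, params.insulation_noise_sd, size=n + 4)
        kernel = np.ones(5) / 5.0
        score = np.convolve(noise, kernel, mode="same")[:n]
        for iv in boundary_intervals:
            if iv.chrom != chrom:
                continue
            b0, b1 = iv.start // binsz, (iv.end - 1) // binsz
            score[b0 : min(b1 + 1, n)] -= params.boundary_dip
        for c, pos in preinsulated_points:
            if c != chrom:
                continue
            bi = pos // binsz
            if 0 <= bi < n:
                score[bi] -= params.preinsulation_dip
        starts = np.arange(n) * binsz
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + binsz, "score": score,
        }))
    return pd.concat(frames, ignore_index=True)


BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _revcomp(seq: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    return comp[seq][::-1]


def _ancestral_sequence(anc: Ancestor, rng: np.random.Generator) -> dict[str, np.ndarray]:
    seqs = {}
    for chrom, clen in anc.chrom_sizes.items():
        seqs[chrom] = BASES[rng.integers(0, 4, size=clen)]
    for b in anc.boundaries:
        _plant_motifs(seqs[b.chrom], b.start, b.end, anc.params, rng)
    return seqs


def _plant_motifs(seq: np.ndarray, start: int, end: int,
                  params: EvolutionParams, rng: np.random.Generator) -> int:
    """Plant non-overlapping motif instances in ``seq[start:end]``; returns count."""
    n = 1 + rng.poisson(max(params.motifs_per_boundary_mean - 1, 0.0))
    motif_names = sorted(params.motifs)
    placed: list[tuple[int, int]] = []
    count = 0
    for _ in range(int(n)):
        name = motif_names[rng.integers(0, len(motif_names))]
        m = np.frombuffer(params.motifs[name].encode(), dtype=np.uint8)
        if rng.random() < 0.5:
            m = _revcomp(m)
        for _attempt in range(20):
            pos = int(rng.integers(start, end - len(m)))
            if all(pos + len(m) <= a or pos >= b for a, b in placed):
                seq[pos : pos + len(m)] = m
                placed.append((pos, pos + len(m)))
                count += 1
                break
    return count


# ---------------------------------------------------------------------------
# evolution


@dataclass
class Junction:
    """A planted rearrangement junction, in ancestral coordinates."""

    chrom: str
    pos: int
    kind: str     # inversion | translocation_cut | translocation_insert | insertion | deletion
    splits: bool  # whether the containing domain's image becomes discontiguous
    domain: Optional[int]
    state: str = ""


@dataclass
class TruthSet:
    """Ground truth of planted events, keyed by feature call names."""

    domain_category_ab: dict = field(default_factory=dict)
    domain_category_ba: dict = field(default_factory=dict)
    boundary_status_a: dict = field(default_factory=dict)
    boundary_status_b: dict = field(default_factory=dict)
    junctions: list = field(default_factory=list)
    gains: list = field(default_factory=list)   # (species, chrom, center, anc interval)
    losses: list = field(default_factory=list)  # (species, boundary_id)
    de_gene_ids: list = field(default_factory=list)
    planted_motifs: dict = field(default_factory=dict)  # species -> {boundary name: count}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "domain_category_ab": self.domain_category_ab,
            "domain_category_ba": self.domain_category_ba,
            "boundary_status_a": self.boundary_status_a,
            "boundary_status_b": self.boundary_status_b,
            "junctions": [asdict(j) for j in self.junctions],
            "gains": self.gains,
            "losses": self.losses,
            "de_gene_ids": self.de_gene_ids,
            "planted_motifs": self.planted_motifs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        t = cls()
        t.domain_category_ab = d["domain_category_ab"]
        t.domain_category_ba = d["domain_category_ba"]
        t.boundary_status_a = d["boundary_status_a"]
        t.boundary_status_b = d["boundary_status_b"]
        t.junctions = [Junction(**j) for j in d["junctions"]]
        t.gains = [tuple(g) for g in d["gains"]]
        t.losses = [tuple(l) for l in d["losses"]]
        t.de_gene_ids = d["de_gene_ids"]
        t.planted_motifs = d["planted_motifs"]
        return t


@dataclass
class SpeciesCalls:
    name: str
    chrom_sizes: ChromSizes
    boundaries: FeatureSet
    domains: FeatureSet
    replicate_boundaries: dict = field(default_factory=dict)  # rep -> FeatureSet
    replicate_domains: dict = field(default_factory=dict)
    insulation: dict = field(default_factory=dict)  # rep -> DataFrame
    sequence: Optional[dict] = None


@dataclass
class SimulatedPair:
    ancestor: Ancestor
    species_a: SpeciesCalls
    species_b: SpeciesCalls
    chain: OrthologyMap
    synteny: list[AlignmentBlock]
    genes: pd.DataFrame
    state_segments: FeatureSet
    truth: TruthSet
    polymorphic_breakpoints: list[tuple[str, int]]
    params: EvolutionParams


# -- segment surgery (species B genome construction) ------------------------


@dataclass
class _Segment:
    """One piece of a descendant chromosome: ancestral slice or insertion."""

    anc_chrom: Optional[str]  # None for novel insertions
    start: int
    end: int
    orient: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


class _GenomeBuilder:
    """Mutable segment-list representation of the evolving B genome.

    Event regions are pairwise disjoint in ancestral coordinates, so every
    region a new event touches is still a pristine, forward-orientation,
    contiguous run of segments at the time the event is applied.
    """

    def __init__(self, chrom_sizes: ChromSizes):
        self.chroms: dict[str, list[_Segment]] = {
            c: [_Segment(c, 0, L)] for c, L in chrom_sizes.items()
        }
        self._ins_count = 0

    def _locate(self, chrom: str, pos: int) -> int:
        """Index of the pristine segment containing ancestral ``pos``."""
        for i, s in enumerate(self.chroms[chrom]):
            if s.anc_chrom == chrom and s.orient == "+" and s.start <= pos < s.end:
                return i
        raise ConfigurationError(f"ancestral position {chrom}:{pos} not pristine")

    def _split_at(self, chrom: str, pos: int) -> int:
        """Ensure a segment boundary at ancestral ``pos``; return index of the
        segment that starts there."""
        i = self._locate(chrom, pos)
        s = self.chroms[chrom][i]
        if s.start == pos:
            return i
        self.chroms[chrom][i : i + 1] = [
            _Segment(s.anc_chrom, s.start, pos, s.orient),
            _Segment(s.anc_chrom, pos, s.end, s.orient),
        ]
        return i + 1

    def invert(self, chrom: str, p1: int, p2: int) -> None:
        i = self._split_at(chrom, p1)
        j = self._split_at(chrom, p2)
        sub = self.chroms[chrom][i:j]
        for s in sub:
            s.orient = "-" if s.orient == "+" else "+"
        self.chroms[chrom][i:j] = sub[::-1]

    def delete(self, chrom: str, p1: int, p2: int) -> None:
        i = self._split_at(chrom, p1)
        j = self._split_at(chrom, p2)
        del self.chroms[chrom][i:j]

    def insert(self, chrom: str, pos: int, length: int) -> None:
        i = self._split_at(chrom, pos)
        self.chroms[chrom].insert(i, _Segment(None, 0, length))
        self._ins_count += 1

    def translocate(self, chrom: str, p1: int, p2: int, dest: int, orient: str) -> None:
        i = self._split_at(chrom, p1)
        j = self._split_at(chrom, p2)
        chunk = self.chroms[chrom][i:j]
        del self.chroms[chrom][i:j]
        if orient == "-":
            for s in chunk:
                s.orient = "-" if s.orient == "+" else "+"
            chunk = chunk[::-1]
        k = self._split_at(chrom, dest)
        self.chroms[chrom][k:k] = chunk

    def build_chain(self, src_sizes: ChromSizes) -> tuple[OrthologyMap, ChromSizes]:
        blocks: list[AlignmentBlock] = []
        tgt_sizes = {}
        for chrom, segs in self.chroms.items():
            pos = 0
            for s in segs:
                if s.anc_chrom is not None:
                    blocks.append(AlignmentBlock(
                        GenomicInterval(s.anc_chrom, s.start, s.end),
                        GenomicInterval(chrom, pos, pos + s.length),
                        s.orient,
                    ))
                pos += s.length
            tgt_sizes[chrom] = pos
        tgt = ChromSizes(tgt_sizes)
        return OrthologyMap(blocks, ChromSizes(src_sizes), tgt), tgt


# -- event sampling ----------------------------------------------------------


class _EventSampler:
    """State-weighted sampler of eligible event positions with disjoint
    footprints and one-event-per-domain bookkeeping."""

    def __init__(self, anc: Ancestor, rng: np.random.Generator):
        self.anc = anc
        self.rng = rng
        p = anc.params
        self.footprints: dict[str, list[tuple[int, int]]] = {c: [] for c in anc.chrom_sizes}
        self.gap_margin = p.event_margin + p.boundary_width + 1_000
        units = []  # (chrom, start, end, state, kind, domain_id)
        for d in anc.domains:
            units.append((d.chrom, d.start, d.end, d.state, "domain", d.id))
        if not p.restrict_breakpoints_to_domains:
            for chrom, s, e, st in anc.gap_states:
                units.append((chrom, s, e, st, "gap", None))
        self.units = units
        self.weights = np.array(
            [max(p.breakpoint_state_weights.get(u[3], 0.0), 0.0) * (u[2] - u[1])
             for u in units], dtype=float)
        if self.weights.sum() <= 0:
            raise ConfigurationError("no sampleable genome under the given weights")
        self.prob = self.weights / self.weights.sum()

    def _domain_margin(self, d: Domain) -> int:
        p = self.anc.params
        return max(p.event_margin, int(p.margin_frac * d.length))

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return all(end <= a or start >= b for a, b in self.footprints[chrom])

    def reserve(self, chrom: str, start: int, end: int) -> None:
        pad = self.anc.params.event_margin
        self.footprints[chrom].append((start - pad, end + pad))

    def sample_point(self, max_tries: int = 2000) -> tuple[str, int, Optional[Domain]]:
        """An eligible cut position: inside a unit's margin zone, outside all
        footprints; returns the containing domain (or None for a gap)."""
        for _ in range(max_tries):
            ui = int(self.rng.choice(len(self.units), p=self.prob))
            chrom, s, e, _st, kind, did = self.units[ui]
            if kind == "domain":
                d = self.anc.domains[did]
                if d.used:
                    continue
                m = self._domain_margin(d)
                if d.length <= 2 * m:
                    continue
                pos = int(self.rng.integers(d.start + m, d.end - m))
                if self._free(chrom, pos, pos + 1):
                    return chrom, pos, d
            else:
                m = self.gap_margin
                if e - s <= 2 * m:
                    continue
                pos = int(self.rng.integers(s + m, e - m))
                if self._free(chrom, pos, pos + 1):
                    return chrom, pos, None
        raise ConfigurationError("could not place event: genome too crowded")

    def sample_fitting_interval(
        self, size: int, max_tries: int = 2000
    ) -> tuple[str, int, Optional[Domain]]:
        """An eligible interval [pos, pos+size) wholly inside one unit's
        margin zone and outside all footprints."""
        for _ in range(max_tries):
            ui = int(self.rng.choice(len(self.units), p=self.prob))
            chrom, s, e, _st, kind, did = self.units[ui]
            if kind == "domain":
                d = self.anc.domains[did]
                if d.used:
                    continue
                m = self._domain_margin(d)
                lo, hi = d.start + m, d.end - m - size
            else:
                lo, hi = s + self.gap_margin, e - self.gap_margin - size
            if hi <= lo:
                continue
            pos = int(self.rng.integers(lo, hi))
            if self._free(chrom, pos, pos + size):
                return chrom, pos, (self.anc.domains[did] if kind == "domain" else None)
        raise ConfigurationError("could not place sized event: genome too crowded")


def _state_at(anc: Ancestor, chrom: str, pos: int) -> str:
    for d in anc.domains:
        if d.chrom == chrom and d.start <= pos < d.end:
            return d.state
    for c, s, e, st in anc.gap_states:
        if c == chrom and s <= pos < e:
            return st
    for b in anc.boundaries:
        if b.chrom == chrom and b.start <= pos < b.end:
            return anc._state_left_of(b)
    return "unassigned"


def evolve_pair(anc: Ancestor, seed: int = 0) -> SimulatedPair:
    """Evolve species A and B from the ancestor; see the module docstring.

    Returns the complete bundle: per-species call sets (with replicates),
    the exact A->B alignment chain, derived synteny blocks, the gene /
    expression table, and the :class:`TruthSet` of planted events.
    """
    p = anc.params
    rng = np.random.default_rng(seed if seed is not None else 0)
    sampler = _EventSampler(anc, rng)
    builder = _GenomeBuilder(anc.chrom_sizes)
    junctions: list[Junction] = []

    def junction(chrom: str, pos: int, kind: str, splits: bool, dom: Optional[Domain]):
        junctions.append(Junction(chrom, pos, kind, splits,
                                  dom.id if dom else None, _state_at(anc, chrom, pos)))

    # -- inversions
    placed = 0
    tries = 0
    while placed < p.n_inversions:
        tries += 1
        if tries > 200 * max(p.n_inversions, 1):
            raise ConfigurationError("could not place requested inversions")
        chrom, p1, d1 = sampler.sample_point()
        span = int(np.clip(rng.normal(p.inversion_span_mean, p.inversion_span_sd),
                           p.inversion_span_min, None))
        p2 = p1 + span
        if p2 >= anc.chrom_sizes[chrom]:
            continue
        d2 = next((d for d in anc.domains
                   if d.chrom == chrom and d.start < p2 < d.end), None)
        if d2 is not None:
            if d2.used or d2.id == (d1.id if d1 else -1):
                continue
            m = sampler._domain_margin(d2)
            if not (d2.start + m <= p2 < d2.end - m):
                continue
        else:
            in_gap = any(c == chrom and s + sampler.gap_margin <= p2 < e - sampler.gap_margin
                         for c, s, e, _ in anc.gap_states)
            if not in_gap or p.restrict_breakpoints_to_domains:
                continue
        # breakpoint acceptance depends on chromatin state at BOTH cut
        # points: the second cut passes a weight-proportional rejection step
        w2 = p.breakpoint_state_weights.get(_state_at(anc, chrom, p2), 0.0)
        wmax = max(p.breakpoint_state_weights.values())
        if wmax <= 0 or rng.random() >= w2 / wmax:
            continue
        if not sampler._free(chrom, p1, p2):
            continue
        sampler.reserve(chrom, p1, p2)
        if d1:
            d1.used = True
        if d2:
            d2.used = True
        builder.invert(chrom, p1, p2)
        junction(chrom, p1, "inversion", d1 is not None, d1)
        junction(chrom, p2, "inversion", d2 is not None, d2)
        placed += 1

    # -- intra-chromosomal translocations
    placed = 0
    tries = 0
    while placed < p.n_translocations:
        tries += 1
        if tries > 200 * max(p.n_translocations, 1):
            raise ConfigurationError("could not place requested translocations")
        csize = int(rng.integers(p.translocation_chunk_min, p.translocation_chunk_max + 1))
        chrom, p1, d1 = sampler.sample_fitting_interval(csize)
        p2 = p1 + csize
        qchrom, q, d2 = sampler.sample_point()
        if qchrom != chrom:
            continue
        if abs(q - p1) < 2 * p.event_margin + csize or (p1 <= q < p2):
            continue
        sampler.reserve(chrom, p1, p2)
        sampler.reserve(chrom, q, q + 1)
        if d1:
            d1.used = True
        if d2:
            d2.used = True
        orient = "+" if rng.random() < 0.5 else "-"
        builder.translocate(chrom, p1, p2, q, orient)
        junction(chrom, p1, "translocation_cut", d1 is not None, d1)
        junction(chrom, p2, "translocation_cut", d1 is not None, d1)
        junction(chrom, q, "translocation_insert", d2 is not None, d2)
        placed += 1

    # -- large indels (applied to lineage B)
    placed = 0
    tries = 0
    while placed < p.n_indels:
        tries += 1
        if tries > 200 * max(p.n_indels, 1):
            raise ConfigurationError("could not place requested indels")
        size = int(np.clip(rng.normal(p.indel_size_mean, p.indel_size_sd),
                           p.indel_size_min, None))
        if rng.random() < 0.5:  # insertion
            chrom, pos, d = sampler.sample_point()
            sampler.reserve(chrom, pos, pos + 1)
            if d:
                d.used = True
            builder.insert(chrom, pos, size)
            # an insertion splits the image only when its size reaches the
            # domain merge gap; sizes are constrained >= event_margin (20 kb)
            junction(chrom, pos, "insertion", d is not None and size >= p.event_margin, d)
        else:  # deletion: both sides shrink together, image stays contiguous
            chrom, pos, d = sampler.sample_fitting_interval(size)
            sampler.reserve(chrom, pos, pos + size)
            if d:
                d.used = True
            builder.delete(chrom, pos, pos + size)
            junction(chrom, pos, "deletion", False, d)
        placed += 1

    # -- boundary losses (either lineage may lose; flanks must be event-free
    # and of comparable length so the merged call fails reciprocal overlap)
    losses_a: set[int] = set()
    losses_b: set[int] = set()

    def loss_eligible(b: Boundary) -> bool:
        if not b.internal:
            return False
        dl, dr = anc.domains[b.left_domain], anc.domains[b.right_domain]
        if dl.used or dr.used:
            return False
        lo, hi = sorted((dl.length, dr.length))
        return lo + p.boundary_width >= 0.15 * hi

    def commit_loss(b: Boundary, species: str) -> None:
        (losses_a if species == "A" else losses_b).add(b.id)
        anc.domains[b.left_domain].used = True
        anc.domains[b.right_domain].used = True

    if p.n_boundary_losses is not None:
        cands = [b for b in anc.boundaries if loss_eligible(b)]
        if len(cands) < p.n_boundary_losses:
            raise ConfigurationError("not enough eligible boundaries for losses")
        idx = rng.choice(len(cands), size=p.n_boundary_losses, replace=False)
        for i in sorted(int(j) for j in idx):
            commit_loss(cands[i], "A" if rng.random() < 0.5 else "B")
    else:
        for b in anc.boundaries:
            if not loss_eligible(b):
                continue
            ra, rb = rng.random(), rng.random()
            if ra < p.p_boundary_loss:
                losses_a.add(b.id)
            if rb < p.p_boundary_loss:
                losses_b.add(b.id)
            if ra < p.p_boundary_loss or rb < p.p_boundary_loss:
                anc.domains[b.left_domain].used = True
                anc.domains[b.right_domain].used = True

    # -- boundary gains (position sampled in ancestral coordinates)
    gains_a: list[tuple[str, int, int]] = []  # chrom, center, domain id
    gains_b: list[tuple[str, int, int]] = []

    def gain_margin(d: Domain) -> int:
        return max(sampler._domain_margin(d), p.boundary_width)

    def commit_gain(d: Domain, species: str) -> None:
        m = gain_margin(d)
        g = int(rng.integers(d.start + m, d.end - m))
        (gains_a if species == "A" else gains_b).append((d.chrom, g, d.id))
        d.used = True

    if p.n_boundary_gains is not None:
        cands = [d for d in anc.domains
                 if not d.used and d.length > 2 * gain_margin(d)]
        if len(cands) < p.n_boundary_gains:
            raise ConfigurationError("not enough eligible domains for gains")
        idx = rng.choice(len(cands), size=p.n_boundary_gains, replace=False)
        for i in sorted(int(j) for j in idx):
            commit_gain(cands[i], "A" if rng.random() < 0.5 else "B")
    else:
        for d in anc.domains:
            if d.used or d.length <= 2 * gain_margin(d):
                continue
            ra, rb = rng.random(), rng.random()
            if ra < p.p_boundary_gain:
                commit_gain(d, "A")
            elif rb < p.p_boundary_gain:
                commit_gain(d, "B")

    full_chain, b_sizes = builder.build_chain(anc.chrom_sizes)

    # -- unalignable regions: alignment holes centred on sampled features,
    # padded into the flanks so that jittered replicate calls still fail to
    # lift.  Eligibility (event-free, sufficiently long flanking domains,
    # one hole per domain) keeps every other feature's truth unchanged.
    pad = p.unalignable_pad
    missing_bids: set[int] = set()
    missing_dids: set[int] = set()
    hole_adjacent: set[int] = set()
    for b in anc.boundaries:
        if b.id in losses_a or b.id in losses_b:
            continue
        flanks = [anc.domains[i] for i in (b.left_domain, b.right_domain)
                  if i is not None]
        if any(d.used or d.id in hole_adjacent or d.length < 12 * pad
               for d in flanks):
            continue
        if rng.random() < p.p_missing_boundary:
            missing_bids.add(b.id)
            hole_adjacent.update(d.id for d in flanks)
    for d in anc.domains:
        if d.used or d.id in hole_adjacent:
            continue
        if rng.random() < p.p_missing_domain:
            missing_dids.add(d.id)
            d.used = True
            hole_adjacent.add(d.id)
            for b in anc.boundaries:
                if b.left_domain == d.id or b.right_domain == d.id:
                    hole_adjacent.update(
                        i for i in (b.left_domain, b.right_domain) if i is not None)
    holes: list[GenomicInterval] = []
    for bid in sorted(missing_bids):
        b = anc.boundaries[bid]
        holes.append(GenomicInterval(b.chrom, max(0, b.start - pad),
                                     min(anc.chrom_sizes[b.chrom], b.end + pad)))
    for did in sorted(missing_dids):
        d = anc.domains[did]
        holes.append(GenomicInterval(d.chrom, max(0, d.start - pad),
                                     min(anc.chrom_sizes[d.chrom], d.end + pad)))
    chain = _punch_holes(full_chain, holes) if holes else full_chain

    # -- per-species structures (ancestral coordinates first)
    struct_a = _species_structure(anc, losses_a, gains_a)
    struct_b = _species_structure(anc, losses_b, gains_b)

    species_a = _emit_species("A", anc, struct_a, None, rng, p)
    species_b = _emit_species("B", anc, struct_b, full_chain, rng, p,
                              b_sizes=b_sizes, builder=builder)

    truth = _build_truth(anc, junctions, struct_a, struct_b,
                         losses_a, losses_b, gains_a, gains_b,
                         species_b_domains=species_b.domains, chain=chain,
                         missing_bids=missing_bids, missing_dids=missing_dids)

    genes = _plant_expression(anc, junctions, gains_a, gains_b, rng, truth)

    synteny = derive_synteny_blocks(chain, p.synteny_join_gap)

    # polymorphic comparator breakpoints: uniform over the genome (neutral)
    poly: list[tuple[str, int]] = []
    chroms = list(anc.chrom_sizes)
    lens = np.array([anc.chrom_sizes[c] for c in chroms], dtype=float)
    for _ in range(p.n_polymorphic_breakpoints):
        c = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
        poly.append((c, int(rng.integers(0, anc.chrom_sizes[c]))))

    # insulation: pre-insulated ancestral sites are the positions where
    # junctions and novel boundaries arose
    pre_sites = [(j.chrom, j.pos) for j in junctions]
    pre_sites += [(c, g) for c, g, _ in gains_b]  # orthologs of B-specific boundaries
    signal_a = _insulation_track(
        anc.chrom_sizes, list(species_a.boundaries), pre_sites, p, rng)
    pre_sites_b = []
    for c, pos in [(j.chrom, j.pos) for j in junctions] + [(c, g) for c, g, _ in gains_a]:
        img = _map_point_via(full_chain, c, pos)
        if img is not None:
            pre_sites_b.append(img)
    signal_b = _insulation_track(
        species_b.chrom_sizes, list(species_b.boundaries), pre_sites_b, p, rng)
    for sp, signal in ((species_a, signal_a), (species_b, signal_b)):
        for rep in (1, 2):
            t = signal.copy()
            t["score"] = t["score"] + rng.normal(
                0.0, p.replicate_track_noise_sd, len(t))
            sp.insulation[rep] = t

    # sequence
    if p.with_sequence:
        _attach_sequences(anc, species_a, species_b, builder,
                          gains_a, rng, truth)

    pair = SimulatedPair(anc, species_a, species_b, chain, synteny, genes,
                         anc.state_segments(), truth, poly, p)
    return pair


def _map_point_via(chain: OrthologyMap, chrom: str, pos: int):
    return map_position(chain, chrom, pos)


def simulate_pair(params: EvolutionParams, seed: int = 0) -> SimulatedPair:
    """Convenience wrapper: ancestor plus evolved pair from a single seed."""
    anc = generate_ancestor(params, seed)
    return evolve_pair(anc, seed + 1)


@dataclass
class _SpeciesStructure:
    """Call structure in ancestral coordinates, before coordinate mapping."""

    boundaries: list[tuple[str, int, int, str]]  # chrom,start,end,name
    domains: list[tuple[str, int, int, str]]
    # provenance flags keyed by call name
    gain_half: set = field(default_factory=set)     # domain halves created by own gain
    merged_by_loss: dict = field(default_factory=dict)  # name -> lost boundary id
    source_domain: dict = field(default_factory=dict)   # name -> ancestral domain id(s)


def _species_structure(anc: Ancestor, losses: set[int],
                       gains: list[tuple[str, int, int]]) -> _SpeciesStructure:
    bw = anc.params.boundary_width
    st = _SpeciesStructure([], [])
    gain_by_domain: dict[int, int] = {did: g for _, g, did in gains}

    # boundaries: ancestral minus losses, plus own gains
    for b in anc.boundaries:
        if b.id in losses:
            continue
        st.boundaries.append((b.chrom, b.start, b.end, f"b{b.id:04d}"))
    for c, g, did in gains:
        st.boundaries.append((c, g - bw // 2, g + bw // 2, f"bg{did:04d}"))
    st.boundaries.sort(key=lambda t: (t[0], t[1]))

    # domains: merge across lost boundaries, split at own gains
    i = 0
    doms = anc.domains
    while i < len(doms):
        d = doms[i]
        # extend across consecutive lost boundaries
        j = i
        end = d.end
        members = [d.id]
        while True:
            nb = next((b for b in anc.boundaries
                       if b.left_domain == doms[j].id and b.internal), None)
            if nb is not None and nb.id in losses:
                j += 1
                end = doms[j].end
                members.append(doms[j].id)
            else:
                break
        if len(members) > 1:
            name = "d" + "_".join(f"{m:04d}" for m in members)
            st.domains.append((d.chrom, d.start, end, name))
            st.merged_by_loss[name] = members
            st.source_domain[name] = members
        elif d.id in gain_by_domain:
            g = gain_by_domain[d.id]
            n1, n2 = f"d{d.id:04d}L", f"d{d.id:04d}R"
            st.domains.append((d.chrom, d.start, g - bw // 2, n1))
            st.domains.append((d.chrom, g + bw // 2, d.end, n2))
            st.gain_half.update((n1, n2))
            st.source_domain[n1] = [d.id]
            st.source_domain[n2] = [d.id]
        else:
            name = f"d{d.id:04d}"
            st.domains.append((d.chrom, d.start, d.end, name))
            st.source_domain[name] = [d.id]
        i = j + 1
    st.domains.sort(key=lambda t: (t[0], t[1]))
    return st


def _emit_species(name: str, anc: Ancestor, struct: _SpeciesStructure,
                  chain: Optional[OrthologyMap], rng: np.random.Generator,
                  p: EvolutionParams, b_sizes: Optional[ChromSizes] = None,
                  builder=None) -> SpeciesCalls:
    """Materialise a species' true call sets in its own coordinates and
    derive the two noisy replicate call sets."""
    if chain is None:  # species A lives in ancestral coordinates
        sizes = ChromSizes(anc.chrom_sizes)
        bints = [GenomicInterval(c, s, e) for c, s, e, _ in struct.boundaries]
        bnames = [n for *_, n in struct.boundaries]
        dints = [GenomicInterval(c, s, e) for c, s, e, _ in struct.domains]
        dnames = [n for *_, n in struct.domains]
    else:
        sizes = ChromSizes(b_sizes)
        bints, bnames, dints, dnames = [], [], [], []
        for c, s, e, n in struct.boundaries:
            pieces = _map_interval_pieces(chain, GenomicInterval(c, s, e))
            if pieces:
                big = max(pieces, key=len)
                bints.append(big)
                bnames.append(n)
        for c, s, e, n in struct.domains:
            pieces = _map_interval_pieces(chain, GenomicInterval(c, s, e))
            pieces = [iv for iv in pieces if len(iv) >= 5_000]
            if len(pieces) == 1:
                dints.append(pieces[0])
                dnames.append(n)
            else:
                for k, iv in enumerate(sorted(pieces, key=lambda v: (v.chrom, v.start))):
                    dints.append(iv)
                    dnames.append(f"{n}.p{k}")

    sp = SpeciesCalls(
        name, sizes,
        FeatureSet(f"{name}_boundaries", bints, bnames),
        FeatureSet(f"{name}_domains", dints, dnames),
    )
    for rep in (1, 2):
        sp.replicate_boundaries[rep] = _noisy_replicate(sp.boundaries, sizes, rng, p)
        sp.replicate_domains[rep] = _noisy_replicate(sp.domains, sizes, rng, p)
    return sp


def _map_interval_pieces(chain: OrthologyMap, iv: GenomicInterval) -> list[GenomicInterval]:
    """Contiguous images of an ancestral interval in B coordinates (abutting
    alignment segments are fused)."""
    lifted = lift_interval(chain, iv)
    if not lifted.raw_segments:
        return []
    fs = FeatureSet("x", [GenomicInterval(s.chrom, s.start, s.end)
                          for s in lifted.raw_segments])
    return list(merge_intervals(fs, 1))


def _noisy_replicate(calls: FeatureSet, sizes: ChromSizes,
                     rng: np.random.Generator, p: EvolutionParams) -> FeatureSet:
    ints, names = [], []
    for iv, n in zip(calls.intervals, calls.feature_names()):
        if rng.random() < p.p_replicate_drop:
            continue
        if p.jitter_sd > 0:
            delta = int(np.clip(round(rng.normal(0.0, p.jitter_sd)),
                                -p.jitter_max, p.jitter_max))
        else:
            delta = 0
        s = max(0, iv.start + delta)
        e = min(sizes[iv.chrom], iv.end + delta)
        if s < e:
            ints.append(GenomicInterval(iv.chrom, s, e))
            names.append(n)
    return FeatureSet(calls.name, ints, names)


# -- truth -------------------------------------------------------------------


def _punch_holes(m: OrthologyMap, holes: list[GenomicInterval]) -> OrthologyMap:
    """Remove the given source-coordinate intervals from the alignment,
    splitting blocks as needed (an 'unalignable sequence' model: the target
    genome keeps the material, only the alignment loses it)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for h in holes:
        by_chrom.setdefault(h.chrom, []).append((h.start, h.end))
    new_blocks: list[AlignmentBlock] = []
    for blk in m.blocks:
        pieces = [(blk.src.start, blk.src.end)]
        for hs, he in by_chrom.get(blk.src.chrom, ()):
            nxt = []
            for s, e in pieces:
                if he <= s or e <= hs:
                    nxt.append((s, e))
                    continue
                if s < hs:
                    nxt.append((s, hs))
                if he < e:
                    nxt.append((he, e))
            pieces = nxt
        for s, e in pieces:
            if blk.orientation == "+":
                t0 = blk.tgt.start + (s - blk.src.start)
            else:
                t0 = blk.tgt.start + (blk.src.end - e)
            new_blocks.append(AlignmentBlock(
                GenomicInterval(blk.src.chrom, s, e),
                GenomicInterval(blk.tgt.chrom, t0, t0 + (e - s)),
                blk.orientation,
            ))
    return OrthologyMap(new_blocks, ChromSizes(m.src_sizes), ChromSizes(m.tgt_sizes))


def _preimage_split(chain: OrthologyMap, piece: GenomicInterval,
                    gap_thresh: int = 20_000) -> bool:
    """Does the ancestral preimage of a B interval carry an internal hole of
    ``gap_thresh`` bp or more (material deleted from B or moved elsewhere)?

    Computed from the generator's own alignment blocks: a B-contiguous call
    whose preimage is interrupted lifts back to discontiguous regions.
    """
    subs: list[tuple[str, int, int]] = []
    for b in chain.blocks:
        if b.tgt.chrom != piece.chrom:
            continue
        a = max(piece.start, b.tgt.start)
        z = min(piece.end, b.tgt.end)
        if a >= z:
            continue
        if b.orientation == "+":
            subs.append((b.src.chrom, b.src.start + (a - b.tgt.start),
                         b.src.start + (z - b.tgt.start)))
        else:
            subs.append((b.src.chrom, b.src.start + (b.tgt.end - z),
                         b.src.start + (b.tgt.end - a)))
    subs.sort()
    for (c1, _s1, e1), (c2, s2, _e2) in zip(subs, subs[1:]):
        if c1 != c2 or s2 - e1 >= gap_thresh:
            return True
    return False


def _build_truth(anc, junctions, struct_a, struct_b,
                 losses_a, losses_b, gains_a, gains_b,
                 species_b_domains: FeatureSet, chain: OrthologyMap,
                 missing_bids: set[int] = frozenset(),
                 missing_dids: set[int] = frozenset()) -> TruthSet:
    truth = TruthSet(junctions=junctions,
                     gains=[("A", c, g, d) for c, g, d in gains_a]
                     + [("B", c, g, d) for c, g, d in gains_b],
                     losses=[("A", b) for b in sorted(losses_a)]
                     + [("B", b) for b in sorted(losses_b)])
    missing_dnames = {f"d{did:04d}" for did in missing_dids}
    missing_bnames = {f"b{bid:04d}" for bid in missing_bids}

    truth.domain_category_ab = _domain_truth(anc, struct_a, junctions,
                                             losses_a, losses_b, gains_b)
    cat_ba = _domain_truth(anc, struct_b, junctions,
                           losses_b, losses_a, gains_a)
    for nm in missing_dnames:
        if nm in truth.domain_category_ab:
            truth.domain_category_ab[nm] = "missing"
        if nm in cat_ba:
            cat_ba[nm] = "missing"
    # Reverse direction operates on B's emitted calls.  A call whose
    # ancestral preimage is interrupted (deleted or translocated-away
    # material of at least the domain merge gap) lifts back to multiple
    # regions -> split_by_rearrangement.  Pieces of forward-split domains
    # with contiguous preimages lift back into part of their ancestral
    # domain -> truncated_expanded.  Intact contiguous calls follow the
    # boundary gain/loss rules.
    truth.domain_category_ba = {}
    for iv, nm in zip(species_b_domains.intervals,
                      species_b_domains.feature_names()):
        if nm in missing_dnames:
            truth.domain_category_ba[nm] = "missing"
        elif _preimage_split(chain, iv):
            truth.domain_category_ba[nm] = "split_by_rearrangement"
        elif nm in cat_ba:
            truth.domain_category_ba[nm] = cat_ba[nm]
        else:
            truth.domain_category_ba[nm] = "truncated_expanded"
    truth.boundary_status_a = _boundary_truth(anc, struct_a, losses_a, losses_b)
    truth.boundary_status_b = _boundary_truth(anc, struct_b, losses_b, losses_a)
    for nm in missing_bnames:
        if nm in truth.boundary_status_a:
            truth.boundary_status_a[nm] = "missing"
        if nm in truth.boundary_status_b:
            truth.boundary_status_b[nm] = "missing"
    return truth


def _domain_truth(anc, own: _SpeciesStructure,
                  junctions, own_losses, other_losses, other_gains) -> dict:
    """True conservation category of each of the focal species' domain calls
    against the other species, from the planted events alone.

    Precedence mirrors the classifier's decision order: a splitting
    junction strictly inside the call wins, then a boundary present only in
    the other species strictly inside it, then size asymmetry created by
    the call's own gain-split or by a merge on the other side; everything
    else is orthologous.
    """
    cats: dict[str, str] = {}
    other_specific_anc = [b for b in anc.boundaries
                          if b.id in own_losses and b.id not in other_losses]
    other_gain_pos = [(c, g) for c, g, _ in other_gains]

    for chrom, start, end, name in own.domains:
        cat = None
        for j in junctions:
            if j.splits and j.chrom == chrom and start < j.pos < end:
                cat = "split_by_rearrangement"
                break
        if cat is None:
            for b in other_specific_anc:
                if b.chrom == chrom and start < b.center < end:
                    cat = "split_by_boundary"
                    break
        if cat is None:
            for c, g in other_gain_pos:
                if c == chrom and start < g < end:
                    cat = "split_by_boundary"
                    break
        if cat is None:
            if name in own.gain_half:
                cat = "truncated_expanded"
            else:
                src = own.source_domain.get(name, [])
                merged_other = any(
                    b.id in other_losses and b.id not in own_losses
                    and (b.left_domain in src or b.right_domain in src)
                    for b in anc.boundaries if b.internal
                )
                if merged_other:
                    cat = "truncated_expanded"
        cats[name] = cat or "orthologous"
    return cats


def _boundary_truth(anc, own: _SpeciesStructure, own_losses, other_losses) -> dict:
    status: dict[str, str] = {}
    for chrom, start, end, name in own.boundaries:
        if name.startswith("bg"):
            status[name] = "lineage_specific"
        else:
            bid = int(name[1:])
            status[name] = ("lineage_specific" if bid in other_losses
                            else "orthologous")
    return status


# -- expression --------------------------------------------------------------


def _plant_expression(anc, junctions, gains_a, gains_b,
                      rng: np.random.Generator, truth: TruthSet) -> pd.DataFrame:
    p = anc.params
    genes = anc.genes.copy()
    sites: dict[str, list[int]] = {}
    for j in junctions:
        sites.setdefault(j.chrom, []).append(j.pos)
    for c, g, _ in gains_a + gains_b:
        sites.setdefault(c, []).append(g)
    near = np.zeros(len(genes), dtype=bool)
    for chrom, pos_list in sites.items():
        arr = np.sort(np.array(pos_list))
        sel = (genes["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = genes.loc[sel, "start"].to_numpy()
        ends = genes.loc[sel, "end"].to_numpy()
        # a site pos counts when start - window < pos < end + window
        lo = np.searchsorted(arr, starts - p.de_window, side="right")
        hi = np.searchsorted(arr, ends + p.de_window - 1, side="right")
        near[sel] = hi > lo
    p_near = min(1.0, p.p_de_background * p.de_near_factor)
    u = rng.random(len(genes))
    de = np.where(near, u < p_near, u < p.p_de_background)
    direction = np.where(de, np.where(rng.random(len(genes)) < 0.5, "up", "down"), "none")
    lfc = np.where(de, rng.normal(p.de_log2fc_mean, p.de_log2fc_sd, len(genes)), 0.0)
    lfc = np.where(direction == "down", -np.abs(lfc), np.abs(lfc))
    genes["near_disruption"] = near
    genes["de_flag"] = de
    genes["direction"] = direction
    genes["log2fc"] = lfc
    truth.de_gene_ids = list(genes.loc[genes["de_flag"], "id"])
    return genes


# -- sequences ---------------------------------------------------------------


def _attach_sequences(anc, species_a, species_b, builder,
                      gains_a, rng, truth) -> None:
    p = anc.params
    if anc.sequence is None:
        anc.sequence = _ancestral_sequence(anc, rng)
    seq_a = {c: s.copy() for c, s in anc.sequence.items()}
    counts_a: dict[str, int] = {}
    for c, g, did in gains_a:
        iv = (g - p.boundary_width // 2, g + p.boundary_width // 2)
        counts_a[f"bg{did:04d}"] = _plant_motifs(seq_a[c], iv[0], iv[1], p, rng)
    species_a.sequence = seq_a

    seq_b = {}
    for chrom, segs in builder.chroms.items():
        parts = []
        for s in segs:
            if s.anc_chrom is None:
                parts.append(BASES[rng.integers(0, 4, size=s.length)])
            else:
                piece = anc.sequence[s.anc_chrom][s.start:s.end]
                parts.append(_revcomp(piece) if s.orient == "-" else piece)
        seq_b[chrom] = np.concatenate(parts) if parts else np.array([], dtype=np.uint8)
    counts_b: dict[str, int] = {}
    for iv, name in zip(species_b.boundaries.intervals,
                        species_b.boundaries.feature_names()):
        if name.startswith("bg"):
            counts_b[name] = _plant_motifs(seq_b[iv.chrom], iv.start, iv.end, p, rng)
    species_b.sequence = seq_b
    truth.planted_motifs = {"A": counts_a, "B": counts_b}


# -- synteny -----------------------------------------------------------------


def derive_synteny_blocks(chain: OrthologyMap, join_gap: int) -> list[SyntenyBlock]:
    """Join co-linear, same-orientation adjacent chain blocks (gaps below
    ``join_gap`` on both genomes) into maximal synteny blocks.

    Block lengths may differ between the genomes across small indels, so
    synteny blocks are coordinate hulls, not alignments.
    """
    blocks = sorted(chain.blocks, key=lambda b: (b.src.chrom, b.src.start))
    out: list[SyntenyBlock] = []
    for b in blocks:
        if out:
            prev = out[-1]
            ok = (prev.src.chrom == b.src.chrom and prev.tgt.chrom == b.tgt.chrom
                  and prev.orientation == b.orientation
                  and 0 <= b.src.start - prev.src.end < join_gap)
            if ok:
                if b.orientation == "+":
                    ok = 0 <= b.tgt.start - prev.tgt.end < join_gap
                else:
                    ok = 0 <= prev.tgt.start - b.tgt.end < join_gap
            if ok:
                out[-1] = SyntenyBlock(
                    GenomicInterval(prev.src.chrom, prev.src.start, b.src.end),
                    GenomicInterval(prev.tgt.chrom,
                                    min(prev.tgt.start, b.tgt.start),
                                    max(prev.tgt.end, b.tgt.end)),
                    b.orientation,
                )
                continue
        out.append(SyntenyBlock(b.src, b.tgt, b.orientation))
    return out


# -- dataset I/O -------------------------------------------------------------


def write_dataset(pair: SimulatedPair, directory: str | Path, seed: int) -> dict:
    """Write every artefact of the simulated pair; returns the manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "params": asdict(pair.params), "files": {}}

    def rec(key: str, path: Path):
        manifest["files"][key] = path.name

    pair.ancestor.chrom_sizes.write_tsv(d / "ancestor.chrom.sizes")
    rec("ancestor_chrom_sizes", d / "ancestor.chrom.sizes")
    for sp in (pair.species_a, pair.species_b):
        tag = sp.name
        sp.chrom_sizes.write_tsv(d / f"{tag}.chrom.sizes")
        rec(f"{tag}_chrom_sizes", d / f"{tag}.chrom.sizes")
        sp.boundaries.write_bed(d / f"{tag}.boundaries.bed")
        rec(f"{tag}_boundaries", d / f"{tag}.boundaries.bed")
        sp.domains.write_bed(d / f"{tag}.domains.bed")
        rec(f"{tag}_domains", d / f"{tag}.domains.bed")
        for rep in (1, 2):
            sp.replicate_boundaries[rep].write_bed(d / f"{tag}.boundaries.rep{rep}.bed")
            rec(f"{tag}_boundaries_rep{rep}", d / f"{tag}.boundaries.rep{rep}.bed")
            sp.replicate_domains[rep].write_bed(d / f"{tag}.domains.rep{rep}.bed")
            rec(f"{tag}_domains_rep{rep}", d / f"{tag}.domains.rep{rep}.bed")
            sp.insulation[rep].to_csv(d / f"{tag}.insulation.rep{rep}.bedgraph",
                                      sep="\t", header=False, index=False)
            rec(f"{tag}_insulation_rep{rep}", d / f"{tag}.insulation.rep{rep}.bedgraph")
        if sp.sequence is not None:
            with open(d / f"{tag}.fa", "w") as fh:
                for chrom, arr in sp.sequence.items():
                    fh.write(f">{chrom}\n")
                    s = arr.tobytes().decode()
                    for i in range(0, len(s), 80):
                        fh.write(s[i : i + 80] + "\n")
            rec(f"{tag}_fasta", d / f"{tag}.fa")

    write_chain(pair.chain, d / "A_to_B.chain")
    rec("chain", d / "A_to_B.chain")

    with open(d / "synteny.tsv", "w") as fh:
        fh.write("srcChrom\tsrcStart\tsrcEnd\ttgtChrom\ttgtStart\ttgtEnd\torientation\n")
        for b in pair.synteny:
            fh.write(f"{b.src.chrom}\t{b.src.start}\t{b.src.end}\t"
                     f"{b.tgt.chrom}\t{b.tgt.start}\t{b.tgt.end}\t{b.orientation}\n")
    rec("synteny", d / "synteny.tsv")

    gb = pair.genes[["chrom", "start", "end", "id"]]
    gb.to_csv(d / "genes.bed", sep="\t", header=False, index=False)
    rec("genes_bed", d / "genes.bed")
    pair.genes.to_csv(d / "genes.tsv", sep="\t", index=False)
    rec("genes_tsv", d / "genes.tsv")

    seg = pair.state_segments
    with open(d / "chromatin_states.bed", "w") as fh:
        for iv, st in zip(seg.intervals, seg.attrs["state"]):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{st}\n")
    rec("chromatin_states", d / "chromatin_states.bed")

    with open(d / "polymorphic_breakpoints.bed", "w") as fh:
        for c, pos in pair.polymorphic_breakpoints:
            fh.write(f"{c}\t{pos}\t{pos + 1}\tpoly\n")
    rec("polymorphic_breakpoints", d / "polymorphic_breakpoints.bed")

    pair.truth.to_json(d / "truth.json")
    rec("truth", d / "truth.json")
    with open(d / "params.yaml", "w") as fh:
        yaml.safe_dump(asdict(pair.params), fh)
    rec("params", d / "params.yaml")
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_dataset(directory: str | Path) -> dict:
    """Read back the key frames of a written dataset (for round-trip checks
    and for running the pipeline from files)."""
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    out = {"manifest": manifest}
    out["chain"] = read_chain(d / "A_to_B.chain")
    out["synteny"] = pd.read_csv(d / "synteny.tsv", sep="\t")
    out["genes"] = pd.read_csv(d / "genes.tsv", sep="\t")
    out["truth"] = TruthSet.from_json(d / "truth.json")
    for tag in ("A", "B"):
        out[f"{tag}_boundaries"] = FeatureSet.read_bed(d / f"{tag}.boundaries.bed")
        out[f"{tag}_domains"] = FeatureSet.read_bed(d / f"{tag}.domains.bed")
        for rep in (1, 2):
            out[f"{tag}_boundaries_rep{rep}"] = FeatureSet.read_bed(
                d / f"{tag}.boundaries.rep{rep}.bed")
            out[f"{tag}_domains_rep{rep}"] = FeatureSet.read_bed(
                d / f"{tag}.domains.rep{rep}.bed")
            out[f"{tag}_insulation_rep{rep}"] = pd.read_csv(
                d / f"{tag}.insulation.rep{rep}.bedgraph", sep="\t",
                names=["chrom", "start", "end", "score"])
    out["states"] = pd.read_csv(d / "chromatin_states.bed", sep="\t",
                                names=["chrom", "start", "end", "state"])
    return out
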