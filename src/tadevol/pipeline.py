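"""End-to-end orchestration: simulate -> lift -> classify -> enrich -> report.

The pipeline reproduces the comparative-analysis sequence of a
two-species TAD conservation study: replicate consensus calling, liftover
of high-confidence boundaries and domains, conservation classification
(with the reverse direction optionally included), co-linearity against
synteny blocks with shuffle-based expectations, breakpoint derivation,
expression/chromatin/insulation/motif enrichment statistics, and a
Table-1-style conservation report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import insulation as ins
from . import motifs as mo
from . import stats as st
from .chain import OrthologyMap, invert_map, lift_and_merge
from .core import ConfigurationError, FeatureSet, GenomicInterval
from .simulate import (
    EvolutionParams,
    SimulatedPair,
    simulate_pair,
)


@dataclass
class PipelineConfig:
    """Thresholds and run options for the full pipeline.

    All thresholds are in bp and mirror the published analysis: 5 kb
    boundary-orthology distance, 5 kb / 500 bp boundary liftover merge and
    minimum size, 20 kb / 5 kb for domains, 90% reciprocal overlap, 10 kb
    DE window, 5 kb intra-TAD breakpoint distance, 100 co-linearity
    shuffles and 1000 proximity permutations.
    """

    dist_thresh: int = 5_000
    merge_gap_boundary: int = 5_000
    min_size_boundary: int = 500
    merge_gap_domain: int = 20_000
    min_size_domain: int = 5_000
    overlap_frac: float = 0.90
    de_window: int = 10_000
    bt_dist: int = 5_000
    n_shuffles: int = 100
    n_perm: int = 1_000
    direction: str = "A->B"  # "A->B" | "B->A" | "both"
    seed: int = 0
    sim_params: EvolutionParams = field(default_factory=EvolutionParams)

    def validate(self) -> None:
        for name in ("dist_thresh", "merge_gap_boundary", "min_size_boundary",
                     "merge_gap_domain", "min_size_domain", "de_window",
                     "bt_dist", "n_shuffles", "n_perm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.direction not in ("A->B", "B->A", "both"):
            raise ConfigurationError(f"invalid direction {self.direction!r}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.pop("sim_params", None)
        cfg = cls(**d)
        if sim:
            cfg.sim_params = EvolutionParams(**sim)
        return cfg


# ---------------------------------------------------------------------------
# building blocks


def consensus_calls(species) -> dict[str, FeatureSet]:
    """High/low-confidence boundary and domain sets from the two replicates."""
    bh, bl = cl.replicate_consensus(species.replicate_boundaries[1],
                                    species.replicate_boundaries[2], "boundary")
    dh, dl = cl.replicate_consensus(species.replicate_domains[1],
                                    species.replicate_domains[2], "domain")
    all_b = FeatureSet("boundaries_all", bh.intervals + bl.intervals,
                       bh.feature_names() + bl.feature_names())
    all_d = FeatureSet("domains_all", dh.intervals + dl.intervals,
                       dh.feature_names() + dl.feature_names())
    return {"boundaries_high": bh, "boundaries_low": bl, "boundaries_all": all_b,
            "domains_high": dh, "domains_low": dl, "domains_all": all_d}


def lineage_specific_boundaries(
    src_high: FeatureSet, omap: OrthologyMap, other_all_boundaries: FeatureSet,
    cfg: PipelineConfig,
) -> FeatureSet:
    """High-confidence boundaries of one species whose orthologous sequence
    in the other species carries no boundary call of any confidence.
    Returned in the focal species' own coordinates."""
    statuses = cl.classify_boundaries(
        src_high, omap, other_all_boundaries, cfg.dist_thresh,
        cfg.merge_gap_boundary, cfg.min_size_boundary)
    keep = {s.name for s in statuses if s.status == "lineage_specific"}
    ivs, names = [], []
    for iv, nm in zip(src_high.intervals, src_high.feature_names()):
        if nm in keep:
            ivs.append(iv)
            names.append(nm)
    return FeatureSet(f"{src_high.name}_lineage_specific", ivs, names)


def _orthologous_target_boundaries(
    statuses, tgt_boundaries: FeatureSet, dist_thresh: int
) -> FeatureSet:
    """Target boundaries lying within the orthology distance of a lifted
    source boundary classified orthologous (used for the shared-boundary
    flag of orthologous domains)."""
    regions = []
    for s in statuses:
        if s.status == "orthologous" and s.regions:
            regions.extend(s.regions)
    idx = cl._NearestIndex(regions)
    ivs, names = [], []
    for iv, nm in zip(tgt_boundaries.intervals, tgt_boundaries.feature_names()):
        gap = idx.nearest_gap(iv)
        if gap is not None and gap < dist_thresh:
            ivs.append(iv)
            names.append(nm)
    return FeatureSet("tgt_orthologous_boundaries", ivs, names)


def classify_direction(
    src_calls: dict, tgt_calls: dict, omap: OrthologyMap,
    tgt_lineage: FeatureSet, cfg: PipelineConfig,
) -> dict:
    """Full boundary+domain classification for one liftover direction."""
    statuses = cl.classify_boundaries(
        src_calls["boundaries_high"], omap, tgt_calls["boundaries_all"],
        cfg.dist_thresh, cfg.merge_gap_boundary, cfg.min_size_boundary)
    share = _orthologous_target_boundaries(statuses, tgt_calls["boundaries_all"],
                                           cfg.dist_thresh)
    cats = cl.classify_domains(
        src_calls["domains_high"], omap, tgt_calls["domains_all"], tgt_lineage,
        cfg.overlap_frac, cfg.merge_gap_domain, cfg.min_size_domain,
        cfg.dist_thresh, share)
    n_shared = sum(1 for c in cats if c.category == "orthologous" and c.shared_boundaries)
    table1 = cl.build_table1(cl.count_statuses(statuses), cl.count_categories(cats),
                             n_shared)
    return {"boundary_statuses": statuses, "domain_categories": cats,
            "table1": table1}


def compare_by_chromosome_class(
    synteny_blocks, domain_categories, domain_features: FeatureSet,
    class_map: dict[str, str],
) -> dict:
    """X-versus-autosome comparison: rank-sum on synteny block sizes and
    Fisher on the orthologous-domain proportion."""
    x_sizes = [len(b.src) for b in synteny_blocks
               if class_map.get(b.src.chrom) == "X"]
    a_sizes = [len(b.src) for b in synteny_blocks
               if class_map.get(b.src.chrom) == "autosome"]
    if not x_sizes or not a_sizes:
        raise ValueError("both chromosome classes must contain synteny blocks")
    size_test = st.rank_sum_test(x_sizes, a_sizes)
    cat_by_name = {c.name: c.category for c in domain_categories}
    counts = {"X": [0, 0], "autosome": [0, 0]}  # [orthologous, other]
    for iv, nm in zip(domain_features.intervals, domain_features.feature_names()):
        klass = class_map.get(iv.chrom)
        cat = cat_by_name.get(nm)
        if klass is None or cat is None:
            continue
        counts[klass][0 if cat == "orthologous" else 1] += 1
    fisher = st.fisher_exact_2x2([counts["X"], counts["autosome"]])
    return {
        "block_size_rank_sum": size_test,
        "median_block_size_X": float(np.median(x_sizes)),
        "median_block_size_autosome": float(np.median(a_sizes)),
        "orthologous_proportion_fisher": fisher,
        "orth_X": counts["X"], "orth_autosome": counts["autosome"],
    }


# ---------------------------------------------------------------------------
# the full pipeline


def run_pipeline(cfg: PipelineConfig, pair: Optional[SimulatedPair] = None,
                 outdir: Optional[str | Path] = None) -> dict:
    """Run the complete comparative analysis; returns the report dict.

    When ``pair`` is not supplied, a simulated dataset is generated from
    ``cfg.sim_params`` with ``cfg.seed``.  Deterministic given the seed.
    """
    cfg.validate()
    if pair is None:
        pair = simulate_pair(cfg.sim_params, cfg.seed)

    calls_a = consensus_calls(pair.species_a)
    calls_b = consensus_calls(pair.species_b)
    inv = invert_map(pair.chain)

    ls_a = lineage_specific_boundaries(calls_a["boundaries_high"], pair.chain,
                                       calls_b["boundaries_all"], cfg)
    ls_b = lineage_specific_boundaries(calls_b["boundaries_high"], inv,
                                       calls_a["boundaries_all"], cfg)

    report: dict = {"provenance": {"seed": cfg.seed,
                                   "config": dataclasses.asdict(cfg)}}
    directions = (["A->B", "B->A"] if cfg.direction == "both" else [cfg.direction])
    for d in directions:
        if d == "A->B":
            res = classify_direction(calls_a, calls_b, pair.chain, ls_b, cfg)
        else:
            res = classify_direction(calls_b, calls_a, inv, ls_a, cfg)
        report[d] = res

    primary = report.get("A->B") or report["B->A"]

    # co-linearity of source features against synteny blocks
    blocks = pair.synteny
    src_dom = calls_a["domains_high"]
    src_bnd = calls_a["boundaries_high"]
    colin_d = cl.colinearity(src_dom, blocks)
    colin_b = cl.colinearity(src_bnd, blocks)
    exp_d, _ = cl.shuffle_expected_colinear(src_dom, blocks, pair.ancestor.chrom_sizes,
                                            cfg.n_shuffles, cfg.seed + 11)
    exp_b, _ = cl.shuffle_expected_colinear(src_bnd, blocks, pair.ancestor.chrom_sizes,
                                            cfg.n_shuffles, cfg.seed + 12)
    report["colinearity"] = {
        "domains_observed": int(sum(colin_d)), "domains_expected": exp_d,
        "domains_total": len(src_dom),
        "boundaries_observed": int(sum(colin_b)), "boundaries_expected": exp_b,
        "boundaries_total": len(src_bnd),
    }

    breakpoints = cl.derive_breakpoints(blocks, src_bnd, src_dom, cfg.bt_dist)
    intra = [b for b in breakpoints if b.intra_tad]
    report["breakpoints"] = {"total": len(breakpoints), "intra_tad": len(intra)}

    # gene-level analyses live on the A genome
    genes = pair.genes
    segments = pair.state_segments
    membership = st.gene_domain_membership(genes, src_dom)
    cat_by_name = {c.name: c.category for c in primary["domain_categories"]}
    dom_names = src_dom.feature_names()
    gene_cat = membership.map(
        lambda i: cat_by_name.get(dom_names[i], "none") if i >= 0 else "none")
    in_orth = genes[(gene_cat == "orthologous") & (genes["state"] != "unassigned")]
    in_non = genes[gene_cat.isin(["truncated_expanded", "split_by_boundary",
                                  "split_by_rearrangement"])
                   & (genes["state"] != "unassigned")]
    if len(in_orth) and len(in_non):
        report["state_enrichment"] = st.state_enrichment(in_orth, in_non)
        report["expression_comparison"] = st.expression_comparison(in_orth, in_non)
        de_o = int(in_orth["de_flag"].sum())
        de_n = int(in_non["de_flag"].sum())
        report["de_fraction_fisher"] = st.fisher_exact_2x2(
            [[de_o, len(in_orth) - de_o], [de_n, len(in_non) - de_n]])

    bkpt_fs = FeatureSet("breakpoints", [GenomicInterval(b.chrom, b.pos, b.pos + 1)
                                         for b in breakpoints])
    report["de_near_ls_boundaries"] = st.de_proximity_enrichment(
        genes, ls_a, cfg.de_window)
    report["de_near_breakpoints"] = st.de_proximity_enrichment(
        genes, bkpt_fs, cfg.de_window,
        exclude_features_overlapping=calls_a["boundaries_all"])

    red = genes[genes["state"] == "RED"]
    if len(red) and len(ls_a):
        red_fs = FeatureSet("red_genes", [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in red.itertuples(index=False)])
        report["red_gene_ls_boundary_permutation"] = st.permutation_proximity(
            ls_a, red_fs, pair.ancestor.chrom_sizes, "overlap_count",
            cfg.n_perm, cfg.seed + 13)

    intra_pts = [(b.chrom, b.pos) for b in intra]
    poly_intra = [(c, p) for c, p in pair.polymorphic_breakpoints
                  if any(d.chrom == c and d.start <= p < d.end
                         for d in src_dom.intervals)]
    if intra_pts and poly_intra:
        report["breakpoint_state_comparison"] = st.breakpoint_state_comparison(
            intra_pts, poly_intra, segments)

    # insulation comparisons on the A-genome track
    track = pair.species_a.insulation[1]
    track2 = pair.species_a.insulation[2]
    report["insulation_replicate_rho"] = ins.spearman_replicates(
        track["score"].to_numpy(), track2["score"].to_numpy())
    groups = {
        "boundaries": list(src_bnd.intervals),
        "intra_tad_breakpoints": intra_pts,
        "all_intra_tad_bins": ins.intra_tad_bins(track, src_dom, src_bnd, cfg.bt_dist),
        "lineage_specific": list(ls_a.intervals),
    }
    # A-genome orthologs of B-specific boundaries
    orth_of_ls_b = []
    for iv in ls_b.intervals:
        lifted = lift_and_merge(inv, iv, cfg.merge_gap_boundary, cfg.min_size_boundary)
        orth_of_ls_b.extend(lifted.merged_regions)
    if orth_of_ls_b:
        groups["orthologs_of_lineage_specific"] = orth_of_ls_b
    groups = {k: v for k, v in groups.items() if len(v)}
    if len(groups) >= 2:
        report["insulation_groups"] = ins.insulation_group_comparison(track, groups)

    # motif comparison (needs sequences)
    if pair.species_a.sequence is not None:
        motif_models = [mo.MotifModel(n, consensus=c)
                        for n, c in sorted(pair.params.motifs.items())]
        b_seqs, o_seqs = [], []
        for iv in ls_a.intervals:
            lifted = lift_and_merge(pair.chain, iv, cfg.merge_gap_boundary,
                                    cfg.min_size_boundary)
            if not lifted.merged_regions:
                continue
            r = max(lifted.merged_regions, key=len)
            b_seqs.append(pair.species_a.sequence[iv.chrom][iv.start:iv.end]
                          .tobytes().decode())
            o_seqs.append(pair.species_b.sequence[r.chrom][r.start:r.end]
                          .tobytes().decode())
        if b_seqs:
            test, counts = mo.paired_motif_comparison(b_seqs, o_seqs, motif_models)
            report["motif_paired_comparison"] = {"test": test, "counts": counts}

    class_map = {c: ("X" if c == "MullerA" else "autosome")
                 for c in pair.ancestor.chrom_sizes}
    try:
        report["chromosome_class"] = compare_by_chromosome_class(
            blocks, primary["domain_categories"], src_dom, class_map)
    except ValueError:
        pass

    if outdir is not None:
        render_report(report, outdir)
    return report


# ---------------------------------------------------------------------------
# rendering


TABLE1_ROWS = [
    ("Total", "total", None),
    ("Unique lifted-over", "unique_lifted_over", "pct"),
    ("Orthologous", "orthologous", "pct"),
    ("Non-orthologous", "non_orthologous", "pct"),
    ("Non-orthologous (truncated/expanded)", "truncated_expanded", "pct"),
    ("Non-orthologous (split by lineage-specific boundary)", "split_by_boundary", "pct"),
    ("Non-orthologous (split by rearrangement)", "split_by_rearrangement", "pct"),
    ("Missing", "missing", None),
]


def table1_frame(table1: dict) -> pd.DataFrame:
    """The 8-row conservation summary in publication order."""
    rows = []
    for label, key, _ in TABLE1_ROWS:
        rec = {"category": label}
        for side in ("boundaries", "domains"):
            entry = table1[side].get(key)
            if entry is None:
                rec[f"{side}_n"] = ""
                rec[f"{side}_pct"] = ""
            elif isinstance(entry, dict):
                rec[f"{side}_n"] = entry["n"]
                rec[f"{side}_pct"] = entry.get("pct", "")
            else:
                rec[f"{side}_n"] = entry
                rec[f"{side}_pct"] = ""
        rows.append(rec)
    return pd.DataFrame(rows)


def _check_table1(table1: dict) -> None:
    """Internal consistency: percentages recompute from counts and counts
    partition the totals."""
    for side in ("boundaries", "domains"):
        t = table1[side]
        total = t["total"]
        unique = t["unique_lifted_over"]["n"]
        assert unique + t["missing"]["n"] == total
        assert t["unique_lifted_over"]["pct"] == cl.round_pct(unique, total)
        for key in ("orthologous", "non_orthologous", "truncated_expanded",
                    "split_by_boundary", "split_by_rearrangement"):
            if key in t:
                assert t[key]["pct"] == cl.round_pct(t[key]["n"], unique)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def render_report(report: dict, outdir: str | Path,
                  formats: tuple[str, ...] = ("tsv", "json"),
                  plots: bool = False) -> list[Path]:
    """Write the report as JSON plus Table-1-shaped and tidy-test TSVs;
    optional bar-chart figures."""
    for f in formats:
        if f not in ("tsv", "json"):
            raise ValueError(f"unknown report format {f!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    slim = {k: v for k, v in report.items()}
    for d in ("A->B", "B->A"):
        if d in slim:
            _check_table1(slim[d]["table1"])
            slim[d] = {
                "table1": slim[d]["table1"],
                "n_boundaries": len(slim[d]["boundary_statuses"]),
                "n_domains": len(slim[d]["domain_categories"]),
            }
    if "json" in formats:
        p = out / "report.json"
        with open(p, "w") as fh:
            json.dump(_jsonable(slim), fh, indent=1, default=str)
        written.append(p)
    if "tsv" in formats:
        for d, tag in (("A->B", "AtoB"), ("B->A", "BtoA")):
            if d in report:
                p = out / f"table1_{tag}.tsv"
                table1_frame(report[d]["table1"]).to_csv(p, sep="\t", index=False)
                written.append(p)
        rows = []
        for key in ("de_near_ls_boundaries", "de_near_breakpoints"):
            if key in report:
                r = report[key]
                rows.append({"test": key, "statistic": r.observed,
                             "expected": r.expected, "p_value": r.p_value,
                             "observed_pct": r.observed_pct(),
                             "expected_pct": r.expected_pct()})
        for key in ("expression_comparison",):
            if key in report:
                for nm, r in report[key].items():
                    rows.append({"test": f"{key}.{nm}", "statistic": r.statistic,
                                 "p_value": r.p_value, "direction": r.direction})
        if rows:
            p = out / "tests.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            written.append(p)
        for key in ("state_enrichment", "breakpoint_state_comparison",
                    "insulation_groups"):
            if key in report:
                p = out / f"{key}.tsv"
                report[key].to_csv(p, sep="\t", index=False)
                written.append(p)
    if plots:
        written += _render_plots(report, out)
    return written


def _render_plots(report: dict, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if "state_enrichment" in report:
        df = report["state_enrichment"]
        fig, ax = plt.subplots(figsize=(6, 4))
        x = np.arange(len(df))
        ax.bar(x - 0.2, 100 * df["frac_a"], width=0.4, label="orthologous TADs",
               color=[s.lower() for s in df["state"]])
        ax.bar(x + 0.2, 100 * df["frac_b"], width=0.4, label="non-orthologous TADs",
               color=[s.lower() for s in df["state"]], alpha=0.5)
        ax.set_xticks(x, df["state"])
        ax.set_ylabel("% of genes")
        ax.legend()
        p = out / "state_enrichment.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    obs_exp = [(k, report[k]) for k in ("de_near_ls_boundaries", "de_near_breakpoints")
               if k in report]
    if obs_exp:
        fig, ax = plt.subplots(figsize=(5, 4))
        x = np.arange(len(obs_exp))
        ax.bar(x - 0.2, [r.observed_pct() for _, r in obs_exp], width=0.4,
               label="observed")
        ax.bar(x + 0.2, [r.expected_pct() for _, r in obs_exp], width=0.4,
               label="expected")
        ax.set_xticks(x, [k for k, _ in obs_exp], rotation=20)
        ax.set_ylabel("% of DE genes")
        ax.legend()
        p = out / "de_proximity.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
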