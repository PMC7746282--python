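#!/usr/bin/env python
"""Co-linearity of TADs/boundaries with synteny blocks, and breakpoints.

A feature is co-linear when it lies entirely within one synteny block.
Observed co-linear counts are compared with the average over 100 length-
preserving per-chromosome shuffles (the chance expectation).  Breakpoints
are the internal junctions between consecutive synteny blocks; intra-TAD
breakpoints fall inside a high-confidence domain more than 5 kb from any
boundary.  Also compares the X-chromosome surrogate (MullerA) against the
autosomes: synteny-block sizes (rank-sum) and orthologous-TAD proportion
(Fisher).  Tables land in results/colinearity/.

Run:  python analysis/03_colinearity_breakpoints.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from tadevol.chain import invert_map
from tadevol.classify import colinearity, derive_breakpoints, shuffle_expected_colinear
from tadevol.pipeline import (
    PipelineConfig,
    classify_direction,
    compare_by_chromosome_class,
    consensus_calls,
    lineage_specific_boundaries,
)
from tadevol.simulate import EvolutionParams, simulate_pair


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/colinearity"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pair = simulate_pair(EvolutionParams(), args.seed)
    cfg = PipelineConfig(seed=args.seed)
    ca = consensus_calls(pair.species_a)
    cb = consensus_calls(pair.species_b)
    ls_b = lineage_specific_boundaries(cb["boundaries_high"],
                                       invert_map(pair.chain),
                                       ca["boundaries_all"], cfg)
    res = classify_direction(ca, cb, pair.chain, ls_b, cfg)

    out = {}
    for label, feats in (("domains", ca["domains_high"]),
                         ("boundaries", ca["boundaries_high"])):
        obs = sum(colinearity(feats, pair.synteny))
        exp, _ = shuffle_expected_colinear(feats, pair.synteny,
                                           pair.ancestor.chrom_sizes,
                                           cfg.n_shuffles, cfg.seed + 11)
        out[label] = {"observed": int(obs), "expected": round(exp, 1),
                      "total": len(feats)}
        print(f"co-linear {label}: {obs} observed vs {exp:.0f} expected "
              f"by chance (of {len(feats)})")

    bks = derive_breakpoints(pair.synteny, ca["boundaries_high"],
                             ca["domains_high"], cfg.bt_dist)
    intra = sum(1 for b in bks if b.intra_tad)
    out["breakpoints"] = {"total": len(bks), "intra_tad": intra}
    print(f"breakpoints: {len(bks)} total, {intra} intra-TAD")

    class_map = {c: ("X" if c == "MullerA" else "autosome")
                 for c in pair.ancestor.chrom_sizes}
    cc = compare_by_chromosome_class(pair.synteny, res["domain_categories"],
                                     ca["domains_high"], class_map)
    out["chromosome_class"] = {
        "median_block_kb_X": cc["median_block_size_X"] / 1e3,
        "median_block_kb_autosome": cc["median_block_size_autosome"] / 1e3,
        "block_size_p": cc["block_size_rank_sum"].p_value,
        "orthologous_proportion_p": cc["orthologous_proportion_fisher"].p_value,
    }
    print(f"X vs autosome block size: "
          f"{out['chromosome_class']['median_block_kb_X']:.0f} vs "
          f"{out['chromosome_class']['median_block_kb_autosome']:.0f} kb "
          f"(p = {out['chromosome_class']['block_size_p']:.3g})")

    with open(args.out / "colinearity.json", "w") as fh:
        json.dump(out, fh, indent=1)


if __name__ == "__main__":
    main()
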