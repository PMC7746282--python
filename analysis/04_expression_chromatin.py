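#!/usr/bin/env python
"""Expression and chromatin-state correlates of TAD reorganization.

Asks four questions of the seeded dataset: (1) are differentially-
expressed genes concentrated within 10 kb of rearrangement breakpoints and
lineage-specific boundaries (hypergeometric)? (2) do orthologous and
non-orthologous TADs differ in chromatin-state composition (per-state
Fisher) and expression level (rank-sum)? (3) do fixed interspecies
breakpoints occupy different chromatin states than neutral polymorphic
ones (per-state Fisher; the generator's acceptance model favours the
active YELLOW state 3:1)? (4) do lineage-specific boundaries sit near
RED-state genes more often than shuffled boundaries (permutation)?
Tables land in results/expression/.

Run:  python analysis/04_expression_chromatin.py [--seed 1]
"""

import argparse
from pathlib import Path

from tadevol.pipeline import PipelineConfig, run_pipeline
from tadevol.simulate import EvolutionParams


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/expression"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(seed=args.seed, sim_params=EvolutionParams())
    report = run_pipeline(cfg)

    for key in ("de_near_ls_boundaries", "de_near_breakpoints"):
        r = report[key]
        print(f"{key}: observed {r.observed_pct()}% [{r.observed}] vs "
              f"expected {r.expected_pct()}% [{r.expected:.0f}] of {r.draws} "
              f"DE genes (hypergeometric p = {r.p_value:.3g})")

    if "state_enrichment" in report:
        df = report["state_enrichment"]
        df.to_csv(args.out / "state_enrichment.tsv", sep="\t", index=False)
        print("\nchromatin states, orthologous vs non-orthologous TAD genes:")
        print(df[["state", "frac_a", "frac_b", "p_value", "direction"]]
              .to_string(index=False))
    if "expression_comparison" in report:
        r = report["expression_comparison"]["expression_rank_sum"]
        print(f"\nexpression orthologous vs non-orthologous: "
              f"medians {r.extra['median_x']:.2f} vs {r.extra['median_y']:.2f}, "
              f"rank-sum p = {r.p_value:.3g} ({r.direction})")
    if "breakpoint_state_comparison" in report:
        df = report["breakpoint_state_comparison"]
        df.to_csv(args.out / "breakpoint_states.tsv", sep="\t", index=False)
        print("\ninterspecies vs polymorphic breakpoint states:")
        print(df[["state", "frac_interspecies", "frac_polymorphic",
                  "p_value", "direction"]].to_string(index=False))
    if "red_gene_ls_boundary_permutation" in report:
        r = report["red_gene_ls_boundary_permutation"]
        print(f"\nlineage-specific boundaries overlapping RED genes: "
              f"observed {r.statistic:.0f}, null mean "
              f"{r.extra['null_mean']:.1f}, permutation p = {r.p_value:.3g}")


if __name__ == "__main__":
    main()
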