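# tadevol

Comparative analysis of topologically associating domain (TAD) and
TAD-boundary conservation between two genomes, with a synthetic
comparative-genome simulator that provides exact ground truth.

Chromosomal rearrangements shuffle genomes; TAD boundaries — in
Drosophila, 5 kb bins enriched for BEAF-32 and M1BP insulator motifs —
may either move with them as intact units or be reorganised.  Given TAD
boundary/domain calls from two biological replicates per species and an
orthology map between the genomes (UCSC chain), this package classifies
every high-confidence boundary and domain of one species by what became
of it in the other:

* **boundaries** — *orthologous* when the lifted region lies < 5 kb from
  any boundary call (high or low confidence) of the other species,
  *lineage-specific* otherwise, *missing* when nothing lifts over;
* **domains** — *orthologous* when the lifted, merged region reciprocally
  overlaps a target domain by ≥ 90% of both lengths; otherwise *split by
  rearrangement* (discontiguous lift), *split by a lineage-specific
  boundary* (a boundary present only in the target species falls strictly
  inside the region), or *truncated/expanded* (indel-driven size
  asymmetry); *missing* when nothing lifts over.

Around this classification it implements the accompanying statistics:
co-linearity with synteny blocks against a 100-shuffle expectation,
rearrangement-breakpoint derivation, hypergeometric enrichment of
differentially expressed genes within 10 kb of disruption sites
(p = P(X ≥ x) for X ~ Hypergeom(N, K, n), expectation nK/N), per-
chromatin-state Fisher tests, permutation proximity tests with the
add-one correction p = (1 + #extreme)/(1 + n_perm), a simplified diamond
insulation score (mean contact frequency between the w bins flanking each
bin, z-scored; lower = more insulated), and paired signed-rank
comparisons of insulator-motif counts.  It is written for genome
biologists studying 3D-genome evolution who want the full pipeline — or
any single step — reproducible from files and from seeded simulations.

## Worked example

Simulate a study-scale dataset (five ~23 Mb chromosomes, ~560 TADs in
runs separated by unorganised gaps, ~1000 synteny blocks, boundary
gain/loss on both lineages, localized DE effects) and classify it:

```bash
python analysis/01_simulate.py --seed 1 --out results/dataset
python analysis/02_classify_conservation.py --seed 1
```

which prints, for the A→B direction (seed 1):

```
                                            category boundaries_n boundaries_pct  domains_n domains_pct
                                               Total          492                       389
                                  Unique lifted-over          473             96        383          98
                                         Orthologous          409             86        126          33
                                     Non-orthologous           64             14        257          67
                Non-orthologous (truncated/expanded)                                    147          38
Non-orthologous (split by lineage-specific boundary)                                     26           7
            Non-orthologous (split by rearrangement)                                     84          22
                                             Missing           19                         6
truth agreement (under replicate noise): 364/389 = 94%
```

Totals are high-confidence calls (present in both noisy replicates);
percentages are of unique lifted-over features, rounded half away from
zero.  The last line compares the classification against the simulator's
planted ground truth — 94% agreement here, because replicate noise is on;
with noise disabled the suite verifies the agreement is exactly 100% in
both liftover directions.

The remaining drivers compute the downstream analyses
(`03_colinearity_breakpoints.py`, `04_expression_chromatin.py`,
`05_insulation_motifs.py`); for example, seed 1 yields an excess of DE
genes near breakpoints (36.8% observed vs 22.1% expected,
hypergeometric p ≈ 3e-20), YELLOW-state enrichment among fixed
interspecies breakpoints relative to neutral polymorphic ones (49% vs
15%, Fisher p ≈ 3e-4 — recovering the simulator's 3:1 acceptance
weight), a replicate insulation-score correlation of rho = 0.986, and
more insulator motifs in lineage-specific boundaries than in their
orthologous sequences (paired signed-rank p ≈ 6e-4).

The same steps are available as a CLI (`tadevol simulate|lift|classify|
enrich|insulation|motifs|report|run-all`) operating on BED/chain/TSV/
bedGraph/FASTA files, and as library functions under `tadevol.*`.

## Layout

```
src/tadevol/     library: core intervals, chain liftover, simulator,
                 classifier, statistics, insulation, motifs, pipeline, CLI
analysis/        numbered narrative drivers writing under results/
tests/           pytest suite incl. oracle-based acceptance checks
scripts/         acceptance.py
docs/methods.md  models, parameters, numerical choices, limitations
```
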