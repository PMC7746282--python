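# Methods

`tadevol` implements a comparative analysis of topologically associating
domain (TAD) conservation between two genomes, together with a synthetic
comparative-genome generator that provides exact ground truth so the whole
analysis can be exercised and validated offline.  This note describes the
models, the parameters that matter, the numerical choices, and what the
simulation does and does not establish about real data.

## The conservation classification

The analysis takes, for each of two species, TAD boundary and domain calls
from two biological replicates, plus an orthology map between the genomes
in UCSC chain format.

**Replicate consensus.** Boundary calls present in both replicates
(overlap of at least 1 bp) are *high confidence*; domain calls whose start
and end coordinates agree within 5 kb across replicates are high
confidence; calls seen in one replicate only are *low confidence*.  Only
high-confidence features of the source species are lifted over; the target
species' high **and** low confidence calls serve as the comparison set, a
deliberately permissive choice that biases the analysis toward *over*-
estimating conservation.

**Liftover.** An interval lifted through the chain is reported as one
segment per ungapped alignment block, so indels and rearrangements
fragment the image exactly as alignment-based liftover tools do.
Fragments are then reassembled per target chromosome, ignoring segment
orientation (internal inversions do not break a region): segments
separated by less than 20 kb merge and regions shorter than 5 kb are
discarded for domains; 5 kb and 500 bp for boundaries.  A feature with no
surviving region is *missing*.

**Boundary status.** A lifted boundary lying less than 5 kb (strict, gap
distance between half-open intervals) from any target boundary is
*orthologous*; otherwise *lineage specific*.  A lineage-specific boundary
is therefore a high-confidence boundary in one species whose orthologous
sequence in the other carries no boundary call of any confidence.

**Domain category.** Decision order:

1. nothing lifts over → `missing`;
2. more than one merged region (different chromosomes, or a same-
   chromosome gap of at least the 20 kb merge gap) →
   `split_by_rearrangement`;
3. a single region reciprocally overlapping the best target domain by at
   least 90% of both lengths → `orthologous` (flagged as sharing
   boundaries when both region endpoints lie within 5 kb of target
   boundaries that matched orthologous source boundaries);
4. a target-lineage-specific boundary strictly inside the region (it
   overlaps the region and sits at least 5 kb from both endpoints) →
   `split_by_boundary`;
5. residual → `truncated_expanded` (size asymmetry from large indels or
   boundary loss on the other lineage).

The order is a design choice: a multi-region lift is unambiguous evidence
of rearrangement, so it wins; truncated/expanded is the residual that
merely fails the overlap criterion.  The best target domain maximises
overlap, with ties to the smaller then leftmost target.

**Report.** The conservation summary counts each category, with
percentages of "unique lifted-over" features (total minus missing) and of
the total for liftover success, rounded half away from zero; internal
consistency (counts partition, percentages recompute) is machine-checked
at render time.

**Co-linearity and breakpoints.** A feature is co-linear when entirely
contained in one synteny block.  The chance expectation is the mean
co-linear count over 100 shuffles that relocate each feature uniformly on
its own chromosome, preserving length, with no masking and no overlap
constraint among shuffled features.  Breakpoints are the internal
junctions between consecutive synteny blocks on the source genome (the
coordinate is the left block's end; chromosome-end junctions are not
counted); a breakpoint is intra-TAD when inside a high-confidence domain
and strictly more than 5 kb from every boundary.

## Enrichment statistics

Exact tests are scipy-backed; the test suite verifies them against
brute-force enumeration (all 2×2 tables with row margins ≤ 30; all
hypergeometric configurations with N ≤ 30; rank tests against full
enumeration for n ≤ 8).

* **DE proximity** — hypergeometric upper tail with population = all
  genes, successes = genes whose interval lies within a strict 10 kb gap
  of any retained feature, draws = differentially expressed (DE) genes.
  The expectation is n·K/N, and fractions are reported as percentages of
  DE genes to one decimal.  Breakpoints overlapping any boundary call can
  be excluded before testing.
* **Permutation proximity** — queries are relocated uniformly per
  chromosome; the statistic is either the count of queries overlapping a
  reference or the median gap to the nearest reference; p uses the
  add-one correction (1 + #extreme)/(1 + n_perm), so the smallest
  attainable p with 1000 permutations is 1/1001.  The p-value-uniformity
  check in the suite uses the median-distance statistic: it is effectively
  continuous, whereas overlap counts are coarsely discrete and therefore
  conservative rather than uniform on their grid.
* **Chromatin states** — each gene takes the state (BLACK inactive, BLUE
  Polycomb-repressed, GREEN constitutive heterochromatin, RED dynamic
  active, YELLOW constitutively active) covering the largest share of its
  body, introns included; zero coverage → unassigned, dropped from state
  tests.  Genes map to the domain covering the largest part of them (ties
  leftmost).  Per-state comparisons are 2×2 Fisher tests, uncorrected
  across the five states (raw p-values are reported).
* **Breakpoint states** — the state at the junction coordinate (point
  lookup; no window).
* **Expression** — two-sided Wilcoxon rank-sum on normalized expression;
  a Fisher variant compares up- versus down-regulated counts among DE
  genes near two boundary classes.

## Insulation and motifs

The insulation score of bin *i* for window *w* is the mean contact
frequency between the *w* bins upstream and *w* downstream, averaged over
the requested windows and z-scored per chromosome; bins closer than the
largest window to a matrix edge are undefined.  Lower = more insulated.
This is a deliberately simple diamond statistic with the TAD-separation
sign convention; genome-wide analyses normally read a real insulation
bedGraph rather than recomputing from matrices.  Whether published
comparisons of this kind used raw or z-scored values is ambiguous;
z-scored per chromosome is adopted here.  Group comparisons map each
feature to the 5 kb bin containing its midpoint and use rank-sum tests.

Motifs are IUPAC consensus strings or JASPAR-style PWMs; a PWM matches
where its log-odds score (uniform background) reaches 60% of the maximum
attainable score (configurable; external scanners' thresholds are not
published).  Both strands are scanned, `N` never matches, and occurrences
are made non-overlapping greedily left-to-right on the combined match
list.  The boundary-versus-ortholog comparison sums counts over all
motifs per pair and applies a two-sided signed-rank test with zero
differences dropped.

## The synthetic comparative-genome generator

**Ancestral genome.** Five chromosomes of 23.2 Mb carry 560 domains
(normal lengths, mean 42 kb, sd 12 kb, floor 15 kb) arranged in runs of
geometric size (mean 3.75 domains) separated by unorganised gaps; every
run is delimited and subdivided by 5 kb boundaries, giving ~710 boundaries
— matching the observed ratio of ~700 boundaries to ~550 domains in a
two-Drosophila comparison.  Domains and gaps draw chromatin states
(BLACK 0.40, BLUE 0.08, GREEN 0.15, RED 0.12, YELLOW 0.25); genes
(default 8000) inherit the majority state and state-coupled lognormal
expression (active states high).

**Divergence.** Coordinate-changing mutations — 343 inversions, 100
intra-chromosomal translocations, 40 large indels (~30 kb) — are applied
to lineage B as segment surgery, so the alignment chain between the
species is known exactly; this yields ~1000 synteny blocks of ~110 kb
mean.  Because every analysis sees only the divergence between A and B,
placing these mutations on one lineage loses no generality.  Boundary
gain and loss occur on both lineages.  Breakpoint positions are accepted
with probability proportional to the local chromatin-state weight
(default YELLOW 3, others 1) at *both* cut points.  Polymorphic
comparator breakpoints are sampled uniformly (neutral).

**Exact ground truth.** Every planted event is sampled under exclusion
rules — at least max(20 kb, 12% of domain length) from domain edges,
pairwise-disjoint footprints, at most one event per domain, boundary loss
only where the flanking-domain length ratio forces the merged call below
the 90% reciprocal-overlap criterion — chosen so that the true category
of every call is determined by construction and, under zero replicate
noise, equals the classifier's output in both liftover directions (the
suite verifies 100% agreement).  The price is that turnover and missing
rates saturate: with nominal gain/loss probability 0.35 per eligible
candidate the realized lineage-specific fraction is ~12% (the empirical
study's is ~28%), and "missing" (unalignable) features realize at ~4% of
boundaries.  Unalignable features are modelled as holes punched in the
alignment over sampled event-free boundaries/domains, padded 3 kb so
jittered replicate calls still fail to lift.

**Replicates and tracks.** Each species' calls are degraded into two
replicates by independent 15% call drops (targeting the ~72% both-
replicate agreement seen in real data) and coordinate jitter (sd 1 kb,
clipped at ±2 kb).  Insulation tracks are smooth noise with deep dips at
boundaries and shallow dips at "pre-insulated" ancestral sites — the
positions where breakpoints and novel boundaries arose — encoding the
hypothesis that disruptions fall at locations with ancestral insulating
activity; replicates share the signal and differ by small measurement
noise (sd 0.015), reproducing the ~0.99 replicate rank correlation of
real TAD-separation scores.  Sequences (off by default; i.i.d. uniform
background) carry planted BEAF-32/M1BP-like consensus motifs at
boundaries, and at gained boundaries only on the gaining lineage.

**DE effects.** Genes within 10 kb of any disruption site (junctions and
gained boundaries) are differentially expressed with probability
2 × background (defaults 0.14 vs 0.07), with random direction and
log2-fold-changes ~ ±N(1.5, 0.5).

**What passing tests show.** The simulation establishes that the
classifier, statistics and pipeline recover planted structure correctly
and are calibrated under their own null; it does not establish anything
about Hi-C calling, alignment quality, or the biological effect sizes of
real genomes.  Real data differ in ways the generator deliberately omits:
TAD calls from contact matrices are noisy in structured ways, alignments
have base-level ambiguity, indel spectra are heavy-tailed, chromatin
states are finer-grained than five blocks, and real boundary turnover is
not confined to regions where its classification is provable.

## Problem sizes used in the shipped runs

The default simulation (116 Mb, ~560 domains) runs the full pipeline in a
few seconds.  The acceptance script uses: the default-scale pipeline; a
3 × 5 Mb noiseless-recovery run (~120 domains, 10 inversions, 8 gains, 5
indels); and the published summary counts fed through the report
arithmetic.  Power-sensitive suite checks use sizes chosen by power
analysis: ≥2000 genes for DE-proximity recovery, and 600 domains / ~110
junctions / 400 polymorphic comparators for the chromatin-state
breakpoint comparison (a 3:1 acceptance weight is then detectable in
>90% of runs while the one-event-per-domain rule leaves the weighting
unsaturated).  The motif analysis simulates a smaller (2 × 8 Mb)
sequence-bearing genome, since sequence is unnecessary elsewhere.

## Known limitations

* Chimeric "junction domains" that a real TAD caller would report across
  rearrangement junctions are not emitted; split domains contribute their
  contiguous pieces instead.
* The one-event-per-domain and margin rules cap how much divergence can
  be planted with provable truth; study-level divergence fractions are
  therefore emulated qualitatively, not matched numerically.
* The insulation score is a simplified diamond statistic, not a
  re-implementation of any specific TAD-calling tool's separation score.
* Fisher tests across the five chromatin states are reported raw, by
  design; apply multiplicity control externally if needed.
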