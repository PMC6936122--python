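# Methods

This note documents the models and procedures implemented in
`rbpcons`, the conventions and parameters that matter, what the
synthetic-data generators do and do not emulate, and the design
choices made where the problem statement was genuinely open.

## Coordinates and formats

All genomic intervals are 0-based half-open internally. BED is
natively 0-based half-open; a MAF reference row on the '+' strand
converts directly via `start + size`. Blocks whose reference row is on
the '-' strand are rejected per block with a logged warning (multiz
reference rows are always '+'); this is deliberately non-fatal so a
single malformed block does not abort a chromosome-scale scan. The
species identifier of an alignment row is its `src` up to the first
'.', or the whole `src` when no '.' is present. MAF `i`/`e`/`q`
annotation lines are ignored: only aligned sequence rows enter the
species count. All readers accept plain or gzip-compressed text, and
the MAF reader yields blocks incrementally so files larger than memory
stream through.

## Conservation mapping

A site maps only when it is fully contained in a single block's
reference span; sites straddling block boundaries are unmapped. In
multiz alignments blocks partition the reference, so at most one block
can contain a site; for non-multiz inputs where several blocks qualify,
the highest-scoring block is selected, ties broken by lowest reference
start (configurable only in the sense that callers can pre-filter the
block set).

N counts *distinct* species — duplicate rows for one species count
once — and a species counts as present if it has any row in the block,
even if its aligned text is all gaps over the site's columns: block
membership, not per-column coverage, is the unit of conservation here.
A per-column mode was considered and deferred; it changes the statistic
from "species aligned at this locus" to "species with sequence at these
exact columns", a different (also defensible) quantity.

Unmapped sites are excluded from all distributions but reported as
counts. An alternative reading treats an unmapped site as P = 0; both
treatments are available (`ConservationProfile.percents(unmapped_as_zero=True)`),
exclusion being the default because a site without an alignment block
carries no evidence about *how many* species retain it.

`total_species` defaults to 46 (the 46-way vertebrate alignment,
reference included); synthetic runs pass their own species count.

## Rank-sum tests

All two-group comparisons (site vs null, clade vs clade, region vs
region, RBP vs RBP) use the two-sided Wilcoxon rank-sum
(Mann-Whitney U): exact enumeration when both groups have at most 50
values and no ties, the tie-corrected normal approximation otherwise.
P values on the 46-species lattice are heavily tied, so the asymptotic
branch is the common path at scale.

## Random-region nulls

Null regions of exactly the site length (20 bp by default) are drawn
uniformly over eligible start positions pooled across the intervals of
an annotation space (genomic = whole chromosomes; exonic / intronic /
coding spaces are supplied by the caller as explicit interval lists —
how they were merged or which transcript set defined them is the
caller's responsibility). Interval choice is weighted by eligible
position count, so the scheme is exactly uniform over all possible
placements. Overlaps among draws are allowed: with >100k draws over a
genome, collisions are immaterial, and rejection would bias against
long intervals. Replicate null datasets (10 by default) are checked
for mutual agreement; both the minimum and maximum pairwise rank-sum p
are reported, the minimum being the operative statistic (the most
discrepant replicate pair).

## Family similarity

"Conserved in the same % of species" requires a counting rule the
similarity score's definition leaves open. P values are lattice-valued
(k/T×100), so profiles are compared as multisets over that lattice
(rounded to 9 decimals to absorb float noise), and NBS is the multiset
intersection Σ min(count1, count2) — the only symmetric choice bounded
by min(N1, N2), which keeps SS within [0, 1] and SS(a,a) = 1. **This
counting rule is an interpretation**; any analysis comparing SS values
across tools should confirm the rule matches.

Evolutionary distances are consumed from a supplied Newick tree as
patristic (path-sum) distances; missing branch lengths default to 0.
No normalization is applied unless requested (`normalize=True` divides
by the maximum pairwise distance), since a 0-1 range is a property of
some alignment tools' trees, not of trees in general. The association
between SS and distance is defined as a Pearson chi-square
independence test on an nBins×nBins contingency table of quantile bins
(default nBins = 3; per-family by default, pooling across families is
the caller's choice). Expected counts below 5 trigger a logged caution
— with a 4-member family (6 pairs) the table is sparse and the test is
indicative at best, which is why the default examples use nBins = 2.

## RReliefF

The regressional ReliefF accumulation: for each sampled instance, its
k nearest neighbors (Manhattan distance on min-max-normalized
predictors, ties broken by row order for determinism) contribute to
N_dC, N_dF[i] and N_dC&dF[i] with exponential rank weights
exp(−(rank/σ)²) normalized to sum 1; the final weight is
W[i] = N_dC&dF[i]/N_dC − (N_dF[i] − N_dC&dF[i])/(m − N_dC). The diff
function for numeric attributes is |a−b|/range, so a constant column
accumulates nothing and scores exactly 0, and weights are invariant to
positive rescaling of any predictor.

Defaults k = 10, m = "all" (deterministic full sweep), σ = 20 —
standard practice for regressional Relief filters on tables of tens of
rows. The feature table must be complete (no missing values); there is
no imputation. Shuffle robustness permutes one feature column at a
time, reruns the ranking, and flags a feature "rank-critical" when it
started outside the bottom third but its median post-shuffle rank
lands there. Note that shuffled-feature demotion is only diagnostic
when *other* features carry signal; in a table with a single
informative column, shuffling it makes all columns exchangeable and
its post-shuffle rank is uniform. The site-count regression is plain
OLS of the response on one feature with a t-test on the slope.

## Genic thirds

Gene spans (whole gene bodies; spliced-transcript thirds are out of
scope) are cut by integer division into three segments whose lengths
differ by at most 1 bp; the 0-2 remainder bp go to the
transcriptionally-last segment(s) by default (`remainder="first"`
flips this — the choice is arbitrary and sub-bp-scale, but it must be
fixed for determinism). Labels follow strand: on a '-' gene the 5′
segment has the larger genomic coordinates. Sites are assigned to the
segment containing their midpoint ((start+end)//2); a site overlapping
several genes yields one assignment per gene, a deliberate site-centric
double count. Pairwise region comparisons use raw per-RBP rank-sum
p values at α = 0.05 — no multiplicity adjustment across RBPs, matching
the per-RBP reporting convention; the summary counts RBPs whose 3′
region is significantly more conserved than the 5′ *and* has the larger
median.

## Enrichment

Gene scores are medians of site P values through a caller-supplied
site→gene mapping (a site mapping to several genes contributes to
each). Permutation draws of |overlap| genes come from the scored
universe *excluding* the overlap (the standard permutation null;
including it is available via `exclude_overlap=False`). The universe
is the set of scored genes, not all annotated genes — an unscored gene
carries no conservation information to compare against. A permutation
counts as significant only when the two-sided U test has p < α and the
overlap's median exceeds the draw's: the analysis seeks *highly
conserved* sets, and without the direction gate a set of unusually
low-scoring genes would also be called. Corrected p is
max(1 − #sig/#total, 1/#total) ∈ [1/n_perm, 1]. Sets with overlap
below 3 are flagged, and each set in a collection gets an independent
child seed from a `SeedSequence`, so results are reproducible and
independent of collection order.

## Synthetic data

The generators emulate the *shape* of the real inputs, not their
content:

- **Alignments**: blocks of uniform random length (100-300 bp by
  default) tile each chromosome; each non-reference species is present
  independently with its clade's retention probability. Defaults: 46
  species — reference + 36 "mammal-like" at retention 0.9 + 9
  "lower-vertebrate-like" at 0.2 — echoing the 46-way alignment's
  37-mammal composition and its strong-in-mammals, weak-in-fish
  gradient. Block classes with retention multipliers plant
  high-conservation territory; a gap fraction plants unmappable
  territory. Sequence text is uniform random A/C/G/T: no implemented
  statistic reads the letters.
- **Sites**: 20 bp, 60 RBPs × 200 sites by default; a planted fraction
  (10%) straddles block boundaries and is therefore unmappable by
  construction; positional bias routes mappable sites to designated
  gene thirds by rejection sampling; a site block class confines sites
  to boosted blocks.
- **Feature tables**: response = 50 + effect·z(planted feature) +
  N(0, 5), planted feature `n_binding_sites` with effect −15 percent
  points per SD by default (the negative sign mirrors the
  more-sites-less-conservation direction; Relief weights are
  sign-blind). All other columns are independent noise.
- **Gene sets**: one planted set whose member scores get a +30 shift
  (the scale of a strong conservation signal against a N(50, 10²)
  score universe) among size-matched random sets.

What the generators do *not* emulate: substitution processes, indels,
alignment quality, GC/repeat structure, per-species phylogenetic
correlation (species are independent given the clade), overlapping
genes, isoforms. Passing tests therefore demonstrate that the
*pipeline machinery and statistics* recover planted structure at
realistic scales — they say nothing about biological conclusions on
real alignments, and in particular the independence-across-species
assumption makes the synthetic per-species presence matrix cleaner
than a real one would be.

Per-block species presence is i.i.d., so every mapped site in the
default scenario has the same P distribution; per-RBP conservation
*differences* are planted via block classes and per-RBP tier
probabilities, not via per-RBP retention.

## Pipeline

Stages (conserve → nulls → families → features → regions → enrichment)
communicate through headered TSVs under the output directory; the
manifest records a SHA-256 checksum per output file, and a rerun with
identical config reproduces byte-identical files (floats are written
with a fixed `%.10g` format). All randomness descends from the config
seed. The RReliefF stage adapts k to min(10, rows−1) so small
scenarios remain runnable.

## Problem sizes

Default test and reproduction scales were chosen to make planted
effects statistically decisive while running on a laptop-class single
core: ~2,000 alignment blocks (two 200 kb chromosomes) for clade
gradients, 60×11 feature tables with 100 seeded replicates for Relief
recovery, 20 RBPs × 150 sites for the genic-thirds comparison, and a
1,000-gene universe with 1,000 permutations for enrichment. The
analysis of full-genome alignments (multi-GB MAF) is supported by the
streaming reader but is not exercised in tests.

## Known limitations

- The SS counting rule and the chi-square association construction are
  documented interpretations of under-specified definitions.
- Exact rank-sum enumeration is disabled in the presence of ties; on
  the P lattice ties are the norm, so small-sample comparisons use the
  tie-corrected normal approximation and their p-values are
  approximate.
- Sex-chromosome handling is the caller's choice: nothing is excluded
  by default; pass the chromosome set you want analyzed.
- The enrichment permutation loop calls the U test per draw; for
  collections of thousands of sets a vectorized or cached-statistic
  implementation would be the next optimization.
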