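# Methods

This note documents the statistical procedures `setsig` implements, the
choices made where conventions genuinely diverge, what the synthetic-data
module does and does not emulate, and the problem sizes the test suite runs
at.

## Over-representation analysis

The test is the one-sided (enrichment) Fisher exact test: with a test list
of size |T|, a query set of size |Q|, overlap a, and universe N, the
p-value is the exact hypergeometric tail P(X ≥ a) with population N, |T|
successes and |Q| draws. We compute it through the hypergeometric survival
function rather than a normal approximation; the test suite checks it
exhaustively against integer-arithmetic enumeration for every 2×2 table
with N ≤ 30.

Conventions:

- **Universe.** The default analysis is size-only: the caller declares N
  (e.g. 20,438 for the human coding genome) and the sets are trusted to be
  drawn from it. Passing an explicit universe list intersects both sets
  with it first. We deliberately expose universe construction as an input
  rather than inferring it, because ortholog-mapped universes depend on
  collision handling upstream that the caller controls.
- **Adjustment.** Bonferroni (min(1, m·p)) is the default everywhere except
  UES construction, which defaults to Benjamini–Hochberg; both are exposed
  as a `method` parameter and the family size m is the number of library
  sets actually tested. Both routes delegate to
  `statsmodels.stats.multitest`.
- **Odds ratio.** The sample (cross-product) OR ad/bc, not the
  conditional-MLE variant some environments report; it is closed-form,
  deterministic, and monotone in a. Zero cells take the Haldane–Anscombe
  +0.5 correction on all four cells, keeping the estimate finite without a
  sentinel.
- **Significance.** α = 0.05 on the adjusted p, strict inequality,
  throughout.
- **Ties.** ORA results sort by (adjusted p, raw p, query name); every
  downstream ranking inherits deterministic lexicographic tie-breaks.

## Permutation null of odds ratios

`null_odds_distribution` draws n_perm gene lists of size k without
replacement from the universe and records each draw's OR against the query
set over that same universe. The seed is a required parameter and is stored
in the result. The empirical p uses the add-one estimator
(1 + #{draws ≥ observed}) / (n_perm + 1), so ties count toward the tail and
the estimate is never zero. Under the null this p is approximately uniform;
the acceptance suite verifies the rejection rate at 0.05 and that the null
OR distribution is centered on 1.

## Upstream enrichment signatures

Significance scores are −log(adjusted p) for regulators with adjusted
p < α and exactly 0 otherwise. The logarithm base is 10; the source
convention leaves the base unstated, and because the scores are subsequently
max-normalized, the base cancels and rankings are base-invariant — the
choice is documented rather than consequential. Normalization divides by
the maximum raw score: the top regulator maps to exactly 1 and
non-significant regulators stay at exactly 0. Min–max scaling was rejected
because it would collapse the weakest *significant* regulator onto the
non-significant ones. An adjusted p of exactly 0 (floating-point underflow)
is clamped to the smallest positive double before the log, with a warning.

UES vectors are sparse: absent regulators are implicit zeros, and distances
are computed over the union of keys, so regulators at zero in both vectors
never affect a ranking. UES-blast sorts reference entries by ascending
Euclidean distance with lexicographic tie-breaks and returns all entries
with ranks 1..n. Normalization is applied per gene set, before reference
assembly. Whether a query present in the reference should match itself is
left to the caller via `exclude_origin`. Reference assembly supports a
minimum-set-size filter (`min_genes`), reflecting the practice of dropping
small gene sets (e.g. below 500 or 250 genes depending on the source
library) whose signatures are unstable.

## Histone-mark counting and the H3K27me3 score

Query-set names in mark libraries encode their mark as the leading
whitespace-delimited token ("H3K27me3 cerebellum mm9"); the tokenizer is a
parameter for libraries with other naming schemes, and unparseable names
fail loudly with the offending names listed. The per-library score for the
target mark is

    (n_sig_mark / n_total_mark) × (n_sig_mark / n_sig_all_marks),

where the second denominator counts significant sets across *all* marks
including the target (so 60 target + 10 other significant sets gives
0.6 × 60/70 ≈ 0.51). It is 0 when no target-mark set is significant and the
two-library combined score is the plain sum, in [0, 2]. The score is
monotone in the target-mark count and strictly penalized by off-target
significance.

## Peak analyses

All intervals are 0-based half-open (BED convention); bookended intervals
do not overlap and the minimum overlap is 1 bp. Peaks are strandless;
genes carry strand. Overlap queries run on per-chromosome interval trees
(`intervaltree`), checked in the suite against an all-pairs scan.

Promoters are strand-aware TSS windows, default −1000/+500 bp: a + strand
gene with TSS t spans [t−1000, t+500), a − strand gene [t−500, t+1000).
The defaults follow the promoter window used for primer design in the
assays this package accompanies and are exposed as parameters, since peak-
to-gene assignment tools differ in their defaults. A gene hit in both
promoter and body counts once. Peak-to-gene mapping returns a (possibly
empty) set of symbols; the empty case is well-defined and flows through
conditioned enrichment as an all-p=1 arm.

`overlap_conditioned_enrichment` returns the unconditioned and conditioned
result lists in library order so entries pair by index.

## Behavioral and assay scores

- **Social score**: mean over frames of the affine map sending the
  empty-compartment wall to −1 and the social-stimulus wall to +1; the
  score is invariant under affine re-parameterization of the axis and
  antisymmetric under reflection. Tracker jitter up to 1% of the chamber
  length beyond a wall is clamped; larger excursions raise, on the theory
  that they indicate a tracking failure rather than noise.
- **Open field**: percent of frames inside the center rectangle (boundary
  inclusive — the tie-break is documented rather than consequential) and
  mean velocity as total path length over duration ((n−1)/frame_rate).
- **Adjusted fold change** for ChIP-qPCR: the target/reference-gene fold
  change ratio in the treatment sample divided by the same ratio in the
  vehicle control; positive inputs required.
- **Coefficient of exploratory variation**: sample SD (n−1 denominator; the
  source convention is unstated, so the choice is made explicit and tested)
  of per-hole head-poke counts divided by their mean; scale-invariant;
  undefined (raises) for all-zero counts.

## Synthetic data

Every generator is a pure function of a `PlantedDesign` plus a seed and
returns its ground truth alongside the data; recovery tests read truth only
from that channel. Randomness flows through one seeded NumPy generator per
call, with independent streams per generator derived from the design seed.

Default scales mirror the real analyses this pipeline was built for: a
20,438-gene universe, a 5,044-gene test list, a 1,000-gene disease set
(the size of a typical curated risk-gene database), regulator libraries of
~100 sets × 300 targets, and a planted test/disease overlap of 390 genes,
which corresponds to a design odds ratio of about 2. Planting strength is
expressed as a target odds ratio and converted to a sampling probability
q = OR·p₀/(1−p₀+OR·p₀) (odds multiplied by OR relative to the baseline
fraction p₀); planted sets then draw each gene from the preferred pool with
probability q. The disease/test overlap itself is exact rather than
sampled, so the design odds ratio is known without Monte Carlo error.

The peak generator places colocalized A/B peak pairs at gene promoters
(biased toward disease genes at the planting odds ratio), non-colocalized A
peaks at promoters of other genes with one gene per peak, and B's remaining
peaks intergenic; because non-colocalized placements are constructed to
avoid the partner set, the realized colocalization fraction equals the
planted fraction exactly. Trajectories are bounded random walks with
Gaussian steps (SD 2 length-units/frame) plus a drift of preference_p × 1.5
units/frame toward the social wall, reflecting at the walls; at
preference_p = 1 the stationary distribution hugs the social wall (mean
score ≈ 0.95), at 0 the walk is symmetric.

What the generators do **not** emulate: realistic gene-length and GC
structure, correlated regulator targets (real ChIP libraries share targets
heavily), inter-tissue correlation within a mark, read-level noise, and
tracking artifacts beyond boundary jitter. Passing recovery tests therefore
demonstrates correctness of the statistics and the planted-signal plumbing,
not robustness to every failure mode of real data.

## Problem sizes in the test suite

The acceptance-style tests run at deliberately scaled sizes chosen to keep
the default test run fast while leaving comfortable statistical margins:
Fisher enumeration is exhaustive to universe 30; null calibration uses 200
replicates at universe 2,000, k = 200, 199 permutations each, and the
null-median check runs at universe 10,000, k = 1,000, 500 permutations;
signature recovery runs 100 replicates at universe 10,000 with 60
regulators × 250 targets, 4 planted regulators, and 55 decoy sets;
mark-score discrimination runs 100 replicates at universe 5,000 with
4 marks × 4 tissues × 2 libraries; the trajectory monotonicity check uses
100 seeds × 900 frames per preference level.

## Known limitations

- The Fisher test assumes a fixed, correctly specified universe; an
  inflated N inflates enrichment. Nothing in the package can detect a wrong
  universe declaration in size-only mode.
- UES distances treat regulators as independent axes; strongly correlated
  regulator target sets (common in ChIP compendia) make distances
  optimistic about specificity.
- The permutation null draws uniformly from the universe and does not model
  gene-level covariates (expression level, gene length) that bias real
  differential-expression lists.
- `venn_counts` counts peaks, not merged genomic regions: two sets covering
  the same locus each contribute their own peak to a signature.
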