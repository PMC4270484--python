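# Methods

## Cross-species interval mapping

Chains are parsed in the UCSC format and validated (block sizes plus
gaps must equal the declared spans on both sides). Query coordinates of
'-'-strand chains stay in the reverse-complement frame the format uses
and are converted to forward-strand coordinates only when a base is
actually mapped — one conversion point, pinned down by oracle tests that
map every base independently.

An interval maps when the fraction of its bases inside aligned blocks of
the single best-overlapping chain reaches `min_match` (default 0.10).
"Best" is most aligned bases, ties broken by chain score and then lower
chain id. With `require_unique` (default), a second chain that also
reaches `min_match` rejects the lift as split/ambiguous — the one:one
behavior of the reference implementation. The lifted interval is the
bounding span of the images of the first and last aligned base: gaps
inside the interval are spanned, not excised. Peaks are lifted as
summit ± 50 bp windows, clipped at chromosome bounds; the narrow window
avoids spurious failures from diverged peak edges.

## Conservation classes

Mapped source windows overlapping ≥ 1 destination-peak base are
conserved, otherwise lost; the denominator for every rate is the number
of successfully mapped source peaks. A destination peak within ± 5 kb of
a lost lifted window is compensatory, unless it is already conserved for
some other source peak (priority conserved > compensatory keeps the
destination partition disjoint and avoids double counting). Remaining
destination peaks are gained; the top `ceil(0.10 · n)` gained peaks by
read score are relabeled strongly gained, with score ties broken by
genomic order so the labeling is deterministic. Top-percentile peak
filtering (`rank_filter_peaks`) uses the same ceiling-and-genomic-order
rule. The strongly-gained decile is taken within each TF separately (a
pooled variant is a one-line change in the caller); per-TF matches how
the per-factor analyses are organized.

Genes are attached to categories by proximity: any site of a class
within ± 10 kb of the gene body flags the gene, and a gene near several
classes takes the highest-priority one
(conserved > strongly_gained > compensatory > gained > lost). The 10 kb
window and the priority order are configuration knobs.

## Co-occupancy regions

Summits of the TF panel are clustered by single linkage at ≤ 1000 bp;
a region's TF set is every factor contributing a summit, giving 2^k − 1
groups. Regions are lifted via their full span when shorter than 500 bp,
otherwise via the ± 50 bp window around the median summit, keeping the
mapping consistent with single-peak summit windows. A mapped region is
assigned to the destination region it overlaps (larger overlap wins,
ties to the nearer median summit) or to "absent"; unmapped regions are
excluded from the denominators, so transfer-matrix rows are stochastic
over mapped regions. Gene assignment takes the nearest TSS within 50 kb
of the region midpoint (a conventional enhancer-proximity cap),
equidistant ties resolved by lexicographic gene id.

## Permutation and state enrichment

The permutation test re-places each query segment uniformly at random
within the workspace — each segment wholly inside one workspace
interval, no overlap among placed segments (rejection sampling,
vectorized across permutations) — and compares the base overlap with the
reference against the permutation distribution. p-values use the add-one
rule, (1 + #{perm ≥ obs}) / (1 + n_perm), so they are never zero, with a
resolution floor of 1/(n_perm + 1); two-sided doubles the smaller tail,
capped at 1. Isochore- or GC-conditioned randomization is deliberately
out of scope: the uniform null is the one the calibration tests verify.
Default n_perm is 100,000; the calibration property (type-I error within
[0.03, 0.07] at α = 0.05 under a true null) is checked at 200
permutations per test.

State folds are `(query bases in state / query bases) /
(workspace bases in state / workspace bases)` per state; query bases
outside the segmentation tally under a reserved state 0 with a warning.
Occupancy odds for species-specific genes use the 2×2 odds ratio with a
0.5 Haldane–Anscombe correction when any cell is zero, and Fisher's
exact p. Rank-sum comparisons use the exact Mann–Whitney distribution
for tie-free samples of ≤ 20, otherwise the normal approximation with
tie correction.

## Signal quantification

Tags extend 3'-ward to 200 bp from their 5' end; coverage is kept as
mean per-base depth per bin (default 25 bp; bin 1 is exact per-base and
serves as the oracle in tests), scaled to reads-per-million, and the
input control is subtracted in RPM with flooring at 0 — negative
post-subtraction signal has no interpretation and flooring keeps the
log2(1 + x) transform defined. The promoter window is TSS ± 2 kb,
strand-oriented, matching the metagene flank convention; the pseudocount
1 inside log2 preserves zeros. Metagene profiles keep flanks at native
bin resolution and resample the gene body to 100 equal-width bins,
reversing '-'-strand genes. Promoter classification thresholds
(H3K4me3 > 1 RPM active, H3K27me3 > 0.5 RPM repressed, both = bivalent)
apply on the pre-log RPM scale.

## Expression models

Promoter matrices from the two species are quantile normalized per mark
(mean of order statistics across species; ties share their block mean;
idempotent), removing species-scale differences before pooling. The
lasso standardizes predictors internally, builds a 100-point λ grid
log-spaced three decades down from the smallest all-zero penalty, and
cross-validates with folds stratified by response decile under a
mandatory seed. The chosen penalty is the largest λ whose CV error is
within one standard error of the minimum (the sparser side); the model
is refit on all rows at that λ, and both in-sample and cross-validated
R² are reported because the two answer different questions. The default
fold count is 10, exposed as a parameter.

The consensus model is one lasso on the row-concatenated species
matrices; per-species R² applies that single model to each species. The
difference model applies the consensus coefficients to X_h − X_m with no
intercept (intercepts cancel in differences) and scores 1 − RSS/TSS
against y_h − y_m; under a shared-coefficient generative model with
independent noise this converges to Var(X_Δ β) / (Var(X_Δ β) + 2σ²),
which the acceptance checks verify. Species-specific genes are the top
and bottom deciles of the signed log2((FPKM_h + 1)/(FPKM_m + 1)) ranking
at a chosen stage (default ProE), deterministic under ties. Expression
summaries report medians and quartiles of log2(1 + FPKM), replicates
averaged first.

## Synthetic data: what it emulates, and what it does not

The generator builds two genomes joined by one chain per chromosome
(default 2 × 20 Mb; blocks 2–20 kb; target-side gaps sized for a 20 %
unmappable fraction; 30 % of blocks followed by query insertions up to
2 kb), 2,000 genes with orthologs at chain-corresponding positions, and
per-TF peak sets of 2,000 mapped source peaks: conserved with the
planted probability (0.25 for GATA1/TAL1/NFE2-like factors, 0.60 for
KLF1-like, reflecting the contrast the comparison is built around),
otherwise lost, with a 0.25 compensatory fraction placed 0.2–4.3 kb from
the lifted window, plus 1,000 destination-only gains with lognormal
scores. Mapped sites are placed with an 11.5 kb exclusion zone on the
destination genome so that a lost site has a nearby destination peak if
and only if one was planted — recovered rates are then clean binomial
estimates of the planted rates; the genome length is set by the packing
this requires at 2,000 peaks per TF. Conserved sites draw scores with a
boosted lognormal location so that score correlates with conservation,
reproducing the top-quantile sensitivity behavior qualitatively.

Combinatorial CRM regions are planted separately (400 triples, 800
pairs, 1,600 singles) with retention 0.35/0.15/0.05; retention is
planted as an exact per-group count (shuffled) rather than a Bernoulli
coin per region, so the planted proportion is the configured rate and
recovery error reflects the pipeline, not the generator's coin flips.

Promoter mark intensities are Gamma-derived on the rpm scale
(planted X = log2(1 + rpm) exactly); ortholog pairs share a latent
intensity with per-mark jitter (sd 0.2). Expression is
y = 5 + Xβ + ε with β nonzero for H3K9ac (3), H3K4me3 (2),
H3K27me3 (−1.5), H3K36me3 (1) and GATA1 (0.5) — active marks positive,
the repressive mark negative, five of ten marks silent — and σ set from
the realized Var(Xβ) so the population R² equals 0.60. FPKM is exported
as 2^y − 1 floored at 0, making the log2(1 + FPKM) response invert the
generative model exactly (the floor censors well under 1 % of genes at
these settings). A 10 % planted fraction of pairs per direction receives
a mark shift along the positive coefficients worth 8 log2-units of
expression, creating mark-driven species-specific genes; gene-category
expression offsets (conserved 2.0 > strongly gained 1.5 > compensatory
1.0 > gained 0.5 > lost 0, shared across stages and species) plant the
category ordering. Tags are Poisson-thinned from the planted rpm plus a
uniform background, with a uniform input library; because a uniform
library's RPM background is fixed by genome size and fragment length,
input subtraction leaves a small constant negative bias at promoters —
it shifts recovered intensities without reordering them. Default depth
is 150,000 reads per mark per species (pipeline scale); the
tag-recovery check runs at 1,000,000 reads with a single mark, where the
planted matrix is recovered at r ≥ 0.95.

The generator does not emulate: sequence (no motifs, no mappability
structure), biological replicate structure in ChIP, isochore/GC
composition, peak-calling artifacts, or correlated noise between marks.
Passing tests therefore demonstrate correctness of the estimators under
the stated statistical structure, not robustness to those real-data
phenomena.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; every reader enforces
  its type's invariants and every writer round-trips bit-identically.
- Summit fallback (missing narrowPeak offset) is the interval midpoint,
  logged.
- The λ → 0 lasso limit is checked against closed-form least squares at
  λ = λ_max · 1e-10 with tolerance 1e-12 (agreement well under 1e-6
  relative).
- Permutation placement rejects a whole permutation row on intra-query
  overlap and resamples it, which preserves uniformity over
  non-overlapping configurations; a round cap guards against crowded
  workspaces.
- Pipeline stages derive their random generator from (run seed, stage
  name), so re-running any stage subset reproduces byte-identical
  outputs; the end-to-end run at default scale completes in about a
  minute on one CPU.
- Problem sizes in tests and the acceptance script (2,000 peaks per
  factor, 2,000 genes, 10 marks, 500 calibration replicates at 200
  permutations, 20 lasso seeds) are the package's desk-scale study
  conditions; they keep every planted quantity estimable with tight
  binomial error.

## Known limitations

- The transfer matrix assigns each mapped region to a single destination
  group; partial-overlap ambiguity is resolved by overlap size, not
  split fractionally.
- The permutation sampler places segments independently subject to
  non-overlap; it does not condition on local composition.
- Fold display scaling across states is provided
  (`StateEnrichment.scaled`) but folds are the primary, tested output.
- The difference model reuses the consensus coefficients; it never
  refits on differences, by design — its R² is a transfer measurement,
  not a fit.
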