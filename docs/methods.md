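# Methods

`karyoshift` implements the comparative analyses used to characterize
chromosomal rearrangements between closely related fish genomes — repeat
landscapes around inversion breakpoints, gene-order synteny, windowed
population divergence, and the phylogenetic association between karyotype
and distribution — together with a synthetic-data generator that produces
inputs with the statistical structure these analyses assume, plus exact
ground truth for recovery testing.

## Coordinates and repeat categories

All internal coordinates are 0-based half-open; 1-based inclusive
conventions exist only at format boundaries (RepeatMasker `.out`, VCF,
GFF3) and are converted exactly once at read/write time.

Repeat classes follow the RepeatMasker class/family convention (the prefix
of the family string before `/`). Density categories are fixed unions of
classes: retroelements = {LINE, SINE, LTR}; DNA elements = {DNA, RC};
all interspersed TEs = both plus Unknown; simple tandem repeats =
{Simple_repeat, Low_complexity, Satellite}. Unknown-class features count
toward "all TEs" but toward neither subcategory, so the three interspersed
tracks are additive up to the Unknown remainder. Multiallelic VCF sites are
dropped (with a counter) rather than decomposed; hard filtering is assumed
to have happened upstream.

## Window densities and peaks

Density is the merged-coverage fraction of a window: features of one
category are clipped to the window, overlaps across families merged, and
covered bases divided by the window's true width, giving a value in [0, 1].
This is coverage semantics, not element counts — overlapping annotations
are never double-counted. Windows tile each chromosome from coordinate 0
in non-overlapping 10-kb steps (500 bp in the fine-scale gene-cluster mode,
which scans a cluster ± 25 kb); the final partial window is kept and
normalized by its own width, so telomeric signal — where translocations
concentrate — is not discarded. Peak calls compare each window against the
95th percentile of its own chromosome's windows for the same category,
computed with linear interpolation between order statistics; a peak
requires a strictly greater density. Chromosome distributions include all
windows (no masking of putative centromeric high-density regions; a
scientist can pre-filter the input annotation if that is wanted).

Coverage queries run through a prefix-sum index over merged intervals
(`CoverageIndex`), making per-window and per-region evaluation O(log m)
and fully vectorized — the permutation test below evaluates ~20,000
candidate windows per inversion in a few milliseconds.

## Breakpoint-enrichment permutation test

Each inversion defines two breakpoint regions: its start and end
coordinates ± 50 kb (100-kb regions, clipped at chromosome ends; a clipped
region keeps its true width). The observed statistic pools the 10-kb
subwindow densities of both regions and takes one median, giving one test
per inversion. The null distribution draws 1,000 pairs of 100-kb regions
uniformly from the same chromosome; every null region avoids all
breakpoint regions of all inversions on that chromosome (the stricter
reading of "non-breakpoint"), the two members of a pair are mutually
disjoint, and pairs are drawn with replacement across replicates. Each
pair is scored with the identical pooled median.

Significance follows the percentile rule: observed median strictly greater
than the 95th percentile of the null medians. An add-one empirical p-value
`p = (1 + #{null >= observed}) / (n + 1)` is reported alongside — the `>=`
makes fully tied cases conservative (p = 1) — and the two can disagree by
one rank near the boundary; the percentile flag is authoritative.

Null sampling is exact, not rejection-only: valid start positions form a
union of integer ranges (complement of the dilated exclusion set), sampled
by inverse transform. Pair disjointness uses vectorized batch rejection;
when free space barely fits two regions (acceptance collapsing), the
sampler enumerates the valid start set and draws the pair exactly, so the
degenerate "only one disjoint pair exists" geometry still works.

Calibration: on homogeneous landscapes the false-positive rate sits at
~0.05 with a small (< +0.01) upward drift from percentile interpolation
and from the exclusion of the focal breakpoint regions out of the null
area; both are properties of the published design, and the exact binomial
calibration check passes with margin (see `scripts/acceptance.py`).

## Synteny blocks and rearrangement calls

Anchors are one-to-one ortholog pairs with dense per-chromosome gene-order
ranks. A block is a maximal chain with consecutive query- and
reference-rank gaps ≤ `max_gap` (default 10, the MCScanX default gene gap),
strictly monotone reference ranks with a fixed sign, and ≥ `min_anchors`
(default 5) anchors.

Chaining is greedy over the query gene order with multiple chains open at
once. Each anchor joins the compatible open chain with the smallest
reference-rank step, ties broken by query continuity (the chain whose last
anchor is nearest). One lookahead rule handles orientation pivots: when an
anchor's bond to the *next* query gene is tighter than its bond to a
candidate chain and points the other way, that candidate is vetoed — this
is what keeps the first gene of an inversion out of the preceding forward
block. Greedy partitions are not guaranteed optimal on adversarial
interleaved gene orders, so the chromosome is re-chained by iterated
extraction of the DP-optimal single chain whenever the greedy blocks cover
fewer anchors than that optimum (an O(n·max_gap) dynamic program; the
fallback fires on roughly 2 in 46,000 random small permutations and never
on rearrangement-structured data).

Fusion calls: a query chromosome is a fusion product when ≥ 2 reference
chromosomes each hold ≥ 10% of its block anchors (major partners) and the
major partners jointly cover ≥ 80% — thresholds chosen so clean two-way
fusions carrying up to ~10% translocated content are still called with
exactly two partners. The junction estimate is the midpoint between
adjacent major-partner query spans, accurate to about one anchor spacing.

Translocation calls are maximal runs of minority-partner blocks; a run is
internal when major-partner anchors lie on both sides of its query span
(a single spanning block suffices — block order alone cannot see spatial
embedding), otherwise terminal, matching the telomeric reallocations such
analyses report.

Interval projection maps endpoints through each intersecting block by
linear interpolation between block endpoints, reversing for reverse
blocks, and merges the images per reference chromosome; resolution is
bounded by local anchor spacing. Inversion overlap projects inversion A
into B's genome, intersects with B, and calls "partly overlapping" at
≥ 10 kb shared (a default; the underlying studies do not state a minimum).
Breakpoint contact is evaluated per side from the *boundaries* of the
projected interval ± 50 kb — projecting a breakpoint flank itself through
an inverted block would map it onto both ends and always double-fire.

## Windowed π, D_XY, F_ST

All three are ratio-of-sums estimators per 10-kb window, never means of
per-site ratios, and π/D_XY require invariant sites in the input — this
count-based form (the one pixy popularized) is what keeps the estimators
unbiased under missing data. Per site with non-missing ref/alt allele
counts:

* π: differences `n1·n2`, comparisons `(n1+n2)(n1+n2−1)/2`; invariant
  sites contribute comparisons only.
* D_XY: differences `x_ref·y_alt + x_alt·y_ref`, comparisons
  `(x_ref+x_alt)(y_ref+y_alt)`.
* F_ST: Weir–Cockerham variance components in the haploid-sample
  (haplotype-count) formulation — the within-individual component is
  identically zero — summed over polymorphic biallelic sites, window value
  Σa / Σ(a+b). Hudson's estimator is available behind a flag. Negative
  values are reported as computed.

A window with zero denominator (or, for F_ST, no usable polymorphic site)
is missing, never zero. Missing data enter only through per-site
non-missing counts; nothing is imputed.

Conserved tracts are maximal runs of windows with F_ST below 0.5, bridged
across at most one missing window — the scan that picks out
low-differentiation stretches against a ~0.8–0.9 background.

## PGLS under Brownian motion

The regression is closed-form GLS with residual covariance σ²C, where
C_ij is the shared root-to-tip path length of tips i and j:
β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with X = [1, x], σ̂² = RSS_C/(n−2), two-sided p from
Student's t with n−2 df. For BM on a fixed tree the rate profiles out
analytically, so no iteration is needed and the fit is exact; on a star
tree with equal depths it reduces to OLS. Bonferroni adjustment multiplies
by the number of models fitted in one invocation, capped at 1. Chromosome
number is treated as continuous, as the standard phylogenetic-regression
workflow does. Singular C (duplicate tips via zero-length cherries) and
constant predictors are rejected with errors rather than regularized.

Alignment statistics define a variable column as ≥ 2 distinct non-gap
states, a parsimony-informative column as ≥ 2 states each seen ≥ 2 times
(gaps are never states), and a gap column as containing ≥ 1 gap. The
filter keeps alignments with length > 500, VAR% > 5, PI% > 2.5 and
gap% ≤ 30 — strict and non-strict exactly as the thresholds are usually
printed, which the boundary tests pin down.

Quartet frequencies restrict each gene tree to the members of four taxon
groups and count which of the three pairings appears as an exact edge
bipartition; polytomies and non-monophyletic arrangements count as
unresolved and leave the denominator, trees missing a whole group are
skipped.

## Synthetic-data generator

The generator's job is first-order statistical structure with exact ground
truth, not sequence realism (no nucleotides, reads, or coalescent
machinery).

* **Repeats** per family are a homogeneous Poisson process (rate in
  insertions/bp; lengths uniform in a per-family range, default
  100–1000 bp) with independent placement; overlaps within and across
  families are allowed, as in real annotations. Inside the ± 50 kb flanks
  of planted inversion breakpoints the rate is multiplied by λ as a step
  function — thinning for λ < 1, superposed extra process for λ > 1, both
  exact, so λ = 1 is indistinguishable from background by construction.
* **Anchor tables**: genes are laid evenly along each ancestral
  chromosome (`genes_per_mb`, default 10 — cod-like gene density is ~35,
  but 10 keeps desk-scale runs fast; recovery tests use 12–40). Fusions
  concatenate partner coordinates, inversions mirror fully contained
  genes, translocations move gene runs with offsets preserved; one
  ortholog pair per gene, no missing or spurious orthologs.
* **Genotypes** are haploid sequences over a contiguous block of sites
  (written as diploid VCF by pairing haplotypes; default 28 haplotypes =
  14 diploid individuals per population, matching typical resequencing
  panels). Each site is exactly one of: fixed inter-population difference
  (rate d), polymorphic in one population, or invariant. Polymorphic sites
  draw their alternate-allele count uniformly on 1..n−1, and the
  polymorphism probability is calibrated so the expected ratio-of-sums π
  equals the requested rate (E[j(n−j)]/(n(n−1)/2) = (n+1)/(3(n−1))).
  Inside conserved tracts the fixed-difference rate is multiplied by a
  tract factor **and** polymorphisms become shared (same allele count in
  both populations): private polymorphism alone leaves Weir–Cockerham
  F_ST high, whereas shared haplotypes are what actually drives the
  below-0.5 windows — with the side effect, also seen in real data, that
  π rises inside the tracts. The uniform frequency spectrum is flatter
  than a neutral 1/j SFS; none of the estimators' expectations depend on
  that choice, only the variance of window values does.
* **Traits** evolve by Brownian motion: trait = intercept + slope ·
  predictor + residual, residuals multivariate normal with covariance σ²C
  (eigendecomposition handles PSD C that Cholesky rejects).

One integer seed determines everything; substreams are derived per stage,
chromosome and family (`default_rng([seed, stage, chrom, family])`), so
outputs are byte-identical across runs and partial re-runs are stable.

What passing tests on these simulations does *not* show: robustness to
annotation noise (false/missed repeat calls), ortholog inference errors,
tandem duplications breaking one-to-one anchors, alignment/reference bias
in genotypes (a known cause of depressed π on the non-reference species),
or non-uniform gene spacing. Detector thresholds were exercised only on
clean planted structure.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep full suites
in minutes: 10-Mb chromosomes and ~2e-4/bp TE rates (≈ 27% genome
coverage) for landscapes; 2,000 simulated inversions × 1,000 permutation
replicates for calibration, each inversion on its own freshly simulated
landscape so the hit count stays binomial (tests sharing one realized
landscape are positively correlated); 23 ancestral chromosomes of 12–34 Mb at 12
genes/Mb for the karyotype reconstruction; 200-kb all-sites genotype
blocks; 1,000 replicates for BM null calibration; every anchor
permutation of n ≤ 9 plus 200 random 15-anchor instances for the chaining
oracle.

## Known limitations

* Projection and junction estimates are anchor-resolved, not
  base-resolved; uncertainty is one local anchor spacing.
* The enrichment test conditions on one category at a time; no
  per-family tests and no covariate matching (GC, gene density) of null
  regions.
* The F_ST tract scan thresholds at a fixed 0.5; no significance is
  attached to tract calls.
* `detect_fusions` assumes the reference genome is approximately
  ancestral; reciprocal fusions in the reference would be read as
  fissions and are not modeled.
* The pipeline treats chromosomes independently; inter-chromosomal repeat
  correlations (e.g. shared centromeric families) are not simulated.
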