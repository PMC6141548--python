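# Methods

`circage` analyzes circular-RNA expression measured as back-splice junction
(BSJ) read counts across a multi-region brain design: 8 anatomical regions
(PFC, PCC, TC, PC, OC, CA1, DG, CB) × 2 sexes × 2 age groups (10 y, 20 y),
one pooled library per cell, 32 samples in total. This note records the
statistical model behind each stage, the defaults and why they were chosen,
and what the synthetic benchmark does and does not establish.

## Quantification and identity

A circRNA is identified by its exact back-splice locus
`(chrom, start, end, strand)`; the BSJ read count is its raw expression.
Internally every coordinate is 0-based half-open; the CIRI2 and GTF dialects
(1-based inclusive) are converted once at the I/O boundary. Per-sample calls
are unified across samples by exact locus match. Tolerant matching — the
±5 nt window used when comparing predictions from different detection tools
— is available separately (`annotation.match_circ_sets`) and is deliberately
not used for matrix assembly: silently merging near-identical loci would
make counts depend on file order. Strand `.` is treated as a wildcard only
in tolerant matching, where tools disagree about strand assignment.

## Genomic-context classification

A circRNA is *exonic* when both back-splice sites fall inside exons of one
same-strand gene; *intronic* when it overlaps a same-strand gene body but
fails the exonic test; *antisense* when only opposite-strand genes overlap;
*intergenic* otherwise. Precedence is exonic > intronic > antisense >
intergenic. The permissive exonic rule (sites *within* exons) is the
default because annotation of non-model genomes is incomplete;
`strict_boundaries=True` requires the sites to coincide with annotated exon
boundaries. A chromosome missing from the annotation degrades to
*intergenic* with a warning rather than an error.

## Expression filtering

Candidate calls need ≥ 2 junction reads in their sample. The analysis set
is then defined by a five-rule cascade on the count matrix: a sample
*expresses* a circRNA at ≥ 3 reads; an area is *expressed* with ≥ 2
expressing samples; keep if ≥ 2 areas are expressed (rule 3), or exactly
one area is expressed and ≥ 6 samples express overall (rule 4), or the
total count reaches ≥ 30 (rule 5). Rule 4's sample count spans all areas:
with 4 samples per area a within-area reading of "≥ 6" would be
unsatisfiable, so the cross-area reading is the only consistent one. The
kept set is the disjunction of the three routes; route labels are assigned
first-match in the order 3 → 4 → 5. Keeping is monotone in every cell, a
property the tests exercise directly.

## Normalization

Size factors follow the median-of-ratios estimator: for rows positive in
every sample, `s_j = median_i(k_ij / geomean_i)`. Rows containing zeros are
excluded because their geometric mean is undefined; the estimator therefore
requires at least one all-positive row and raises otherwise (run the
expression filter first). The median is taken on the ratio scale — the
literal formula — not as `exp(median(log ratio))`; the two differ whenever
the number of contributing rows is even. Note that only factor *ratios*
are identifiable: scaling one sample's counts by `c` multiplies its factor
by `c^((m-1)/m)` and divides the rest by `c^(1/m)`, because the per-row
geometric mean absorbs `c^(1/m)`.

Downstream tests operate on `log2(normalized + 1)` by default (variance
stabilization; `log_transform=False` gives the raw normalized scale).
Fold changes are `log2((mean₂ + ψ) / (mean₁ + ψ))` with pseudocount
ψ = 1 on the normalized scale.

## Specificity screens

All screens use the two-sided Welch t-test (unequal variances). Degenerate
inputs resolve deterministically: two constant groups with equal means give
(t = 0, p = 1); with unequal means, (±∞, 0). A paired variant tests matched
differences.

* **Spatial.** `one_vs_rest` tests each region's 4 samples against the
  other 28; a circRNA is called for a region when p < α (default 0.01) and
  the region mean is strictly higher, and is assigned to at most one region
  (smallest p; ties broken lexicographically). The stricter `vs_each` mode
  — "consistently higher than every other area" — additionally requires a
  pairwise Welch test against each other region (each p < α with a strictly
  higher mean) and is by construction a subset of `one_vs_rest`. The
  4-vs-28 one-vs-rest screen has a heavy null tail on log-count data
  (small-group variance estimates occasionally collapse, and log-NB values
  are mildly skewed), so at desk scale its raw-α calls carry many false
  positives; `vs_each` suppresses these because seven independent pairwise
  exceedances are required at once. Benchmarks that score spatial recovery
  therefore use `vs_each` at α = 0.05.
* **Sex / age bias.** Per-row Welch test between the two factor levels
  (16 vs 16), called at p < α (default 0.05); the enriched group is the
  higher-mean level. Raw-threshold calls mirror the screening convention of
  the study design; Benjamini–Hochberg q-values are emitted alongside, and
  recovery benchmarks score q ≤ 0.05 calls because at a fixed raw α the
  false-discovery proportion is set by the planted-effect prevalence, not
  by the method.
* **Permutation null.** The statistic is the difference of group means;
  one shared set of label permutations serves all rows;
  `p = (1 + #{|stat_perm| ≥ |stat_obs|}) / (1 + n_perm)` (add-one, so
  p ≥ 1/(n_perm+1) and is never 0). `exact=True` enumerates all label
  splits (refused above 200,000 splits). Default `n_perm` = 10,000;
  calibration tests use 2,000 for speed.

No multiple-testing correction is applied to `called` columns; q-values are
always available in the output tables.

## Co-expression modules

Unsigned weighted network: `a_ij = |cor(x_i, x_j)|^β` with cubic soft
threshold β = 3 (a signed option exists). Topological overlap

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with `1 − TOM` the clustering dissimilarity. Modules come from a single
average-linkage tree with a *static* cut — deterministic and oracle-testable,
unlike dynamic tree cutting; the trade-off is less adaptive module
resolution on real, large networks. `min_module_size` = 30 and
`cut_height` = 0.25 are conventional; the cut height is the one parameter
that genuinely depends on network density (benchmarks with three strong
planted modules use 0.6, since near-orthogonal inter-module profiles sit at
dissimilarity ≈ 1). Clusters below the size floor become module 0. The
module eigengene is the first right-singular vector across samples of the
row-standardized module submatrix, unit norm, sign-oriented to correlate
positively with the module's mean standardized profile; variance explained
is `s₁²/Σs²`.

## circRNA–host-mRNA correlation

Pearson correlation across the 32 shared samples between each circRNA and
its host gene's mRNA profile, with the two-sided p-value from the
t-transform with n − 2 df. Pairs with |PCC| ≥ 0.3 and p ≤ 0.1 — boundaries
inclusive, reading "no less than / no more than" literally — are classified
positive or negative. Zero-variance profiles are flagged undefined and
excluded from classification. Units cancel in correlation, so the mRNA
matrix may carry counts, FPKM or TPM; both matrices are log2(x+1)
transformed by the pipeline before correlating.

## Enrichment

One-sided upper-tail hypergeometric test, P(X ≥ k) for overlap k of an
n-draw from a universe of N with K successes. Terms are summed in log
space; log-binomials are computed from exact big-integer binomial
coefficients (`math.comb`), because log-gamma differences drift to ~1e-11
relative error near N = 17,050 while the package holds itself to 1e-12 on
the pmf-sum identity. Gene-set enrichment intersects each set with the
universe, skips empty sets, and applies BH across tested sets. Annotation
sources are plain two-column TSVs; no ontology databases are fetched.

## Synthetic data: what it emulates, and what it does not

`simulate_counts` draws `count_ij ~ NB(mean = λ_i s_j f_ij, dispersion α)`
with λ_i log-normal(μ = 4.0, σ = 1.0 on the natural-log scale; median ≈ 55
reads), library factors s_j log-normal(0, 0.2), and planted folds f. The
baseline describes a *filtered, well-expressed* circRNA set rather than the
raw candidate pool, which is dominated by 2–10-read loci. Dispersion 0.1 is
a typical bulk RNA-seq value. Default spikes: 50 CB- and 50 OC-enriched,
100 male-biased, 100 aged-biased rows, all fold 4 and mutually disjoint, in
2,000 rows. Host mRNA profiles are planted on the log2 scale as
`ρ·z + √(1−ρ²)·ε` against the standardized circRNA log profile, then
back-transformed with exp2 − 1 so `log2(x+1)` recovers ρ exactly at ρ = 1;
default 300 pairs each at ρ = +0.8, −0.8, 0.

The generator is exchangeable within factor levels: no region–sex–age
interactions, no batch structure, no count-level correlation between
circRNAs (except planted modules in `simulate_module_matrix`), no
detection-efficiency dependence on abundance, and no read-level error.
Passing recovery benchmarks therefore demonstrates that the screens are
correctly implemented and calibrated under the declared model — not that
real tissue yields those sensitivities, where unmodeled biological
covariance will lower them.

## Problem sizes and determinism

Benchmarks run at the native design scale (2,000 × 32; 2,000 permutations;
50 oracle instances; 1,000 toy filter matrices), which keeps the whole
suite under a minute on one CPU while leaving every statistical check at
full resolution. All randomness flows from explicit integer seeds;
the pipeline fans a single global seed into per-stage seeds via fixed
`SeedSequence` offsets, so identical configurations yield byte-identical
output tables.

## Known limitations

* Detection itself (CIRI2 / find_circ), alignment, and conservation
  analyses are out of scope; the pipeline starts from junction tables.
* The static tree cut can split or merge modules that dynamic cutting would
  resolve; module counts are not comparable across cut heights.
* Raw-α screening calls inherit the multiplicity behaviour of the original
  screening design; use the q-value columns for FDR-controlled sets.
* The exact permutation mode is limited to small designs by combinatorial
  growth.
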