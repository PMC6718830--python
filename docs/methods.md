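# Methods

This note documents the models, numerical choices and limitations of
the `tripathotype` pipeline, in the order the stages run.

## Pathotype classification

Biopsies are scored 0–4 for CD3, CD20, CD68 lining/sublining and CD138,
with CD20⁺ aggregates graded 0–3. The rules, in precedence order:

* **Lympho-myeloid (L)** — grade 2–3 CD20⁺ aggregates with CD20 ≥ 2,
  *or* CD138 > 2. The plasma-cell route (CD138 > 2 with no graded
  aggregates) is treated as sufficient for L on its own; this reading of
  the "and/or" is the only one that keeps plasma-cell-rich,
  aggregate-poor biopsies out of the myeloid class, and is exposed for
  sensitivity analysis simply by editing the rule.
* **Diffuse-myeloid (M)** — CD68SL ≥ 2 and CD138 ≤ 2 and (CD20 ≤ 1 or
  CD3 ≥ 1), and not L. The parenthesised disjunction is the only parse
  of the published "CD20 ≤ 1 and/or CD3 ≥ 1" that keeps M disjoint from
  L while still covering T-cell-containing myeloid biopsies.
* **Fibroid (F)** — CD68SL < 2 and CD3, CD20, CD138 all < 1.

Score combinations firing no rule return `ungraded`, a legal output:
the rules do not tile the full 5⁵×4 score lattice (e.g. CD68SL ≤ 1 with
CD3 ≥ 1 fires nothing). Ungraded samples are dropped pairwise from all
ordinal analyses. The inflammation ordinal is fibroid 0 < myeloid 1 <
lymphoid 2; shift = baseline − follow-up, so positive shift means the
tissue became less inflammatory, and ΔDAS28 = baseline − 6 months so
positive values mean clinical improvement. Shift–response association
is Pearson's r; a zero-variance shift vector yields a flagged degenerate
result rather than an exception. Shift-direction × ACPA tables use the
two-sided Fisher exact test.

## Cell-specific module derivation

The atlas is a genes × tissues matrix of normalized expression (the
shape of a CAGE primary-tissue panel). Where the input is feature-level
(several peaks per gene), only the feature with the highest mean across
tissues is kept; exact ties go to the lexicographically smallest
feature id. Each gene is Z-scored across tissues with **sample** SD
(n − 1) — the small-panel convention; this is configurable. Zero-variance
genes get an all-zero Z row and are ineligible for modules rather than
erroring, since housekeeping-like rows are expected. Tissue ranks per
gene break exact ties by higher value first, then tissue column order.

A gene joins the module of tissue *t* iff rank_t ≤ 3, Z_t > 5 and its
specificity score (tissues with Z > 3, including *t* itself — it always
qualifies when Z_t > 5) is < 10. All inequalities are strict/non-strict
exactly as printed. All four cut-offs are parameters.

## Eigengene scoring

A module's score vector is the first right-singular vector of the
row-centered module × sample submatrix, which is the standard eigengene
construction. Row-centering and the sign convention (score correlates
positively with the module-mean profile) are the two free choices of
that construction; both are fixed here so scores are reproducible and
comparable. Scores have unit norm. Module genes absent from the matrix
are dropped with a warning below 50% missing, an error at or above it.

The variance-stabilized input is `log2(count/size_factor + 1)` of
median-of-ratios-normalized counts. This preserves the normalized log
scale that a regularized-log transform produces but performs no
per-gene shrinkage; at the moderate counts of the synthetic cohorts
the difference is immaterial for rank-based statistics, and the
function is isolated so a different transform can be substituted.
Scoring is done per compartment.

## Three-group differential expression

Size factors are median-of-ratios (genes with any zero count excluded
from the ratios), rescaled so their geometric mean is 1; with no
all-nonzero gene the stage falls back to library-size normalization
with a warning.

Each gene is fitted with a negative-binomial GLM (log link, log size
factors as offset): full model `~ pathotype (+ covariates)` versus
reduced `~ (covariates)`. Fitting is IRLS, vectorized across genes
(shared design matrix; batched normal equations), with step-halving and
a likelihood-based convergence test; non-converged genes get missing p
and leave the FDR family. The linear predictor is clipped at ±30 and
p = 0 underflow at 1e−300 before −log₁₀.

**Dispersion** is a group-aware method of moments on normalized counts:
within each pathotype group the excess of the sample variance over the
offset-corrected mean estimates α·μ², pooled across groups with
(n_k − 1) weights, floored at 1e−8, and shared between the full and
reduced models. There is no empirical-Bayes shrinkage — a deliberate
simplification relative to DESeq2-class tools, adequate at the
synthetic effect sizes; an externally computed DE table can be imported
instead where shrinkage matters.

**Reference distribution.** The LRT statistic is referred to
F(df, n − p_full) via stat/df, not to χ²(df). With per-gene moment
dispersions at n = 10/group the χ² reference is visibly anticonservative
(an excess of small p values from dispersion-estimation noise); the F
reference — the standard quasi-likelihood small-sample correction —
restores a uniform null (Kolmogorov–Smirnov checked over 20 simulated
null cohorts) and converges to χ² as n grows. Pairwise two-group tests
are the same construction with df = 1, sharing the cohort's size
factors and dispersions.

BH FDR is the textbook step-up with monotone enforcement; missing p
values are excluded and returned missing. The q threshold is 0.05,
configurable.

**Color classes.** Per significant gene (LRT q < 0.05) the reference is
the group with minimum normalized mean (exact ties resolve F < M < L,
deterministically); a group is "up" versus the reference iff its
pairwise q < 0.05 *and* its log2 fold change versus the reference is
positive. One up-group → blue/red/green (L/M/F); two → purple (L+M),
yellow (M+F), cyan (L+F); a significant LRT with no up-call is logged
as an anomaly and left gray. The optional fold-change gate
(|log2FC| > threshold, default off) reflects the source convention
being ambiguous between "FDR < 0.05" alone and with a fold filter.

Cluster analysis of DE genes: Z-scaled rows, Euclidean distance, Ward
linkage, tree cut at k (default 4) clusters.

## Polar projection

Group mean Z scores (per-gene Z across all samples of the log
expression matrix, averaged within groups) feed

x = √3/2·(M − F), y = L − ½(M + F), θ = atan2(y, x) in [0, 360), r = √(x²+y²),

placing L/M/F at 90°/330°/210°. θ at the origin is defined as 0
(atan2(0,0) is implementation-defined). Adding a constant to (L, M, F)
leaves (x, y) unchanged; cyclic permutation rotates θ by −120°. The
fold-change radial mode (centered log2 group means) changes r and, in
general, θ as well — the two angles coincide only when folds are
proportional to centered Z differences — so the payload reports the
empirical median |Δθ| between modes instead of asserting equality
(≈7° on the default synthetic cohort). Colors are serialized with a
fixed hex map so payload tests can be bit-exact; the map is
configurable. Payloads are plain JSON; no plotting library is required
to validate them.

## Association statistics

Module–trait correlation is Spearman's rho with two-sided p,
pairwise-complete (never imputed), requiring ≥ 6 complete pairs; the
BH family is {all modules} × one trait × one compartment, matching
per-trait adjustment of a correlation heatmap column, and is
configurable to a global family. Concordance between compartments:
`both` needs q < 0.05 in both *with the same rho sign*; sign-discordant
dual-significant pairs are `neither`. Module annotation is the
upper-tail hypergeometric test P(X ≥ k) against user-supplied marker
sets within an explicit gene universe, BH-adjusted across labels.
Group comparisons of module scores (ACPA status, erosion progression,
EULAR response) use Welch's t with a pooled-SD standardized mean
difference; this preserves the contrast a variance-inflated gene-set
test (QuSAGE) evaluates while replacing its machinery with a
transparent statistic on the eigengene scores — a documented
divergence, validated against planted shifts.

## Synthetic data: what it emulates and what it does not

**Atlas.** Values are baseline + N(0, σ²) noise per tissue (σ = 1).
Each of the 135 tissues gets 10 markers elevated in its home tissue.
Because a single spike inflates its own row SD, the realized Z of a
spike of height Δ is capped at (n_t − 1)/√n_t; the generator therefore
solves Δ = E·σ/√(1 − E²/n_t) so the *realized* Z equals the requested
`marker_effect` (default 8), saturating gracefully for small panels
where E² ≥ n_t. 100 broad decoy genes are elevated in 11 tissues each
with a large offset, pinning their per-tissue Z near its multi-spike
ceiling ≈ √(n_t/11 − 1) ≈ 3.4: above the specificity threshold of 3 in
≥ 10 tissues (so the specificity criterion must exclude them) but below
the marker threshold of 5. The default panel size of 135 matches the
scale of the real primary-tissue panel; markedly smaller panels cannot
realize Z > 5 at all, which is a property of the criterion, not of the
generator.

**Cohort.** 65 samples (25 L / 20 M / 20 F) by default — the scale of
the real synovial cohort — with gene baseline means from a log-normal
grid (median 30, log-sd 1.2, floored at 1), uniform library-size
factors in [0.7, 1.4], and NB counts via gamma–Poisson mixing at a
single spec-level dispersion (default 0.1), matching the DE stage's
model assumptions. Six planted classes of 50 genes each (L, M, F, L+M,
M+F, L+F) get a log2 effect of 2 in their up-groups, drawn from
non-module genes. Per-sample module activities are standard normal;
module genes' means swing by 2^(activity) (amplitude 1 log2/SD).
Histology scores are sampled uniformly inside the rule region of each
sample's pathotype, plus 5% deliberate rule-gap (ungraded) samples so
every classifier branch is exercised. Clinical traits are affine
transforms of ρ_p·activity + √(1−ρ_p²)·noise with
ρ_p = 2·sin(π·ρ_s/6), the bivariate-normal inversion that makes the
planted *Spearman* correlation (default 0.5) analytically exact in
expectation; affine unit maps keep it so. Follow-up pathotypes step
down the inflammation ordinal with a rounded-Gaussian step
(mean 0.6, sd 0.9, clipped to the ordinal range) and
ΔDAS28 = 0.8 + 1.2·strength·shift + N(0, 1.5²), so shift and response
are coupled only when `response_strength` > 0.

One integer seed fans out to fixed per-generator substreams
(`default_rng([seed, k])`), so every generator is bitwise reproducible
and independent of the others.

**Not emulated:** read-level data, GC/length biases, batch structure
beyond an optional covariate column, gene–gene correlation outside
planted modules, outlier samples, and the real cohort's joint
distribution of histology, expression and clinic. Passing tests
demonstrate that the pipeline recovers what was planted under its own
model assumptions — not that the biological effect sizes of the real
cohort would be recovered.

## Problem sizes and determinism

Default analyses use 2,000 genes, 65–90 samples, a 2,000 × 135 atlas,
20 null cohorts for calibration checks and 50 cohort replicates for
association-recovery rates; these sizes make every stage and the whole
test suite run in seconds to a few minutes on a single CPU while
keeping the Monte-Carlo error of the reported rates small relative to
their acceptance margins. All numeric tables are written with a fixed
float format so identical configurations reproduce byte-identical
files; the pipeline manifest records SHA-256 hashes of all inputs and
outputs.

## Known limitations

* The NB GLM has no dispersion shrinkage and no outlier handling
  (Cook's-distance-style); very small groups rely on the F-reference
  calibration instead.
* The regularized-log stand-in under-stabilizes variance for genes with
  very low counts; rank-based downstream statistics are insensitive,
  variance-sensitive ones (the eigengene) are affected only through
  gene weighting within a module.
* The "CD138 > 2 alone implies lympho-myeloid" reading and the M-rule
  parse are documented interpretations of an ambiguous published rule;
  both are trivially editable and covered by the exhaustive-oracle test.
* `ungraded` is reachable by rule gaps; real-world unclassifiable
  biopsies may instead reflect tissue-quality failure, which the
  generator does not model.
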