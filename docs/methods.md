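# Methods

This note documents the models implemented in `cnvpairtwas`, the
synthetic-data generator they are validated on, the numerical choices,
and the limits of what the validation shows.

## The scientific question

A multi-genic CNV region associates with a trait, but association alone
cannot say whether the signal reflects (i) a single driver gene, (ii)
specific pairs of genes acting jointly, or (iii) a diffuse region-wide
contribution. The package probes these competing architectures with
genotype-based expression imputation: SNP-weight models predict the
genetically regulated expression of single genes and of pairwise "joint
genes", predicted expression is associated with the trait, and three
complementary analyses — variance-explained model comparison,
pair-membership composition, and a region-wide rank score — discriminate
among the architectures.

## Expression models

**Targets.** Single-gene targets are rank-based inverse-normal
transformed (INT) expression vectors; a pair unit's target is
`INT(e_A + e_B)` over the shared samples of one tissue. The INT
convention is `Φ⁻¹(r/(n+1))` with tie-averaged ranks; the same
convention is reused for all normalized ranks in the package so that
rank-based quantities are directly comparable. A pair whose expression
sum is constant is degenerate and skipped with a log record.

**Fitting.** Elastic net with mixing parameter α = 0.5 (the convention
of the standard TWAS weight databases), candidate SNPs from the unit's
cis window (±100 kb; pairs use the union of both members' windows),
intersected with an optional per-dataset SNP allowlist. Dosages are
standardized within the training panel; weights are stored on the
standardized scale together with each SNP's training mean/SD so that
prediction in any cohort is exactly reproducible. The penalty strength
is chosen on an automatic path (default 20–25 values) by seeded k-fold
cross-validation (default k = 10) minimising mean CV error.

**Performance estimate.** `cv_performance_r2` is the squared Pearson
correlation between *nested* out-of-fold predictions and the target:
the penalty is re-selected inside every training fold, and predictions
and target are demeaned within evaluation folds before the correlation.
Both details matter — with a shared fold split the estimate is strongly
anti-conservative on null targets (about half survive the default
filter), and without fold demeaning the per-fold intercept (the
complement folds' mean) is systematically anti-correlated with the
held-out target (|r| ≈ √(k/n)). With both corrections, pure-noise
targets pass the default filter (`R² > 0.01` and `p < 0.05`) at roughly
the nominal rate. Models that select no SNPs are kept as flagged empty
models and removed by filtering, never raised as errors.

## Association

* **Individual level.** Predicted expression is `Σ_l w_l · d̃_l` over
  model SNPs present in the cohort, with dosages harmonized to the
  model's effect alleles (`d → 2−d` on an allele swap; mismatched
  alleles are skipped, never imputed) and standardized by the training
  stats. Coverage (fraction of model SNPs found) is recorded and units
  below 50% are flagged. Per-tissue association is OLS of the trait on
  the prediction with covariates; binary traits use the linear 0/1
  coding so that effects stay on the variance-explained scale used by
  the model comparison. Cross-tissue combination follows the
  principal-component approach: PCs of the samples × tissues prediction
  matrix with condition-number cutoff λ_max/λ_i ≤ 30, F-test against
  the covariate-only model; the reported direction is the sign of the
  mean per-tissue univariate beta, which is what the meta-analysis
  consumes.
* **Summary level.** `z_unit = Σ_l w_l z_l / √(wᵀΓw)` on the
  standardized-dosage scale, with Γ the correlation of model SNP
  dosages in a reference panel and `z_l` harmonized GWAS z-scores; the
  cross-tissue statistic projects the per-tissue z vector on the
  eigenvectors of the reference tissue-correlation matrix (same
  condition-number cutoff) and sums squared scaled projections as a χ²
  with one df per retained component.
* **Meta-analysis.** Sample-size-weighted z-scores:
  `z_i = Φ⁻¹(1−p_i/2)·direction_i`, weights √n_i. `Φ⁻¹(1−p/2)` is
  evaluated as `−Φ⁻¹(p/2)` so extreme p-values stay finite; p = 0
  inputs are clamped to 1e−300 with a warning.
* **Permutation threshold.** Per control region the 5th percentile
  (linear interpolation) of its unit p-values, pooled per unit class
  (singles and pairs separately); the threshold is the median across
  regions. Because control units within a region share genes, the
  per-region percentile is noisy; the validation studies therefore use
  10–20 control regions, and the demo pipeline's 4-region threshold
  should be read as illustrative.

## Control-region matching

Candidates are contiguous gene windows (per chromosome, genomic order)
with exactly the target's gene count. All bounds inclusive: span within
80–120% of the target's length; coding:noncoding ratio at least 80% of
the target's (for a target with no noncoding genes the criterion
degenerates to "also none"); no overlap with the target, configured
exclusion regions, or previously accepted windows (greedy left-to-right
scan — whether published control sets could overlap each other is not
specified anywhere we know of, so non-overlap is this package's choice,
made to avoid pseudo-replication in the permutation null). The matcher
is deterministic and is tested against brute-force enumeration.

## Variance comparison

Per tissue-cohort pair, three designs with covariates: all single-gene
predictions (k = genes); all pairwise predictions (k = pairs); and the
interaction design — single-gene main effects plus one product of
standardized predictions per pair (a products-only design is available
behind a flag but is statistically incoherent as a default). Fit quality
is adjusted R², `1 − (1−R²)(n−1)/(n−k−1)`; rows with n ≤ k+1 are
excluded and logged. Winners are the argmax with ties broken
single > interaction > pairwise — deliberately conservative against the
pairwise hypothesis, and a probability-zero event for continuous
predictions. CNV-vs-control winner proportions are compared by Pearson
χ² without continuity correction on the 2×2 table
{CNV, control} × {pairwise-best, not}; a zero margin raises (the
experiment wrappers count such null-arm replicates as "no evidence",
p = 1).

Why can the pairwise design genuinely win? All three designs are linear
in genotypes, and with perfect models the pairwise predictions would lie
in the span of the singles. With finitely trained models they do not:
the pairwise design carries ~k²/2 independently trained, partially
independent views of each gene's genetic value, and the cohort-level
regression averages their training noise away, buying real signal that
more than offsets the larger adjusted-R² penalty at n = 5000. When
single-gene models are accurate (high cis-h², larger training panel) the
advantage disappears and single-gene traits hand the win back to the
parsimonious single design — both behaviours are asserted in the tests.

## Pair composition and the region-wide score

Significant pairs (meta p below the pair-class permutation threshold)
increment both members' counts; genes with zero appearances stay in the
denominator. A gene is flagged disproportionately over-represented when
its count strictly exceeds mean + 2.5 sample SD (ddof 1) of all region
genes' counts; with zero SD nothing is flagged. Boundary handling
(strict inequality, sample SD) is a documented convention of this
package. Single-gene significance flags and ranks (ascending p among
significant genes) annotate the same table.

The region-wide score: per gene, normalized rank of predicted expression
within each tissue, median across tissues with a retained model; the
per-individual sum of gene ranks is re-ranked to (0, 1]. The choice of
rank/(n+1) over rank/n is monotone-equivalent for every downstream test
and is shared with the INT. Quantitative traits: Pearson r and p. Binary
traits: two-sample Kolmogorov-Smirnov plus Welch t-test of case vs
control scores; the package reports both and leaves the significance
decision to the caller. Decile summaries sort by score and spread any
remainder over the lowest bins.

## The synthetic-data generator

The generator defines the study conditions for all validation; its
defaults are fixed once and shared by tests and the acceptance script.

* **Catalog.** One CNV region (default 8 genes, 75% coding, 600 kb) laid
  out in jittered slots rescaled to the declared span, plus background
  genes on 4 chromosomes with the *same* spacing distribution, so that
  control matching has realistic material. Biotypes: protein-coding at
  the configured fraction, the remainder drawn from
  lincRNA/pseudogene/antisense/miRNA.
* **Genotypes.** Per gene, `variants_per_gene` variants within ±5 kb of
  the gene body; MAF ~ U(0.05, 0.5). LD is a block compound-symmetric
  latent-Gaussian copula (blocks of 5, ρ = 0.3, never spanning genes):
  per haplotype a latent normal is thresholded at Φ⁻¹(MAF) and two
  independent haplotypes are summed to a 0/1/2 dosage. This is a
  deliberately controllable stand-in for real LD maps; it exercises
  elastic-net SNP selection but does not reproduce human LD block
  structure, allele-frequency spectra, or imputation noise.
* **Expression.** Per gene, 3 causal variants drawn from the gene's own
  proximal (±10 kb) variants — a broad causal window would place
  "causal" variants at neighbouring genes and blur the single-gene
  architecture, while model *training* still searches the full ±100 kb
  cis window so decoy SNPs remain. Per-gene cis heritability
  h² ~ U(0.1, 0.8) (gene-to-gene variation in predictability is what
  makes the pair-quality "in-between" property informative: the pair
  target's genetic fraction is approximately the mean of its members').
  Tissue t's causal weights are √s·shared + √(1−s)·specific with
  s = 0.7, so the between-tissue expression correlation is ≈ h²·s.
  Observed expression is genetic value + Gaussian noise, INT-ed per
  (tissue, gene).
* **Traits.** "True expression" of a gene in a GWAS cohort is its true
  genetic value plus fresh environmental noise at the gene's h². The
  mediator is that expression for `single_gene`; `INT(e_A + e_B)` for
  `gene_pair` (tissue-specific, as joint genes are); and the
  standardized sum over member genes of their *cross-tissue average*
  expression for `regionwide` (the region-wide architecture is a
  tissue-agnostic deviation of the whole segment). Quantitative traits:
  `y = √es·m + √c·covariates + √(1−es−c)·ε`, so the realized variance
  explained matches the requested effect size; binary traits threshold
  the same liability at the (1−prevalence) normal quantile. Covariates
  default to age, age², and 5 synthetic PCs with a small (2%) total
  contribution. GWAS summary statistics come from per-variant linear
  regression with covariates — also for binary traits (0/1 coding),
  keeping the variance-explained convention consistent across the
  package; a logistic alternative was considered out of scope.

## Validation studies and problem sizes

The studies in `cnvpairtwas.validation` (shared by the test suite and
`scripts/acceptance.py`) use cohorts of 2000–5000, training panels of
300–500, 3 tissues, and 10–20 control regions; the larger studies use
5-fold CV with a 15-value penalty path, and the pairwise study trains
models once per simulation block (4 blocks × 5 trait replicates) — these
sizes keep a full run near ten minutes on one CPU while leaving every
measured rate well inside its target band. Where the stage under study
is not model fitting itself (threshold calibration, hub composition),
units are oracle weight models derived from the generative truth, or
random sparse weight models for pure null calibration — any linear
genotype combination is a legitimate unit there, and this isolates the
stage being validated; elastic-net behaviour has its own study. The hub
study draws the hub from the more-heritable half of the region's genes
and pairs it with 10 partners at effect 0.03 (n = 3000): the hub's
mediator share is k/(k+1) against 1/(k²+k) per partner, which puts hub
pairs far above the permutation threshold and partner spillover below
it.

**What passing does and does not show.** The synthetic universe has no
population structure, no relatedness, no real LD, no expression
confounding (PEER-style factors are assumed already removed), perfectly
aligned variant identifiers, and no missing genotypes. Passing therefore
validates the statistical machinery and its calibration under the stated
generative models — not robustness to the data pathologies of real
cohorts.

## Known limitations

* Binary-trait association uses linear models on 0/1 by design;
  odds-ratio-scale effects are out of scope.
* The permutation threshold inherits the high variance of a 5th
  percentile over correlated units; with few control regions it can be
  lenient (the demo) and should be used with ≥10 regions.
* Pair and region-wide analyses assume the training panel and cohorts
  share variant identifiers and alleles up to swaps; strand ambiguity
  (A/T, C/G) handling is not implemented.
* The region-wide score weights all genes equally; no tissue weighting
  or extreme-tail-only scoring is attempted.
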