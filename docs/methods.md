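# Methods

## Model

`plscova` quantifies the shared structure between two subject-aligned
blocks: a genetic block `X` (n × p; SNP alternate-allele counts in
{0,1,2}, or transcript TPMs) and a phenotype block `Y` (n × q; either 7
imaging-derived global therapeutic-need values, one per modality and
modality combination of grey-matter density, resting functional activity
and dopaminergic integrity, or 5 longitudinal motor-score slopes: tremor,
bradykinesia, rigidity, axial and total). After preprocessing, both
blocks are column-standardised, so

    R = XᵀY / (n − 1)

is a p × q matrix of Pearson correlations. The thin SVD `R = U S Vᵀ`
yields `K = min(p, q, n − 1)` component pairs; the columns of `U` and `V`
are unit-norm saliences (feature weights), subject scores are `X u_k` and
`Y v_k`, and component k explains the fraction `σ_k² / Σ_j σ_j²` of the
total squared cross-correlation ("explained covariance"; the blocks are
standardised, so covariance and correlation coincide).

The decomposition assumes rows are independent subjects and that the
association of interest is linear in the transformed variables. It makes
no sparsity or distributional assumption on the saliences; with p ≫ n
the leading components are still well-defined because `R` has rank at
most n − 1.

Sign convention: SVD signs are arbitrary, so each pair (u_k, v_k) is
flipped to make the largest-magnitude entry of `u_k` positive. This keeps
bootstrap replicates, sensitivity re-runs and repeated fits comparable.
In all supported analyses q ≤ 7, so the thin SVD of the p × q matrix is
O(p q²) in time and O(p q) in memory and no special large-p code path is
needed; the test suite verifies the engine against an independent
eigendecomposition of `RᵀR` at 1e-10.

## Preprocessing

Order of operations per analysis (each step feeds the next):

1. **Complete-case intersection.** Subjects present with complete data in
   the genetic block, phenotype block and covariate table, sorted by
   subject id. Missing genotypes are retained at read time and handled
   only here (complete case); the study data's handling of missing calls
   is not specified anywhere we could follow, and complete case is the
   conservative default.
2. **Non-variable filtering.** Zero-variance genetic columns are dropped
   (they carry no association information and cannot be standardised).
3. **Covariate normalisation.** Continuous covariates are Box-Cox
   transformed (profile-likelihood λ searched on [−5, 5]; columns with
   min ≤ 0 are shifted by 1 − min first) and z-scored. Binary covariates
   (sex, handedness, drug dummies) are z-scored only — a two-point
   distribution has no shape for a power transform to correct.
4. **Phenotype normalisation.** Genotype analyses rank-transform the
   phenotypes (average ranks on ties) then z-score — ranks are robust to
   the discrete genotype distribution on the other side of the
   cross-product. Expression analyses use Box-Cox + z-score on the
   phenotypes instead.
5. **Covariate removal.** Each phenotype column is regressed on the
   normalised covariates with a Huber M-estimator (tuning constant 1.345,
   IRLS, coefficient tolerance 1e-8, max 50 iterations — the default
   robust regression of mainstream statistics stacks) and replaced by
   intercept + residuals. The genetic block carries no covariates. An
   OLS route is available (`covariate_method="ols"`) and makes the
   residual exactly orthogonal to the covariate span.
6. **Re-standardisation.** Adjusted columns are z-scored again so the
   cross-product is exactly a correlation matrix. This re-scaling is
   exposed rather than hidden because it is one of the genuinely open
   choices: residualisation changes column variances, and without
   re-scaling the decomposition would weight phenotype features by their
   residual variance.

### Clinical derivations

- **Motor subscores.** The 33 MDS-UPDRS part III items are partitioned
  into tremor (10 items), bradykinesia (12), rigidity (5) and axial (6)
  following the standard clinical grouping, plus total = sum of all 33.
  The map ships as YAML configuration, not code, and any partition can be
  substituted; the partition property (subscores sum to the total) is
  enforced by test.
- **Treatment-response slopes.** Per subject and subscore, the
  least-squares slope of score against time, in years since the
  subject's first included on-medication visit (slopes are
  scale-equivariant, so the time unit only affects reporting). Subjects
  with fewer than 3 on-medication assessments are excluded and logged.
  All on-medication visits enter the fit, including baseline.
- **Absolute levodopa response (aLR).** OFF-state total minus ON-state
  total at visits with paired assessments; positive = improvement under
  drug. Longitudinal aLR summaries reuse the slope fitter.
- **LEDD.** Levodopa-equivalent daily dose = Σ dose × frequency × factor
  over a subject's PD medications, matched by case-insensitive keyword.
  COMT inhibitors contribute no dose of their own but multiply the
  concurrent levodopa equivalents (entacapone ×1.33, tolcapone/opicapone
  ×1.5). The conversion table (levodopa 1.0, controlled-release 0.75,
  pramipexole 100, ropinirole 20, rotigotine 30, rasagiline 100,
  selegiline oral 10, amantadine 1.0, apomorphine 10) follows the widely
  used published factors and is fully user-overridable YAML.

## Inference

- **Permutation FWE (default B = 1000).** Rows of the preprocessed `Y`
  are permuted, X fixed: this preserves each block's internal covariance
  and the covariate adjustment while destroying only the X–Y link, which
  is the exchangeability target. Familywise error over components is
  controlled by the max statistic: per permutation the maximum σ² across
  components is recorded, and `p_k = (1 + #{max_b ≥ σ_k²}) / (B + 1)`,
  never below 1/(B+1). B ≥ 100 is enforced (p-resolution).
- **Added explained covariance.** Observed PC1 explained-covariance
  percentage minus the mean of the per-permutation top-component
  percentages; reported in percentage points. It is a descriptive effect
  size, not a test statistic; under the null its expectation is slightly
  negative (an observed max is compared against the mean of maxima).
- **Bootstrap feature significance (default B = 1000, 95% percentile
  CI).** Subjects resampled with replacement jointly in both blocks; the
  resampled blocks are re-standardised, decomposed, and the replicate
  component is matched to the original by maximal |inner product| of
  y-saliences, then sign-aligned — without this alignment, axis swaps and
  sign flips inflate the SE. Per feature: SE = sd across replicates,
  ratio = original salience / SE, CI = percentile interval; a feature is
  significant when its CI excludes zero (the ratio is reported
  alongside). Resamples with fewer than 10 unique subjects are redrawn.

## Synthetic data

`simulate_joint_dataset` plants a rank-K cross-block structure: latent
subject factors `z_k ~ N(0,1)` drive a continuous genetic block
`X* = Σ_k effect_k z_k u_kᵀ + noise`, which is discretised per SNP by
quantile thresholding at Hardy-Weinberg proportions `(1−f)² : 2f(1−f) :
f²` for a minor-allele frequency `f ~ U(0.05, 0.5)` — discretisation
attenuates but preserves the planted direction, matching the discrete
genotype distributions of real arrays. Expression is the softplus of an
analogous latent block (non-negative, TPM-like scale). Phenotypes are
`Y = Σ_k effect_k z_k v_kᵀ + covariates·coefs + noise`, with covariates
drawn at realistic cohort values (age ≈ N(62, 10) years, ~50% male,
education ≈ N(14, 3) years, 90% right-handed, baseline motor score ≈
N(21, 9), LEDD ≈ N(450, 200) mg clipped at 0). Defaults: n = 294
subjects (a baseline cohort with genetic, clinical, medication and
demographic data), planted SNP saliences 5% sparse, effect size 3,
noise sd 1. A single master seed is split deterministically per
sub-generator; identical seeds give bit-identical data.

`simulate_longitudinal_clinic` (default n = 216, 5 yearly visits) draws a
true yearly slope per subject and subscore from N(1, 1); each item in a
group carries an equal share of the group slope so the group sum follows
the planted trend exactly, item noise is N(0, 0.3) and scores are clipped
to the 0–4 item range, with baselines placed to make clipping rare. It
can emit paired OFF assessments (OFF total = ON total + 8 by default) and
per-subject levodopa logs whose implied LEDD is returned as truth.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: linkage-disequilibrium block structure
(correlation between SNPs arises only through the planted factors),
population stratification, negative-binomial RNA-seq count noise,
informative missingness, visit-schedule irregularity, and floor/ceiling
effects beyond simple clipping.

## Numerical choices and edge cases

- Box-Cox λ by `scipy` profile likelihood, clipped to [−5, 5]; constant
  columns are an error (cannot be standardised).
- Collinear covariates raise an error naming the dependent columns rather
  than silently dropping one.
- Tied |saliences| in feature ranking keep stable feature order.
- `p_FWE` uses the add-one estimator, so it is never 0.
- Genomic coordinates are 1-based inclusive internally; BED input is
  converted on read, and SNP→gene overlap is strict containment with 0 bp
  tolerance at both ends. Strand is ignored (the rule is purely
  positional). A SNP inside several genes maps to all of them, and each
  mapped gene counts once per significant-SNP query.
- Enrichment: one-sided hypergeometric tail with Benjamini-Hochberg
  adjustment across sets; the query must be a subset of the universe, and
  set members are intersected with the universe before testing.

## Verification problem sizes

The acceptance checks run at deliberately compact sizes chosen to give
stable Monte-Carlo estimates on a single CPU: 50 random small blocks for
the SVD-vs-eigendecomposition oracle; 200 null datasets (n = 100, p = 50,
q = 7, 199 permutations) for rejection-rate calibration; 20 planted
rank-1 datasets (n = 200, p = 200, q = 7, dense saliences, effect 8) for
signal recovery; 5 sparse-support datasets (5% nonzero weights, 200
bootstrap draws) for feature discrimination; 1000 random visit records
for the subscore partition; and 30 random configurations on universes
≤ 25 genes for the hypergeometric oracle.

## Known limitations

- No sparse or regularised PLS variant; with very large p the leading
  saliences spread estimation noise over all features, and feature-level
  inference relies entirely on the bootstrap.
- The permutation test assumes exchangeable subjects; family structure
  or batch effects would need restricted permutation schemes.
- Huber residualisation leaves exact covariate orthogonality only in the
  outlier-free limit; the OLS route is exact.
- The added-explained-covariance quantity is reported as defined
  (observed minus permuted mean) and should not be read as out-of-sample
  validated variance.
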