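# Methods

## The problem setting

A PRS built by pruning and thresholding (P+T) on European-trained GWAS
summary statistics keeps, per LD block, the SNP with the strongest
marginal association. In the training ancestry that SNP is usually an
excellent tag for the causal variant; in a target ancestry with shorter
LD it may tag nothing. The package's premise is that per-SNP regulatory
scores from tissue-specific functional models concentrate causal
variants in their upper percentiles, so partitioning SNPs by functional
score — and letting partitioned heritability decide *which* tissues are
trait-relevant — yields models that port better across ancestries.

## Stratified LD-score regression

For SNP j and annotation C, the stratified LD score is
`ℓ(j,C) = Σ_k a_C(k) r²(j,k)` over SNPs k within a physical window on
the same chromosome (self-term included; monomorphic SNPs contribute
r² = 0; r² is the pairwise-complete squared Pearson correlation of
reference-panel dosages). The regression

    E[χ²_j] = intercept + N_j Σ_C τ_C ℓ(j,C)

is fit by two-step weighted least squares: an unweighted pass predicts
per-SNP χ², then weights `1 / (max(ℓ_base, 1) · pred²)` absorb both LD
overcounting and heteroskedasticity. Uncertainty comes from a
delete-one block jackknife over 200 contiguous SNP blocks (reduced to
`⌊M/50⌋` on small panels). The standardized effect

    τ*_C = τ_C · sd(a_C) · M / h²_total ,   h²_total = Σ_C τ_C Σ_j a_C(j)

is the proportional change in per-SNP heritability per standard
deviation of annotation value. Its significance follows the reference
convention: the standardizing factor is a plug-in constant, so
`z(τ*) = τ/se_jack(τ)` with a two-sided normal p-value. Jackknifing the
full ratio instead would roughly double the standard error under real
enrichment (τ and ĥ² co-vary across blocks) without improving null
calibration, which we verified by simulation. Enrichment
(`prop. h² / prop. SNPs`, membership = nonzero annotation) and its
jackknife SE are reported alongside.

Candidate tissues must satisfy `τ* > 0` and `p(τ*) < 0.05 / 51`
(Bonferroni over the tissue models; the divisor follows the number of
tracks supplied).

Window choice: the operation-level default is 1000 kb, appropriate for
human-scale panels; the pipeline default is 50 kb, matched to the LD
decay length of the synthetic panels (blocks span 100 kb with
correlation decaying as 0.95^distance). A window much wider than the
true LD range only adds panel-sampling noise to ℓ.

## Clumping and block sampling

Clumping is the standard greedy algorithm: rank by ascending p (ties by
position then rsID), absorb unassigned SNPs with `r² ≥ 0.2` within
250 kb of each successive index variant. SNPs above the p-value ceiling
or monomorphic in the panel are carried as one-SNP blocks.

Block sampling enforces **at most one SNP per LD block in the cumulative
model, across iterations**: a block already represented contributes
nothing; otherwise the index variant is taken if it lies in the
requested partition, else the partition member with the smallest GWAS p.
The cross-iteration scope is deliberate — a per-call rule would not
prevent over-sampling a block over successive refinement steps.

## Scoring and regression models

Scores are raw weighted allele counts (not per-allele averages): the
score enters regressions as a covariate whose scale is absorbed by its
coefficient. Missing dosages contribute exactly zero (no
frequency-based imputation). Alleles are harmonized to the cohort's
counted allele (sign flip on swaps; strand-ambiguous A/T and C/G SNPs
dropped). The 370-member threshold grid is log-uniform on `[1e-5, 1]`
— the count and range are fixed, the spacing is this package's choice,
chosen to resolve the genome-wide-significance region.

The null model regresses the phenotype on intercept, age, sex, ten
principal components and an independently-optimized coding-region PRS;
binary traits use the same ordinary-least-squares machinery on the 0/1
outcome (observed scale, no liability transformation). Adjusted R² uses
`1 − (1 − R²)(n − 1)/(n − p − 1)` with p counting all non-intercept
columns. Nested comparisons use the ANOVA F test (a zero-information
addition yields F = 0, p = 1); non-nested comparisons use the
Davidson–MacKinnon J test — the challenger's fitted values appended to
the current design, two-sided t test on that coefficient, p = 1 with a
warning when the fitted values are collinear with the current design.
Both tests hold their nominal 5% size in simulation (checked over 2000
null replicates each). The per-iteration selection α is 0.05.
Bootstrap confidence intervals for ΔR² resample individuals with
replacement (1000 draws, percentile method), redrawing degenerate
resamples.

## The iterative loop

Candidates are computed once, at entry, and reused across iterations
(refitting the stratified regression on residual SNP sets each
iteration is neither defined nor affordable; the option exists in the
API by passing fresh fits). Each tissue maintains a bin cursor starting
at its top 0.1% bin. Per iteration, each candidate tissue offers its
highest unconsumed bin (cursors skip bins emptied by block-sampling
saturation — emptiness is monotone because the model only grows);
candidate models are the merged cumulative SNP set scored over the full
threshold grid; the chosen threshold therefore applies to the whole
cumulative set. Only the winning tissue's cursor advances. The loop
ends when no candidate passes its selection test with a positive gain,
or at `max_iterations` (default 200; the acceptance study caps at 30).

Fast path: per-iteration grid search uses QR-residualized projections
(each candidate threshold costs O(n)); the winning model's logged
numbers are recomputed through the ordinary model-fitting API, and a
property test asserts the two paths agree.

## The synthetic study generator

The generator emulates the study design, not population genetics:

* **Genotypes.** SNPs sit in equal LD blocks; within a block, latent
  Gaussians follow an AR(1) with population-specific correlation
  (train ρ = 0.95, target ρ = 0.4), thresholded at each SNP's
  allele-frequency quantile; a dosage is the sum of two independent
  haplotypes. Blocks are independent; positions are 10 kb apart, so a
  10-SNP block spans 100 kb. MAF is uniform on (0.05, 0.5) — common
  variants only.
* **Effects.** `n_causal` SNPs carry fixed-magnitude standardized
  effects `±sqrt(h²/n_causal)` with random signs: every causal SNP
  carries an equal heritability share, the model against which
  annotation enrichment is defined. (A Gaussian effect-size law adds
  β⁴ dispersion to the χ² regression residual that at desk scale
  swamps the tissue signal the method depends on.)
* **Annotations.** Raw scores are Beta(1, 4). In each causal tissue,
  causal SNPs draw their score *quantile* from `q = 1 − u^a` with
  `a = ln(0.01)/ln(min(1, enrichment·0.01))`, so the chance of landing
  in the top 1% of the distribution equals `enrichment × 0.01` with a
  graded decay below — e.g. at 20× enrichment the top 1/5/10% of the
  distribution hold about 20/35/45% of causal SNPs, mirroring the
  concentration profile real tissue scores show. Draws are stratified
  (one per equal-mass stratum, randomly assigned) so every realization
  carries the nominal profile. When `enrichment·0.01·n_causal` exceeds
  the top bin's capacity `0.01·M`, rank competition necessarily caps
  realized occupancy — dense architectures cannot exhibit extreme
  bin-level enrichment, which is arithmetic, not a generator defect.
  Non-causal tissues score independently of causal status, and
  quantile normalization erases any marginal-shape differences.
* **Phenotypes.** Liability = standardized genetic value scaled to
  variance h², plus small fixed age and sex effects (0.05 each) and
  N(0, 1 − h²) noise. Binary traits threshold the empirical liability
  at 1 − prevalence and subsample controls to exactly
  `⌊ratio⌋ × n_cases` (default 4:1). PCs are computed per cohort from
  that cohort's standardized dosages (our populations carry no shared
  structure that pooled PCs would capture; real analyses should supply
  their own).
* **GWAS.** Per-SNP marginal least squares; χ² = t²; the reported
  p-value is the 1-df χ² tail of t², keeping both summary-statistic
  dialects mutually consistent to well below any analysis tolerance.

What the generator does **not** emulate: recombination-map LD,
admixture, allele-frequency divergence between populations (variant
metadata is shared), genotyping error, annotation spatial smoothness,
cross-tissue score correlation, and effect-size heterogeneity between
ancestries (causal effects are identical in both populations — exactly
the regime in which causal-variant prioritization should help). Passing
tests therefore show the machinery behaves as designed under shared
causal architecture with differing LD; they do not certify performance
on real cohorts.

## Study conditions for the shipped analyses

The default `SimConfig` — used by the test suite's portability study
and by `scripts/acceptance.py` — is M = 15,000 SNPs in 1,500 blocks,
GWAS N = 8,000, training cohort 4,000, target cohort 2,000, LD panel
500, h² = 0.7, 1,500 causal SNPs, 51 tissue tracks with two causal
tissues at 20× enrichment. These sizes are a deliberate desk-scale
rendition: large enough that stratified LD-score regression has the
power it enjoys at biobank scale (detection of both causal tissues at
the Bonferroni gate), small enough that a 20-seed replication study
runs on one core. The loop is capped at 30 iterations in those runs.

## Numerical choices and degenerate inputs

* Ties in quantile normalization get average ranks; bin boundaries
  break ties by rsID, so binning is seed-independent.
* Weights floor the predicted χ² at 1e-3; the baseline ℓ floor is 1.
* Collinear annotation or design columns raise errors naming the
  offending columns; all-zero design columns are tolerated (zero
  coefficient, counted in p, F = 0 ⇒ p = 1).
* Clumping r² comparisons use a 1e-12 tolerance so r² = threshold
  absorbs; permuting input rows never changes the result.
* PCs use exact SVD up to 600 samples/SNPs and a seeded randomized
  range-finder (4 power iterations) above; a fixed sign convention
  (largest-magnitude loading positive) makes runs identical.
* `h²_total ≤ 0` makes proportion-of-h² undefined (error); a fit whose
  every τ is zero leaves τ* = 0 by convention.

## Known limitations

* The stratified regression assumes the χ² expectation is linear in the
  annotations; indicator architectures violate this mildly and the
  jackknife absorbs the misspecification into wider SEs.
* Observed-scale analysis of binary traits; no liability-scale h².
* The J test is asymptotic; at very small n its size drifts (the suite
  checks n ≥ 300).
* One-chromosome geometry in the generator; the LD-score and clumping
  code handle multiple chromosomes, but the shipped studies do not
  exercise them.
* `block_rho_target` applies to the target population only; panels are
  always drawn from the training population, matching the design where
  the LD reference must represent the GWAS ancestry.
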