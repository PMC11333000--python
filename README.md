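# titr — functionally-informed trans-ancestral polygenic risk scores

Polygenic risk scores (PRS) trained on large European GWAS cohorts
transfer poorly to other ancestries: the tagging SNPs that carry the
strongest association signal in the training population sit on LD blocks
that look different in the target population, so their weights no longer
track the underlying causal variants. Prioritizing SNPs by *functional
regulatory evidence* instead of raw association strength selects variants
that are more likely causal — and causal variants port across ancestries.

This package implements that programme end to end for statistical
geneticists who want to build and stress-test such models:

* **Partitioned heritability.** For each of up to 51 tissue-specific
  regulatory score tracks, stratified LD-score regression fits
  `E[χ²_j] = 1 + N Σ_C τ_C ℓ(j,C)` and reports the standardized
  per-annotation effect `τ*_C = τ_C · sd(a_C) · M / h²`, with
  block-jackknife uncertainty. Candidate tissues pass the gate
  `τ* > 0, p(τ*) < 0.05/51`.
* **Functional pruning and thresholding (P+T).** Tracks are quantile
  normalized, cut into 1000 percentile bins (0.1% resolution), and
  partitioned at the top 1/5/10/20/50%. Greedy PLINK-style clumping
  (`r² = 0.2`) defines LD blocks; block sampling draws at most one SNP
  per block, preferring index variants, then the most significant
  partition member. Scores are raw weighted allele counts
  `score_i = Σ_j β_j d_ij` over 370 log-spaced p-value ceilings in
  `[1e-5, 1]`, with missing dosages contributing zero.
* **TITR — iterative tissue refinement.** Each iteration offers every
  candidate tissue's highest unconsumed 0.1% bin, block-samples new SNPs
  against the cumulative model, tests each candidate (tissue × threshold)
  model against the current model — ANOVA for the nested first step, the
  Davidson–MacKinnon J test afterwards — and merges the significant
  candidate with the greatest adjusted-R² gain. Validation scores every
  iteration's cumulative SNP set in the target-population cohort.
* **Synthetic two-population studies.** A block-latent-Gaussian
  generator produces genotypes with strong training-population LD
  (ρ = 0.95) and weak target LD (ρ = 0.4), annotation tracks whose top
  percentiles are enriched for causal SNPs in designated tissues,
  quantitative or 4:1 control:case binary phenotypes, and marginal GWAS
  summary statistics — so every claim above can be tested against a
  known truth.

## Worked example

```python
from titr import pipeline
from titr.ldops import clump
from titr.ldsc import select_candidates
from titr.simulate import SimConfig, simulate_study

cfg = SimConfig(seed=7)          # default two-population study conditions
study = simulate_study(cfg)

tc = pipeline.TitrConfig(max_iterations=30)
fits = pipeline.fit_tissue_sldsc(study.gwas_stats, study.panel, study.tracks, config=tc)
print("candidate tissues:", select_candidates(fits, n_tissues=len(study.tracks)))

clumps = clump(study.gwas_stats, study.panel)
state = pipeline.run_titr(study.gwas_stats, study.panel, study.train,
                          study.train_phenotype, study.train_covariates,
                          study.tracks, config=tc, clumps=clumps, fits=fits)
pipeline.validate_titr(state, study.gwas_stats, study.target,
                       study.target_phenotype, study.target_covariates)
```

This prints (seed 7; the study plants `adipose` and `pancreas` as the
causal tissues):

```
candidate tissues: ['pancreas', 'adipose']
iterations accepted: 27  model SNPs: 359
final training gain dR2 = 0.1336
final target-population dR2 = 0.0950
 iteration   tissue  bin  p_threshold  n_added  delta_r2_train  delta_r2_valid
         1 pancreas    1     0.417442       15        0.008729        0.008538
         2 pancreas    2     0.417442       15        0.008018        0.017695
         3 pancreas    3     0.417442       15        0.007965        0.020912
         4  adipose    1     0.855558       15        0.004474        0.020901
         5  adipose    2     0.882672       13        0.006314        0.021726
```

Heritability partitioning recovered exactly the two planted tissues; the
loop then alternates between them, consuming one 0.1% score bin per
iteration. `delta_r2_train` is each accepted step's gain in adjusted R²
over the previous model in the training cohort; `delta_r2_valid` is the
cumulative model's gain over the covariate-only null in the
target-population cohort — 0.095 after 27 iterations, versus 0.046 for
the single-tissue top-1% model on the same data.

The same workflow is available from the shell:

```bash
titr simulate --config sim.yaml --out study/
titr clump    --sumstats study/gwas.scoring.tsv --panel study/panel --out clumps.tsv
titr run      --study study/ --out log.tsv
titr validate --study study/ --log log.tsv --out validated.tsv --plot trace.png
```

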