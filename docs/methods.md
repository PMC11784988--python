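# Methods

## The score

The methylation profile score of C-reactive protein (MPS-CRP) is the
epigenetic analogue of a polygenic score: for sample *i* with beta
values β<sub>ij</sub> ∈ [0, 1] and external EWAS weights w<sub>j</sub>,

    S_i = Σ_j w_j · β_ij,

summed over whichever weight probes the sample's array carries (no
intercept, no re-weighting of missing probes).  Raw scores are
Z-standardized within each array subcohort (450K and EPIC dialects; the
two subcohorts are disjoint by design), and every downstream analysis is
run per array and pooled by inverse-variance fixed-effects
meta-analysis.  Two panels are supported: a 7-probe main score and a
~150-probe extended panel sharing 6 of the 7 main probes.  The packaged
weight tables are **synthetic stand-ins** (filenames say so): they
reproduce the scale and sign structure of published CRP EWAS weights but
are not the published values, which this package has no licence to
redistribute.  Users with access to the published tables can drop them
in as 2-column TSV files.

## Synthetic cohort generator

The paper-equivalent data are not shareable, so every stage is exercised
on a generator whose defaults *are* the study conditions: 2,338 dyads
split 1,367 / 971 across arrays, cord serum CRP left-censored at
0.2 mg/L with a 94 % below-limit target, granulocyte-dominant cord-blood
cell mixtures, plate batch structure, item-level prenatal exposures, and
repeated brain (2 occasions) and CBCL (5 occasions) outcomes.

Generative model for the beta values of probe *j* in sample *i*:

    β_ij = Σ_c p_ic R_jc  +  d_{plate(i),j}  +  λ_j η_i  +  ε_ij,   clipped to [0, 1]

* **Cell mixture.** p<sub>i·</sub> ~ Dirichlet(α) with α =
  (22, 3.5, 2, 4.5, 2.5, 1.5, 4) over (granulocytes, monocytes, B,
  CD4T, CD8T, NK, nRBC): granulocyte-dominant with realistic spread
  (concentration ≈ 40).  R is the probe × cell-type mean-beta profile
  matrix; reference probes get strongly discriminating profiles
  (uniform on [0.05, 0.95]) so deconvolution is well posed, score and
  filler probes vary gently around a common mean (SD 0.15 across cell
  types).  That spread makes estimated cell proportions the largest
  single driver of score variance, the qualitative structure reported
  for cord blood.
* **Batch.** Plate effects d ~ N(0, 0.01²) per (plate, probe);
  12 plates by default.
* **Latent inflammation.** η is standard normal and is itself a linear
  combination of the Z-scored cumulative exposure scores,
  η = Σ_s b_s z_s + resid, so prenatal exposures act on the score
  through inflammation.  Probe loadings are proportional to the EWAS
  weights, λ_j = a·w_j / Σw², which makes the weighted score correlate
  positively with η by construction.
* **Effect-size calibration.** Effects are configured on the scale the
  analysis reports: standardized β of the Z-scored score per SD of each
  predictor.  Because Var(S) = Var(M) + a² (M = the non-inflammation
  part of the weighted sum, orthogonal to η), setting
  a = sd(M)·√(r²/(1−r²)) gives inflammation exactly the configured
  variance share r² (default 0.2), and b_s = t_s/√r² makes the
  standardized coefficient of score *s* equal the target t_s.  sd(M) is
  measured on the realized draw, so the calibration holds per
  replicate.  Defaults use the reported effects as generating truth:
  lifestyle → MPS 0.033; MPS × age −0.014 SD/yr (global FA),
  +0.016 (amygdala), −0.007 (cerebellum); MPS main effect −0.085
  (cerebellum).
* **Serum CRP.** log cord CRP = μ + σ(ρ·η + √(1−ρ²)ε) with σ = 3.0,
  ρ = 0.7 and μ derived from the below-LOD target:
  μ = log(0.2) − σ·Φ⁻¹(0.94).  Values under the limit are recorded *at*
  the limit with a below-LOD flag, as clinical laboratories report
  them.  The heavy log-scale SD reflects the extreme skew of cord CRP;
  with these defaults the score-CRP association lands in the reported
  ranges (rank correlations ≈ 0.2, AUC ≈ 0.7 against the > 1 mg/L
  cut-off).  Maternal (two occasions) and child age-5 CRP load on the
  polygenic score (ρ = 0.25), not on cord inflammation — reproducing
  the reported specificity pattern (the PGS tracks maternal/child serum
  CRP but not cord CRP; the MPS tracks cord but not maternal CRP).
* **Outcomes.** Brain and CBCL outcomes follow random-intercept models,
  y_it = u_i + γ·age_c + θ_main·z_i + θ_age·z_i·age_c + e_it with
  Var(u) = Var(e) = 0.5 on the (z or sqrt) analysis scale, where z_i is
  the generator's own Z-scored realized score — so configured θ are
  recoverable by the analysis without attenuation.  Volumes additionally
  load (share 0.15) on a head-size factor observed as ICV.  CBCL scales
  are generated on the square-root scale (location 4.0, secular slope
  −0.08/yr) and squared, so the analysis' sqrt transform recovers
  linearity.
* **Missingness.** Probe- and covariate-level MCAR masks are injected
  *after* generation (rates configurable, 0 by default) so ground truth
  stays complete; a MAR-style stress test can be built by masking on
  observed covariates.

What the generator does **not** emulate: array-specific probe dropout
(both arrays carry the full panel by default; probe-skipping is still
implemented and tested with manually restricted panels), probe-intensity
normalization artefacts, genotype structure beyond a PGS column + 10
PCs, non-MCAR attrition, and measurement covariance between exposures
and covariates.  Passing recovery tests therefore demonstrates that the
statistical machinery is correct under the declared model — not that
real cord-blood data meet that model.

## Analysis pipeline

* **KNN probe imputation** (k = 10 by default, the cited
  implementation's default): neighbours are *probes*, distances are
  pairwise-complete mean squared differences; probes missing in every
  sample or in > 80 % (colmax) of samples are dropped; samples missing
  > 50 % (rowmax) are column-mean filled; imputed values are clipped to
  [0, 1].
* **Deconvolution**: per sample, min ‖β_ref − R p‖² s.t. p ≥ 0,
  Σp = 1, solved exactly by an active-set method on the KKT system
  (vectorized equality-constrained fast path, per-sample active set
  only where nonnegativity binds).  One cell type is dropped from every
  model design matrix to break the simplex collinearity.
* **Exposure scores**: infection = mean over trimesters (with any
  observed item) of per-trimester counts; stress = sum of 4 domain sums
  over 52 items (identical to the 52-item total); lifestyle / pregnancy
  / medical = cumulative 0/1 counts.  Missing items make a score
  missing; chained-equations imputation happens at *item* level and
  scores are passively re-derived in each completed dataset, never
  rescaled to available items.
* **PGS**: Z-scored, regressed on 10 genetic PCs within genotyping
  subsample, residuals re-standardized before merging (which also makes
  the operation idempotent).
* **Collinearity pruning**: pairs with |r| > 0.9 drop the
  lower-priority member; the declared priority puts the medical-
  conditions score last, matching the analytic choice made when it
  tracked the pregnancy-conditions score at r > 0.9.
* **Validation**: CRP binarized at > 1 mg/L (strict; below-LOD = 0);
  AUC by exact midrank Mann-Whitney with the Hanley-McNeil SE (no
  threshold grid); Spearman correlations per occasion with censored
  values entering at the LOD constant (a documented limitation — the
  ties sit where the censoring does); tiered OLS (univariate / + batch
  / + batch + cells) per array, IVW-pooled.
* **Mixed models**: REML random-intercept fits per array, three forms
  (main, × age, × age × gestational age, gestational age continuous),
  outcomes Z-scored (brain) or sqrt-then-Z (CBCL), age centred at the
  per-outcome mean occasion age.  Non-convergence is reported in a
  `converged` flag, never silently dropped; boundary (zero) intercept
  variance is reported as such.  ICV enters only the brain-morphology
  sensitivity refits.
* **FDR**: Benjamini-Hochberg within each (aim × model-form) family
  across outcomes; per-CpG screens form their own family.
* **Meta-analysis**: fixed effects, w = 1/SE²; Cochran's Q reported
  informationally, never used to switch estimators.  Pooling operates
  on standardized per-stratum betas (each stratum Z-scored internally),
  which is what makes it scale-coherent.
* **Multiple imputation**: chained equations with Bayesian-linear
  (continuous), logistic (binary) and ordered (ordinal) conditional
  draws; defaults m = 30 / 60 iterations match the emulated analysis;
  the pipeline and tests run m = 5 / 5-10 iterations as their stated
  problem size.  Rubin's rules with the Barnard-Rubin observed-data df
  adjustment; B = 0 degenerates to the within-imputation variance.  The
  score and brain outcomes are never imputed.
* **Variance partition**: LMG/Shapley decomposition of the linear-model
  R² over predictor groups (each prenatal score, PGS, cell
  proportions), exact subset enumeration up to 10 groups, seeded
  permutation sampling refused beyond that without an explicit seed;
  residual = 1 − R² so fractions sum to one.

## Numerical choices

Active-set deconvolution tolerances: 1e-10 primal, 1e-8 dual.
Z-scoring uses the n−1 denominator everywhere.  Near-zero residual SD
(< 1e-10) in PGS residualization skips the final rescale rather than
amplifying floating-point noise.  A score column with literally zero
variance in one stratum is skipped there with a logged warning and the
term is estimated from the remaining stratum.  Logistic conditional
draws clip the linear predictor at ±35 and fall back to a ridge fit
under separation.  Stage seeds derive from the global seed as
`(seed·1000003 + crc32(stage)) mod 2³¹`.

## Problem sizes used by the tests and the acceptance script

Unit tests run cohorts of 80-300 dyads with 50-80 reference probes.
Recovery tests use the criterion-scale sizes: n = 2,300 × 500
replicates (aim-1 lifestyle effect), n = 1,400 × 200 replicates
(aim-2 age interaction), n = 300 × 500 replicates (null calibration),
n = 500 × 1,500 replicates (MI coverage).  The acceptance script runs
the full pipeline once at n = 2,338 with 1 % probe and 3 % covariate
missingness, m = 5 imputations × 5 iterations.

## Known limitations

Single-draw quantities reported by the acceptance script (AUCs, pooled
betas) carry the sampling noise of one cohort draw at n = 2,338; e.g.
the pooled lifestyle beta has SE ≈ 0.017 around its generating value
0.033.  The censored-at-LOD treatment of CRP in correlations
understates association strength (no Tobit model, by scope).  The
generator's exposures are mutually independent, so collinearity pruning
never fires on default draws; it is exercised on constructed data.
Mixed models fit random intercepts only — no random slopes or growth
curvature.
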