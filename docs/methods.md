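# Methods

`longbatch` implements, end to end, the statistical workflow for removing
measurement-batch effects from two-time-point (baseline BL, follow-up FU)
microarray expression data while preserving biology, in the setting where a
subset of baseline RNA aliquots was re-hybridized at follow-up. Those
re-measurements give three technical-replicate groups per subject —
BL_rep (extracted BL, measured BL), BLFU_rep (extracted BL, measured FU) and
FU_rep (extracted FU, measured FU) — so that BL_rep vs BLFU_rep isolates the
batch effect and BLFU_rep vs FU_rep isolates five-year biology.

## Synthetic cohort generator

Real cohort data of this design are typically not public, so the package
ships a seeded generator whose output has the structure every stage assumes.
Per probe *g*, subject *s* and measurement *m* (log2 scale):

    Y = mu_g + u_gs + t_g·1[extraction = FU] + f_g·1[batch = FU]
        + beta_g·phenotype_s + c_chip(m) + eps,   eps ~ N(0, sigma_t^2)

* **Baselines** `mu_g = 6.0 + Exponential(1.2)`: right-skewed, most probes
  weakly expressed, as on real arrays. Negative controls sit in a background
  band around 5.0 and receive no subject, time-point or phenotype terms.
* **Batch shift** `f(x) = floor + (amp − floor) / (1 + exp((x − x0)/w))`,
  monotone non-increasing in the probe's reference intensity *x*, with
  `amp = 1.2` log2 (weakly expressed probes more than 2-fold higher in the
  later batch), `floor = 0.3` log2 (a small global upward shift of the later
  batch, visible as a density shift), `x0` the lower tertile of the
  baselines, `w = 0.5`, and a per-probe lognormal jitter (sigma 0.2) so the
  shift is not perfectly deterministic. The floor is what makes nearly all
  probes differentially expressed between replicate batches before
  correction, which is the regime the evaluation is calibrated against; a
  pure sigmoid would leave mid/high-intensity probes untouched and the
  uncorrected data implausibly clean.
* **Variance scales** (log2 units): subject profiles `u ~ N(0, 0.3^2)`,
  five-year drift `t ~ N(0, 0.1^2)` (the magnitude of true longitudinal
  drift is a free parameter; 0.1 keeps its variance share at the few-percent
  level), technical noise sd 0.15, chip intercepts sd 0.03 with 12 samples
  per chip.
* **Identity probes**: one female-specific probe (high ≈ 10 in females,
  ≈ 5 in males), one male-specific probe (reversed), and one
  polymorphism-in-probe SNP probe with genotype means 6.5 / 8.8 / 9.9
  (AA/AG/GG, minor-allele frequency 0.47, Hardy-Weinberg draws).
* **Mix-ups**: `n_mixups` subject pairs of opposite sex (different genotype
  preferred) have the contents of their FU-extraction columns swapped, so
  both identity detectors can fire.
* The `truth` record keeps the realized per-probe shifts, phenotype betas,
  swap pairs and an exact per-source variance bookkeeping (mean over probes
  of each additive component's column variance).

What the generator does **not** emulate: probe-sequence effects, intensity
saturation, spatial/bead-level artifacts, RNA-degradation gradients,
correlated gene modules, non-Gaussian heavy-tailed noise. Tests passing on
this generator show the pipeline's statistical machinery is correct under
the stated model, not that any particular real dataset is clean.

## QC cascade

Order: array filters → shared probes → detection → expressed-probe filter →
mix-up removal. Defaults are the published thresholds.

1. **SNR filter**: 95th/5th percentile of raw-scale intensities (linear
   interpolation quantiles); arrays kept only if SNR > 6. The ratio is
   computed on 2^(log2 values) because percentile ratios are scale
   dependent.
2. **Mean-level filter**: within each measurement batch, drop samples whose
   mean log2 expression deviates more than 3 batch SDs from the batch
   mean-of-means.
3. **Shared probes**: both matrices restricted, in annotation order, to
   probes flagged on both chip versions (probe-ID based; sequence identity
   computation is out of scope).
4. **Detection calling**: empirical tail probability against the sample's
   own negative-control distribution with the +1/(n+1) correction,
   `p = (1 + #{controls ≥ x}) / (1 + #controls)`; detected ⇔ p < 0.05.
   Samples with fewer than `min_detected_probes` detected probes are
   excluded; the default is the published 6000, which is meaningful only
   when more probes than that are measured — desk-scale runs on 2,000
   simulated probes set it explicitly (the examples use 500).
5. **Expressed probes**: kept when the detected fraction is strictly above
   10% in the BL batch *and* in the FU batch. Negative-control and identity
   probes are retained regardless, because RUV and the mix-up detectors need
   them.
6. **Mix-up detection**: per subject, the BL−FU difference *d* of each sex
   probe and of the SNP probe; a subject is flagged when
   |d − mean(d)| > 3·SD(d) (strict). The two sex probes are screened
   independently and then the SNP rule runs on the full set; flags are
   merged per subject with detector labels. SD = 0 flags nothing (the band
   is empty only by degeneracy).

**Quantile normalization** (optionally preceding any correction) is done
separately per batch: each column's sorted values are replaced by the mean
of the group's sorted columns; ties receive the average of their target
positions, so within-column ranking is preserved exactly.

## Correction methods

The regression family is fitted on the technical-replicate pairs — all
within-subject BL_rep × BLFU_rep column combinations (Cartesian product,
e.g. 2×3 = 6 pairs per subject), pooled over probes — and then applied by
mapping every BL-batch value through the fitted curve.

* **Deming**: closed-form errors-in-variables line; `lambda` is the
  var(eps_y)/var(eps_x) ratio, default 1 (orthogonal regression).
* **Passing-Bablok**: exact shifted median of all pairwise slopes (slopes of
  −1 and undefined slopes excluded, offset K = #{slopes < −1}), computed on
  probe-wise means per batch. The exact enumeration is used rather than the
  quantile-binned large-n approximation; at probe-mean scale (thousands of
  points) this is cheap and exact.
* **Linear mixed model**: BLFU_rep ~ BL_rep with a random intercept per
  subject (REML, bfgs optimizer; OLS fallback with a warning on singular
  fits). Only the fixed effects rescale the data.
* **Polynomial**: cubic least squares with subject indicator covariates;
  only the four polynomial coefficients are kept.
* **qspline**: per BL column, 99 quantile anchors (levels 0.01…0.99) paired
  with the pooled mean distribution of the BLFU_rep columns; anchor targets
  are isotonically repaired and interpolated with a monotone cubic (PCHIP),
  so the mapping is monotone by construction. Outside the fitted range the
  mapping continues linearly with the boundary slope (logged).
* **ComBat** (parametric empirical Bayes, intercept-only design):
  standardize per gene by the weighted grand mean and pooled residual
  variance (so batch effects satisfy the weighted zero-sum constraint);
  estimate per-batch per-gene location/scale on the standardized scale;
  shrink locations toward a normal prior and scales toward an inverse-gamma
  prior with method-of-moments hyperparameters; iterate the posterior
  fixed-point to 1e-4 (cap 500); restore. Scale estimates use the MLE (1/n)
  denominator, which makes duplicated identical batches an exact no-op;
  the difference from the n−1 convention is O(1/n) and the implementation
  agrees with the Bioconductor reference to < 0.05 log2 units at batch
  sizes in the twenties (regression-tested). Genes that are constant
  overall pass through with a warning; genes constant *within* every batch
  but offset *between* batches (a per-batch quantile-normalization artifact
  at rank-stable extremes) receive the location-only limit of the
  adjustment — batch means mapped to the grand mean — since passing a pure
  batch offset through uncorrected would contradict the method's purpose.
* **ReplicateRUV**: center the BL-aliquot replicate columns (BL_rep +
  BLFU_rep, per subject) within their replicate group; the top-k right
  singular vectors of the stacked centered matrix are the unwanted-factor
  loadings; per-sample scores come from least-squares projection of each
  sample's negative-control values onto the control-restricted loadings;
  subtract scores × loadings everywhere. Default
  k = min(n_samples // 4, median replicates per BL aliquot) (5 for the
  shipped design). Score estimation for non-replicate samples by
  control-gene projection is an assumption; refitting against the
  replicate span is the plausible alternative.

## Evaluation suite

* **Differential expression**: per-probe Welch t-test between BL_rep and
  BLFU_rep (the test behind the published counts is unstated; Welch is the
  robust default for 35-vs-43 unequal groups), with Benjamini-Hochberg and
  Bonferroni control at 0.05. Probes whose within-group spread is at
  floating-point scale relative to their level (SD ≤ 1e-9 × value) are
  compared by their means at the same tolerance instead of a raw t — after
  exact mean equalization the remaining 1e-15 dust is not evidence.
* **PVCA**: PCA on row-centered data (no probe scaling); retain the
  smallest leading-PC set reaching the variance threshold (default 0.60);
  decompose each retained PC's sample scores with a random-intercepts
  variance-components model (measurement batch, extraction time point,
  subject) fitted by an in-house EM-REML — monotone, non-negative by
  construction, robust at zero-variance boundaries where general-purpose
  mixed-model optimizers mis-attribute variance — with a method-of-moments
  fallback; normalize per PC, weight by eigenvalue share among retained
  PCs, sum. Note that at the 0.60 threshold the retained PCs of strongly
  structured data contain almost no noise directions, so the residual share
  is structurally underestimated there; recovering a configured residual
  share requires a threshold near 1 (the parameter-recovery test uses
  0.99).
* **Dendrogram classification**: complete-linkage clustering of Euclidean
  column distances (linkage unstated in the source; complete linkage is the
  classical default of the referenced routine family). Per subject:
  *correct* if all its replicates form a pure subtree, *partly correct* if
  some pure subtree holds ≥ 2 of them from both batches, else *incorrect*.
* **Pair proximity**: in `n_iterations` (default 22) draws of
  `subset_size` (default 50) subjects, cluster their BL+FU columns and
  count subjects whose two columns merge as immediate dendrogram siblings
  (strictest reading of "direct proximity"); a looser same-flat-cluster
  mode (`mode="flat"`, tree cut into `subset_size` clusters) is available
  for sensitivity analysis.
* **Bland-Altman**: per-probe (mean, difference) between two samples.
* **Phenotype association**: per probe, expression ~ sex + age + phenotype
  with a random chip intercept (REML); p-values use a t reference with
  residual degrees of freedom rather than the asymptotic normal, which is
  anti-conservative at n ≤ 100 and breaks BH null calibration; BH over all
  probes. Association scans are meant to run within one measurement batch
  (each subject once) — with both time points included the subject
  correlation invalidates the standard errors. Concordance between two
  scans is the Pearson correlation of betas and of log10 p-values.

## Pipeline, seeds, problem sizes

`run_pipeline` chains simulate → qc → correct → evaluate; one global seed is
expanded into fixed per-stage substreams so toggling a stage never perturbs
another stage's randomness, and the manifest (config hash, per-stage
dimensions, results) is reproducible from (inputs, config, seed) alone.

Shipped problem sizes: the replicate design at 15 subjects × 2,000 probes
(132 columns, 100 negative controls) and cohorts of 60–200 subjects ×
300–2,000 probes; these are desk-scale stand-ins chosen so the full suite
and the acceptance script run in minutes while keeping every effect in the
regime the method comparison probes (uncorrected replicate batches >90%
differentially expressed; corrected, zero).

## Known limitations

* The generator's batch effect is additive per probe given the probe's
  reference intensity; ComBat's location-scale model is therefore exactly
  well-specified, and the advantage of prior quantile normalization is
  correspondingly small on synthetic data (it shows up as slightly tighter
  empirical-Bayes shrinkage, not as the qualitative rescue seen on real
  distribution-shape artifacts).
* Passing-Bablok is exact but O(n²) in input points; it is intended for
  probe-wise means, not raw pooled pairs.
* EM-REML for PVCA converges slowly near variance-component boundaries; the
  iteration cap (300) leaves components near zero slightly positive, which
  only matters in the third decimal of a proportion.
* Mixed-model associations loop over probes; at tens of thousands of probes
  a dedicated vectorized solver would be needed.
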