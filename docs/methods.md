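# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Pipeline and ordering contracts

The pipeline operates on a samples × 89-assay matrix of absolute miRNA
abundances (copies·µL⁻¹). Stage order is enforced by state flags on the
matrix container and matters scientifically:

1. **Replicate averaging** (reference primaries of one patient → arithmetic
   mean per miRNA) happens *before* normalization, so a duplicated patient
   does not count twice in centroid estimation.
2. **50th-percentile normalization** divides each sample by its own median
   over the full 89-miRNA panel. Control assays (SNORD44, SNORD48, snRNAU6,
   UniSp3, UniSp6) never enter normalization — small-RNA reference genes are
   more variable across FFPE samples than the panel median, so the median
   itself is the normalizer. Normalization precedes assay exclusion: the
   median is panel-wide, and only afterwards are the two contaminated /
   non-specific assays dropped.
3. **Assay exclusion** removes miR-122-5p (its signal in liver-site biopsies
   reflects the liver microenvironment, not the tumor) and miR-21-5p
   (ubiquitously expressed in solid tumors, non-specific), leaving 87
   prediction features.
4. **log2(x + 0.01) transform.** The classifiers operate on log-scale
   features; the pseudocount 0.01 is far below one copy·µL⁻¹ on the
   normalized scale, keeps zeros finite and preserves the ordering of low
   values. Switchable off for linear-scale experimentation.

Class labels are merged 19 → 17 before training (STAD + CRC → STAD-CRC,
KIRC + KIRP → KICA): those pairs are not separable by their miRNA patterns
and are predicted as single classes. The map is idempotent and surjective
onto the 17 prediction classes.

## Nearest shrunken centroids

Implemented from scratch (see README for the formulas). Choices the method
description leaves open, with our defaults:

- `m_k = sqrt(1/n_k − 1/n)` and `s0 = median_j s_j` — the canonical NSC
  standardization. At the working threshold Δ = 0 these affect probability
  calibration, not feature selection; both are visible on the results
  object.
- Class priors default to empirical training frequencies; `priors="uniform"`
  is available. Probabilities use softmax of −δ/2 with max-subtraction.
- Pooled SD uses the n − K denominator; a class with fewer than 2 samples is
  a hard error naming the class.

At Δ = 0 the classifier is exactly a diagonal-covariance Gaussian
discriminant with variances (s_j + s0)²; the test suite verifies agreement
with an independently coded Gaussian oracle to 1e−10.

## Multinomial lasso

Objective: mean multinomial negative log-likelihood + λ·Σ|β| (intercepts
unpenalized) in the symmetric K-class parameterization, features
standardized internally (population SD). Optimization is glmnet-style:
outer cycles over classes, each building a weighted quadratic approximation
(weights p(1−p) floored at 1e−5) solved by cyclic coordinate descent with
soft thresholding; one full sweep establishes the active set, then cheap
active-set sweeps polish it. A step-halving line search keeps the penalized
objective monotonically non-increasing (verifiable via
`fit(track_objective=True)`). Convergence: max parameter change < 1e−6
(default) within 10⁴ outer iterations; non-convergence is reported on the
results object, not raised. Optimality is checked by the KKT conditions
(`kkt_violation()`), and the λ = 0 limit is tested against an unpenalized
reference optimizer.

The working penalty λ = 0.019 is interpreted on the mean-log-likelihood
scale. How many features survive at that penalty depends on the training
cohort (on synthetic cohorts it is typically 60–75 of 87); only the penalty
mechanism, not a specific support size, is asserted.

Threshold selection by stratified K-fold cross-validation is provided
(`cross_validate_threshold`); ties in CV error resolve to the larger
threshold, i.e. the sparser model.

## Prediction rules

Sex filtering zeroes TGSC/PRAD for females and OV/UCEC for males and
renormalizes; unknown sex passes through. Prioritization thresholds (0.80,
0.30) are strict inequalities. "Present among the predicted sites in both
models" is implemented as membership in both top-2 lists; a class with
probability > 0.30 that is outside one model's top-2 does not qualify under
rule B — the narrower of the two possible readings, flagged here because
the broader one is also defensible. Ties in top-2 extraction break
alphabetically, making every report deterministic.

## Bootstrap evaluation

Error rates are out-of-bag: each replicate resamples the training set with
replacement stratified within class (so no class vanishes from a
replicate), refits, and scores first-choice misclassification on the
left-out samples. Per-class errors pool counts over replicates; the overall
error is the pooled sample-weighted rate. Resamples are driven by the seed
alone, so two model specifications evaluated with the same seed are
compared on identical resamples (paired comparison). Resubstitution
("apparent") error and unstratified resampling are available by flag.
Out-of-bag was chosen over resubstitution because it is approximately
unbiased at 100 replicates and produces the per-class error structure the
workflow reports.

## Survival screening

Per miRNA: Youden-type cutoff (midpoints of consecutive sorted unique
values; the orientation maximizing sensitivity + specificity for vital
status; ties → lowest threshold), dichotomization, Kaplan-Meier + log-rank,
univariate Cox HR (Breslow ties) with 95% Wald CI. Kaplan-Meier, log-rank
and Cox go through lifelines (with tightened Newton convergence); the
cutoff search and screening workflow are this package's own. A monotone
partial likelihood (no events in a group) is flagged rather than raised.

Interpretive choices: the ROC outcome variable is vital status at end of
follow-up — the only per-patient status available. Significance is raw
p ≤ 0.05 with no multiplicity correction, matching the workflow this
package re-implements; a Benjamini-Hochberg q column is emitted alongside
for transparency. Because the Youden cutoff is selected using the outcome,
p-values at ROC-derived cutoffs are optimistic (the minimum-p-value
problem); `cutoff_method="median"` provides the selection-free variant, and
the type-I calibration tests use it so that what is being calibrated is the
testing machinery, not the selection bias.

## Synthetic-data generator

What it emulates:

- **Log-normal abundances.** ddPCR copies are positive and right-skewed;
  class identity lives in log2-scale mean shifts. Sample i of class k has
  abundance 2^(μ_kj + ε), ε ~ N(0, σ_j).
- **Class structure.** All classes share a baseline mean vector (per-miRNA,
  drawn once from Uniform(2, 10) log2 copies·µL⁻¹ — the working range of
  the assay); each class up-shifts a disjoint block of 5 discriminant
  miRNAs by `class_separation` (default 2 log2 units). The excluded assays
  are never discriminant, so class signal survives preprocessing. Overlap
  between discriminant sets (the confusable-pair phenomenon, e.g.
  CHOL↔PAAD) can be emulated by passing custom profiles.
- **Noise scale.** `sigma_within` defaults to 0.5 log2 units, so the default
  separation equals 4 within-class SDs on discriminant miRNAs. This is the
  generator's definition of a "well-separated" cohort: it makes the design
  property that a separation-2, 5-per-class cohort is solvable (≥ 95%
  held-out accuracy) hold with margin, while keeping within-class spread in
  a realistic range for FFPE material. At σ = 1 the same cohort is *not*
  solvable at n = 5 per class — centroid-estimation noise in 87 dimensions
  dominates — which is a useful hard regime reachable by config.
- **Cohort shape.** 17 classes × 5 primaries by default (the small-n regime
  of real reference cohorts, 3–7 per class). Sex is assigned consistently
  with class (TGSC/PRAD male, OV/UCEC female, otherwise Bernoulli(1/2)).
- **Liver contamination.** Metastases biopsied from the liver have
  miR-122-5p multiplied by `liver_spike_factor` (default 50) — the
  microenvironment artifact that motivates excluding that assay.
- **Multi-metastasis patients.** Assignments share a patient id and hidden
  origin class; sex is drawn once per patient.
- **Survival.** Event times are exponential with hazard
  h0·∏_m HR_m^{g_m}, where g_m indicates expression above the sample median
  of driver miRNA m. h0 = 1/12 month⁻¹ puts the median OS on the CUP scale
  (months, not years); its value is irrelevant to HR recovery. Default
  drivers: miR-124-3p (HR 0.11), miR-375 (HR 9.6), miR-27b-3p (HR 2.6) — a
  strongly protective, a strongly adverse and a moderate effect, the
  spectrum a prognostic screen should detect. Censoring is an independent
  exponential race calibrated to the requested censoring fraction (default
  0.2) at baseline hazard.

Everything is a deterministic function of the config seed (per-operation
substreams), and bit-reproducibility is tested.

What it does **not** emulate — and hence what passing tests do not show
about real data: cross-miRNA correlation within a sample (real miRNA
programs are co-regulated; here residuals are independent), heavy-tailed or
zero-inflated dropout of low-abundance assays, batch/plate effects and
inter-site variability, classes that are *intrinsically* overlapping rather
than separated-by-construction, non-proportional hazards, and informative
censoring. Recovery results on this generator certify the correctness of
the estimators and rules, not clinical performance.

## Problem sizes in the test suite

The suite exercises: 100-replicate held-out recovery (17 classes × 5,
separation 2) for both classifiers; 100-replicate bootstrap on the training
cohort; survival calibration on 3 null cohorts of n = 200 (median-split
screen of all 89 assays) and 100 replicates of HR = 3 recovery at n = 200;
and 30 multi-metastasis clone patients for concordance. These sizes give
Monte-Carlo error comfortably below the asserted margins while keeping the
default test run fast.

## Known limitations

- The NSC probability calibration at Δ = 0 depends on the s0 offset; ranking
  (and hence top-2 and final calls) is insensitive, but absolute posterior
  values should not be over-interpreted.
- The lasso's symmetric parameterization is the glmnet convention; at λ = 0
  exactly, coefficients are only identified up to a shift (probabilities
  are identified, and only they are asserted).
- `optimal_cutoff` is O(n²) in unique values per miRNA — fine at cohort
  scale, not at biobank scale.
- The hand-rolled complete-linkage clustering is O(n³) and intended for
  class-profile dendrograms (tens of leaves), not sample-level clustering of
  thousands.
- "Manhattan correlation distance" in the emulated workflow's description
  conflates two metrics; plain Manhattan (L1) is the default and
  1 − Pearson correlation is available by config. No claim is made about
  which was intended.
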