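# mirtoo

miRNA-based tissue-of-origin (TOO) prediction and prognosis for cancers of
unknown primary (CUP).

Metastatic cancers of unknown primary site cannot be treated with
site-specific regimens because the primary tumor eludes the diagnostic
workup. Metastases nonetheless retain tissue-specific microRNA expression,
which survives formalin fixation far better than mRNA. `mirtoo` implements,
as a tested pipeline, a diagnostic workflow built on absolute miRNA
quantification by droplet digital PCR (ddPCR) of an 89-assay panel: each
tumor sample yields a vector of copies·µL⁻¹ over the panel, and two
independent classifiers trained on a reference set of primary tumors from 17
tumor classes infer the most probable site(s) of origin of a metastasis. A
companion survival module screens the panel for miRNAs whose dichotomized
expression stratifies CUP overall survival.

The package is aimed at computational biologists who want to reproduce,
stress-test or extend this class of workflow. Because ddPCR cohorts of this
kind are not publicly deposited, a first-class synthetic-data generator
emulates the statistical structure of such a cohort (small per-class sample
sizes, log-normal abundances, liver-microenvironment contamination of
miR-122-5p, patient-level replicate metastases, expression-driven hazards),
so every stage is testable end to end.

## The models

**Nearest shrunken centroids (NSC).** For class $k$ and miRNA $j$ with class
centroid $\bar x_{kj}$, overall centroid $\bar x_j$, pooled within-class SD
$s_j$ (offset $s_0 = \mathrm{median}_j\, s_j$) and $m_k = \sqrt{1/n_k - 1/n}$,
the standardized deviation

$$d_{kj} = \frac{\bar x_{kj} - \bar x_j}{m_k\,(s_j + s_0)}$$

is soft-thresholded, $d'_{kj} = \mathrm{sign}(d_{kj})\,(|d_{kj}| - \Delta)_+$,
moving centroids toward the overall centroid. A sample $x$ is scored by the
discriminant $\delta_k(x) = \sum_j (x_j - \bar x'_{kj})^2/(s_j+s_0)^2 -
2\log\pi_k$ and class probabilities are $\propto e^{-\delta_k/2}$. The
working threshold is $\Delta = 0$: no feature is dropped and the rule is a
diagonal-covariance Gaussian discriminant over all 87 prediction miRNAs.

**Multinomial lasso.** The second classifier minimizes

$$\tfrac1n \sum_i -\log p_{y_i}(x_i;\beta_0,\beta) \;+\; \lambda \sum_{k,j} |\beta_{kj}|$$

with softmax class probabilities, by glmnet-style cyclic coordinate descent
on per-class quadratic approximations (intercepts unpenalized, features
standardized internally). The working penalty is $\lambda = 0.019$, which
zeroes a substantial fraction of coefficients and yields a sparse,
complementary classifier.

**Combination rule.** Per sample, both probability vectors are sex-filtered
(TGSC/PRAD zeroed for females, OV/UCEC for males, mass renormalized), the
top-2 classes per model are extracted, and the reported TOO is chosen by:
(A) any class with probability > 0.80 in either model; else (B) classes in
both models' top-2 with probability > 0.30 in at least one; else the union
of both top-2 lists.

**Survival.** Per miRNA, expression is dichotomized at the ROC threshold
maximizing sensitivity + specificity for vital status (Youden-type), groups
are compared by Kaplan-Meier/log-rank, and the hazard ratio comes from a
univariate Cox fit (Breslow ties) with a 95% Wald CI.

## Worked example

```python
from mirtoo import SimulationConfig, NearestShrunkenCentroids, MultinomialLasso
from mirtoo.synthetic import (make_class_profiles, simulate_reference_cohort,
                              simulate_metastases)
from mirtoo.preprocess import (normalize_median, exclude_mirnas,
                               log_transform, merge_classes)
from mirtoo.prediction import predict_sample

cfg = SimulationConfig(seed=7)
profiles = make_class_profiles(17, config=cfg)
matrix, meta = simulate_reference_cohort(profiles, cfg)          # 85 x 89
feats = log_transform(exclude_mirnas(normalize_median(matrix)))  # 85 x 87
y = merge_classes(meta["class_label"]).to_numpy()

nsc = NearestShrunkenCentroids(feats.data, y, delta=0.0).fit()
lasso = MultinomialLasso(feats.data, y, lam=0.019).fit()
print(lasso.summary())

test_m, test_meta = simulate_metastases(
    profiles, cfg, [("PT01", "CHOL", "liver")], role="cup")
x = log_transform(exclude_mirnas(normalize_median(test_m))).data.iloc[0]
report = predict_sample(nsc, lasso, x, "PT01-M1", sex="female")
print(report.final_sites, report.rule_fired)
```

prints

```
Multinomial lasso (coordinate descent, symmetric parameterization)
  classes: 17  features: 87
  lambda: 0.019   converged: True (13 outer iterations)
  features used (nonzero in some class): 69
  nonzero coefficients: 69
['CHOL'] A
```

The NSC model keeps all 87 features at Δ = 0; the lasso at λ = 0.019 keeps
69 of them. The simulated liver metastasis of a cholangiocarcinoma is
called CHOL under rule A: the NSC posterior for CHOL is ≈ 1.00 and the lasso
posterior 0.87, both above the 0.80 confidence bar — and the miR-122-5p
liver spike does not mislead the call because that assay is excluded from
the feature set.

The same chain is available from the shell:

```
mirtoo simulate --seed 7 --out run/
mirtoo preprocess run/matrix.tsv run/meta.tsv --out run/features.tsv
mirtoo train run/features.tsv run/features.meta.tsv --out run/
mirtoo predict run/features.tsv run/features.meta.tsv --models run/
mirtoo evaluate run/features.tsv run/features.meta.tsv
mirtoo survival run/matrix.tsv run/meta.tsv
```

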