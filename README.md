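# nphct

CT volumetry, Radscale scoring and diagnostic-accuracy statistics for
normal-pressure hydrocephalus (NPH).

NPH is a treatable cause of gait disturbance, urinary incontinence and
cognitive decline in the elderly, diagnosed on non-contrast CT by a
combination of ventricular enlargement markers (Evans' index, callosal
angle, temporal horn width) and sulcal patterns (narrow high-convexity
sulci, dilated Sylvian fissures, focally enlarged sulci). Because CSF
redistributes rather than simply increases, distinguishing NPH from
age-related atrophy is hard, and both human point scales and automated
volumetric pipelines are used.

This package implements, end to end and fully tested:

* **`nphct.phantom`** — a seeded synthetic-data generator producing
  CT-like 3D label volumes (background / CSF / white–grey) in which the
  NPH-like preset carries enlarged mid-axial ventricular CSF and focal
  vertex sulcal CSF, while the normal preset is peripheral-dominant; plus
  the grouped total-score table of the published 217-subject reference
  cohort (112 normal, 105 NPH).
* **`nphct.segment`** — a deterministic threshold segmenter standing in
  for a trained CSF-segmentation network, a noisy-label corruptor, and the
  Dice overlap metric.
* **`nphct.features`** — the volumetric feature set: per axial region
  (whole brain and ten contiguous partitions 0–9, inferior→superior) the
  pooled CSF ratio `N_CSF/(N_CSF+N_WG)`, the CSF/WG ratio `N_CSF/N_WG`,
  CSF and brain sizes relative to the image, and the Mean/Min/Max/
  population-Std of the per-slice ratios — 132 named features per scan.
* **`nphct.radscale`** — the seven-item radiological point scale (0–12)
  with configurable cut-offs and the Negative / Borderline / Positive
  prediction bands (0–2 / 3–4 / ≥5).
* **`nphct.classifier`** — min–max scaling, chi² filter selection of the
  top *k* = 10 features, L2 logistic regression (inverse regularization
  *c* = 10), leakage-free stratified 5-fold cross-validation, and exact
  linear attribution (the closed-form Shapley values of a linear model).
* **`nphct.diagnostics`** — confusion matrices from grouped score tables,
  sensitivity/specificity/PPV/NPV/accuracy, ROC points, two AUC readings
  (strict concordance and half-tie-credit Mann–Whitney), odds ratios with
  Haldane–Anscombe correction and Woolf CIs, Pearson chi-squared tests,
  and logistic derivation of score cut-off bands.
* **`nphct.pipeline`** — one-call orchestration of
  phantoms → segmentation → features → classifier → diagnostics, and a
  built-in reproduction of the reference cohort's accuracy tables.

## Worked example

`examples/06_reference_accuracy.py` recomputes every headline statistic of
the reference cohort from its grouped score counts:

```
radiologist metrics at cut-off >= 5 (computed vs published):
   sensitivity:  77.14%   (published  77.14%)
   specificity:  98.21%   (published  98.21%)
           ppv:  97.59%   (published  97.59%)
           npv:  82.09%   (published  82.09%)
      accuracy:  88.02%   (published  88.02%)

comparator model metrics implied by its published rates:
   sensitivity:  99.05%
   specificity:  57.14%
           ppv:  68.42%
           npv:  98.46%
      accuracy:  77.42%

AUC, strict concordance: 0.9537  (published ROC area 0.954)
AUC, half tie credit:    0.9665
```

Calling a subject positive at total score ≥ 5 yields the confusion matrix
(TP 81, FP 2, TN 110, FN 24); all five accuracy metrics follow from it.
The comparator row reconstructs the integer confusion matrix that the
published sensitivity/specificity force given the cohort sizes. The two
AUC values differ because the 0–12 score is heavily tied: strict
concordance counts only strictly ordered (NPH, normal) pairs
(11215/11760), the conventional Mann–Whitney form adds half credit for
ties (11366/11760) and equals the trapezoidal ROC area exactly.

`examples/05_classify_cohort.py` runs the synthetic pipeline on a
30 + 30 phantom cohort (seed 42):

```
out-of-fold AUC:      1.000
out-of-fold accuracy: 1.000

selected features (chi2 top-10):
  CSF ratio_5
  Mean CSF ratio_5
  CSF ratio_8
  Mean CSF ratio_8
  ...

mean |attribution| (logit scale), top 3:
      Mean CSF ratio_8 0.775
           CSF ratio_8 0.761
         CSF_ratio_all 0.540
```

The selection and attribution localize the decision to the ventricular
(partitions 4–5) and focal-sulcal (partition 8) CSF regions — the same
regions a radiologist inspects.

The remaining examples cover phantom generation, segmentation and Dice,
feature extraction, and Radscale scoring. A thin CLI mirrors the library
(`nphct --help`).

## Method in brief

A scan is reduced to slice-level counts `N_CSF`, `N_WG` over its
segmentation mask. Brain-containing slices are ranked inferior→superior
and slice *i* of *n* joins partition `floor(10·i/n)`. For a region *R*
(one partition or all brain slices):

    CSF ratio(R)   = Σ_R N_CSF / Σ_R (N_CSF + N_WG)
    CSF/WG ratio(R) = Σ_R N_CSF / Σ_R N_WG
    Mean/Min/Max/Std over {N_CSF/(N_CSF+N_WG) per slice in R}   (Std with divisor n)

Features are min–max scaled to [0, 1]; the chi² filter scores each feature
by the class-sum contingency statistic Σ_c (O_c − E_c)²/E_c; the top ten
enter an L2 logistic regression (penalty 1/c, c = 10). For this linear
model the attribution of feature *j* for instance *x* is exactly
`w_j (x_j − mean_j(reference))` on the logit scale, and the base value plus
contributions reproduces the model logit to numerical precision.

See `docs/methods.md` for the generator's design, parameter defaults,
numerical conventions and limitations.
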