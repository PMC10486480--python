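# Methods

## Scope and data model

The toolkit analyses non-contrast CT brain scans reduced to 3D label
volumes with three classes: background, CSF, and combined white/grey
matter (WG). All volumetric statistics are functions of per-slice counts
`N_CSF`, `N_WG` and the slice pixel count `image_size`; nothing downstream
of segmentation touches intensities. Real cohorts are not bundled — the
only empirical data shipped is the grouped total-score table of the
published 217-subject reference cohort (112 normal, 105 NPH), which is
sufficient to recompute that study's diagnostic-accuracy figures exactly.

## Synthetic phantoms

`nphct.phantom` generates the study conditions for every cohort-level
test. A phantom is an ellipsoidal head of WG (axes 0.40·nz, 0.42·ny,
0.42·nx, spanning ~80% of axial slices) with CSF as the union of five
compartments:

| compartment | location (fraction of brain slices) | scales with |
|---|---|---|
| paired ventricles | axial cylinders, 38–63% band | `ventricle_scale` (radii) |
| focal sulcal pockets | four peripheral cylinders, 80–91% band, tapered with the head section | `sulcal_scale` (radii) |
| peripheral rim | shell inside the head surface, 5–95% band | `atrophy_scale` (thickness) |
| basal cisterns | central disks, 2–15% band | `atrophy_scale` × heavy-tailed per-subject factor |
| vertex sulci | four peripheral disks, 82–96% band | `atrophy_scale` × heavy-tailed per-subject factor |

Interior compartments are clipped to a 0.95-shrunken head so a parenchymal
ring survives on every slice (no slice is ever pure CSF — real cortex is
never fully replaced). Ventricular dilation is modeled as purely radial,
so every slice of an affected partition carries the signal; this is why
the pooled partition ratios, not the slice-extreme statistics, are the
natural discriminators. Every compartment's per-slice radius is modulated
by a seeded irregularity factor (Gaussian, SD 0.06) with rare spikes
(probability 0.05 each way, multiplying the radius by ~0.35–0.65 or
~1.45–1.95): real anatomy is not smooth along z, and these occasional
extreme slices are what keeps Min/Max/Std-type features from looking
artificially clean.

Two cohort-level variation sources are deliberately diagnosis-independent:
per-subject head size (factor clipped-normal, SD 0.08) and inferior scan
coverage (a uniform 0–6% of the lowest brain slices left unimaged). Both
mirror acquisition realities; together with the cisterns and vertex sulci
they give whole-brain slice aggregates the between-subject variance they
have on real scans. The basal cisterns and vertex sulci are scaled by
`atrophy_scale` so that a phantom with all three scales at zero contains
no CSF at all, and CSF voxel count is nondecreasing in each scale.

**Presets.** NORMAL = (ventricle 1.0, sulcal 0.65, atrophy 1.0);
NPH = (ventricle 1.8, sulcal 1.5, atrophy 1.0). Equal atrophy is a
deliberate choice: the two groups differ in where CSF sits (ventricular
and focal-sulcal versus peripheral), not in total age-related atrophy,
which is the clinically hard part of the differential. Cohorts jitter the
three scales with zero-truncated Gaussians (SD 0.15) around the presets,
giving overlapping distributions. Defaults: 64³ voxels at 3 mm — enough
for ≥40 brain slices under a ten-partition split at desk-scale runtime
(a 200-subject cohort generates and featurizes in a few seconds).

**What passing tests do and do not show.** The phantoms reproduce the
*geometry* of the diagnostic problem (where CSF accumulates along the
axial axis) and several nuisance properties of real cohorts, but not CT
physics (no beam hardening, no bone, no partial-volume intensities), not
anatomy (no gyri, no third/fourth ventricle), and the shipped presets
separate far more cleanly than real patients do — the synthetic
out-of-fold AUC of ~1.0 is a property of the generator, not a claim about
clinical performance. Cohort-scale checks on feature selection and
attribution are seed-pinned regressions: they verify the pipeline
recovers the designed signal under the shipped study conditions, not that
it would on any resampling.

## Segmentation stand-in

The trained 2D segmentation network whose place `threshold_segment`
occupies is out of scope (its value is its weights, which require real CT
and labels). The pipeline's contract is "any producer of a label volume",
so the stand-in is a deterministic intensity threshold: within a brain
mask, voxels below the CSF/WG midpoint become CSF. The intensity renderer
puts class means at 5 (CSF) and 35 (WG) — a CT-like 30-unit contrast —
with Gaussian noise; at noise SD 5 the threshold recovers labels with CSF
Dice > 0.99. `corrupt_labels` flips brain labels independently with a
given probability to emulate noisy (weak) supervision; Dice follows the
implied binomial overlap. Dice is defined as 1 when both sets are empty so
identical volumes always score perfectly.

## Features

Twelve quantities per region, regions being the whole brain and ten
contiguous axial partitions. Conventions that matter:

* **Partition rule**: brain-containing slices (those with any CSF or WG),
  ordered inferior→superior, slice *i* of *n* → partition `floor(10·i/n)`;
  sizes differ by at most one. Empty slices are excluded before ranking.
* **Pooled vs aggregated**: the unqualified `CSF ratio_p` pools counts
  over the partition's slices; `Mean/Min/Max/Std CSF ratio_p` aggregate
  the per-slice ratios. Both are computed and stored — they genuinely
  differ and the pooled form is the more stable estimator.
* **Std** is the population standard deviation (divisor *n*).
* **Degenerate slices**: an empty region yields all-zero ratios; a region
  with CSF but no WG yields a configurable cap (default 10⁶) for the
  CSF/WG ratio rather than infinity, keeping feature matrices finite.
* **Naming** is bit-stable: partition features as `CSF ratio_5`,
  `Std CSF ratio_9`; global features as `CSF_ratio_all` etc.

## Radscale

Seven items: Evans' index, mean temporal horn width (mean of right and
left, mm), callosal angle (degrees), narrow high-convexity parietal sulci
(visual grade), periventricular hypodensities (none/caps/confluent) — each
0–2 points — plus dilated Sylvian fissures and focally enlarged sulci at
0–1, for a maximum of 12. The per-item cut-offs are reference-derived
defaults, declared in one configurable mapping:
Evans <0.30 / 0.30–0.35 / >0.35; temporal horn <4 / 4–6 / >6 mm; callosal
angle >90 / 60–90 / <60°. Cut values themselves take the middle grade (an
Evans' index of exactly 0.35 scores 1), a deterministic tie rule. Totals
map to Negative (0–2), Borderline (3–4), Positive (≥5). The cut-off
derivation utility refits this banding from data: a single-predictor
logistic regression of diagnosis on total score, with Negative/Positive
defined by fitted probability below 0.25 / above 0.75 (both configurable);
on the reference cohort this recovers exactly the published 0–2 / 3–4 / ≥5
bands.

## Classifier

Min–max scaling to [0, 1] per feature (constant features map to 0; the
chi² filter requires non-negative input and the convention makes scores
scale-free). The chi² score treats the scaled values as counts:
O_cj = Σ_{i: y_i = c} x_ij, E_cj = (Σ_i x_ij)(n_c/n), score Σ_c
(O−E)²/E — the standard continuous-feature filter (it matches
scikit-learn's `chi2` exactly, which a test verifies). Top-10 selection
breaks ties lexicographically. The logistic regression penalizes
coefficients (not the intercept) with strength 1/c, c = 10, solved by
L-BFGS to tolerance 1e-6 (convex, hence deterministic). Cross-validation
is stratified 5-fold with seeded shuffling; scaling and selection are
re-fit on each training fold so out-of-fold probabilities are leakage
free; headline metrics pool the out-of-fold predictions (one per subject)
at probability threshold 0.5 (configurable). Attribution uses the linear
model's closed form, `w_j (x_j − mean_j(reference))` on the scaled logit
scale, with exact additivity (tested to 1e-9); cohort-level importance is
the mean absolute contribution with the cohort itself as reference.

## Diagnostic statistics

All computed from grouped (score, n_normal, n_nph) tables. A binary call
at cut-off *t* is score ≥ *t*; borderline subjects below the cut-off count
as test-negative — the only reading under which the reference counts
reproduce the published accuracy row exactly. Metrics with zero
denominators are returned as `None`, never silently 0. Published rates can
be inverted to an integer confusion matrix by nearest-integer rounding
(half away from zero) of sens·n_pos and spec·n_neg.

Two AUC readings are exposed because ordinal scores are heavily tied:
strict concordance (no tie credit) and the Mann–Whitney form (half credit,
equal to the trapezoidal ROC area — an identity the tests check to 1e-12).
On the reference table these are 0.954 and 0.966; the package reports
both and does not assert which convention any external figure used.

Odds ratios use Haldane–Anscombe (+0.5 on every cell when any cell is
zero, guaranteeing finite estimates) with Woolf 95% CIs; the Pearson
chi-squared test takes expected counts from the margins with df
(r−1)(c−1). These method choices are standard and documented here because
the conventions are not uniquely determined by the statistics' names.

## Pipeline and reproducibility

`run_end_to_end` derives every stage's seed from one master seed, embeds
the fully resolved configuration in its JSON report, and rejects unknown
configuration keys by name. Identical configurations produce identical
reports. The reference-table reproduction (`reproduce_reference_tables`)
uses only the built-in grouped counts and published operating points; all
its figures are recomputed at call time.

## Known limitations

* The phantom is a geometric caricature; see the generator section for
  what it does not model.
* The segmentation stand-in cannot quantify how a learned segmenter's
  errors propagate — only the (simpler) independent-flip noise model is
  available.
* Radscale item cut-offs are reference-derived defaults, not fitted to
  data; real deployments should calibrate them per site.
* The CSF/WG cap (10⁶) is arbitrary in magnitude; analyses sensitive to
  its value should prefer the bounded CSF ratio family.
* The cut-off derivation's probability bands (0.25/0.75) are a design
  default; the derived bands are sensitive to them when groups overlap
  heavily.
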