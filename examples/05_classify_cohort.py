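"""Run the full classification pipeline on a small synthetic cohort.

Generates 30 NPH-preset and 30 normal-preset phantoms, extracts the 132
volumetric features, and evaluates the chi2-selection + L2-logistic model
(c = 10, k = 10) with stratified 5-fold cross-validation. Scaling and
selection are re-fit inside each fold, so the out-of-fold AUC is leakage
free. A final full-data fit supplies the selected feature list and the
exact linear attribution ranking.
"""

from nphct import classifier, features, phantom

cohort = phantom.generate_cohort(n_nph=30, n_normal=30, seed=42)
X, y = features.cohort_feature_matrix(cohort)

cv = classifier.cross_validate(X, y, folds=5, seed=42, c=10, k=10)
print(f"out-of-fold AUC:      {cv.pooled['auc']:.3f}")
print(f"out-of-fold accuracy: {cv.pooled['accuracy']:.3f}")

model = classifier.fit_pipeline(X, y, c=10, k=10)
print("\nselected features (chi2 top-10):")
for name in model.selected_features:
    print(f"  {name}")

importance = classifier.mean_absolute_attribution(model, X)
print("\nmean |attribution| (logit scale), top 3:")
for name, v in importance.head(3).items():
    print(f"  {name:>20} {v:.3f}")

print("\nAn AUC near 1 means the presets separate cleanly; the selected and"
      "\ntop-attributed features localize the decision to the ventricular"
      "\n(partitions 4-5) and focal-sulcal (partition 8) CSF regions.")
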