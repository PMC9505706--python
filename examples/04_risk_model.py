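"""Train and evaluate the gradient-boosted risk model.

Runs the full encoding on a simulated clinical cohort, evaluates by 30
repeated stratified 70/30 splits, and inspects the operating point and the
genera the model relies on.
"""

from taxrisk import cross_validate, importance, preprocess, select_features
from taxrisk.risk_model import fit_gbm
from taxrisk.synth import clinical_spec, planted_genera, simulate_cohort

spec = clinical_spec(n_control=100, n_case=100)
table, metadata = simulate_cohort(spec, seed=5)
features = select_features(preprocess(table).values)
y = (metadata.labels_for(list(features.index)) == "IBD").astype(float)

cv = cross_validate(features, y, n_iter=30, train_frac=0.7, base_seed=5)
s = cv.summary()
print(f"AUC over 30 iterations: mean {s['mean_auc']:.3f}, "
      f"sd {s['sd_auc']:.3f}, min {s['min_auc']:.3f}, max {s['max_auc']:.3f}")

best = cv.best_iteration()
op = best["operating_point"]
print(f"best split: AUC {best['auc']:.3f}, sensitivity {op['sensitivity']:.3f}, "
      f"specificity {op['specificity']:.3f} at threshold {op['threshold']:.3f}\n")

bundle = fit_gbm(features, y, seed=5)
imp = importance(bundle, "impurity")
planted = set(planted_genera(spec))
print("top 10 genera by impurity importance ('*' marks a planted effect):")
for name, row in imp.head(10).iterrows():
    mark = " *" if name in planted else ""
    print(f"  {name:<22s} {row['importance']:.3f}{mark}")
print("\nA well-behaved model concentrates importance on the planted genera;")
print("the AUC spread across splits shows how stable the classifier is.")
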