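"""Sex-stratified k-means reference labelling and bootstrap stability.

k-means (k=4, many random restarts) on the five Ahlqvist variables, fitted
separately for women and men on z-scored values, produces the reference
subtype labels the classifier is later trained against.  Bootstrap
resampling quantifies how stable each cluster is.
"""

import t2dsub as t

spec = t.GeneratorSpec.default()
lab = t.generate_cohort(spec, n=1200, seed=2)
df = lab.cohort.baseline()

model, labels = t.fit_kmeans_by_sex(df, seed=3, restarts=200)
print("label counts:")
print(labels.value_counts().to_string())

truth = lab.true_subtype.loc[df["id"]]
pure = truth != t.BLENDED
agree = (labels.loc[df["id"]][pure.to_numpy()] == truth[pure]).mean()
print(f"\nagreement with generator truth (non-blended): {100 * agree:.1f}%")

rep = t.jaccard_stability(df, model, labels, B=50, seed=4, restarts=20)
print("\nbootstrap Jaccard stability (50 resamples):")
print(rep.table.round(2).to_string(index=False))
# Jaccard near 1 = the cluster reappears almost unchanged in resampled data;
# values in the 0.7-0.9 range are typical for real overlapping clusters.
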