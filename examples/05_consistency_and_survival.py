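"""Temporal consistency of subtype labels and complication risk by subtype.

A five-year follow-up visit is simulated with within-person drift; the
classifier labels both visits and the migration matrix shows who changed
subtype.  Complication event times follow subtype-specific hazards
(retinopathy elevated in SIDD, kidney disease in SIRD), recovered here by
Cox regression adjusted for age and sex.
"""

import t2dsub as t

spec = t.GeneratorSpec.default()
lab = t.generate_cohort(spec, n=2000, seed=14)
df = lab.cohort.baseline()
_, labels = t.fit_kmeans_by_sex(df, seed=15, restarts=200)
train_ids, _ = t.train_test_split_ids(df["id"].to_numpy(), 0.7, seed=16)
clf = t.tune_and_train(df[df["id"].isin(train_ids)], labels,
                       grid={"n_estimators": (300,)}, seed=17)

fup = t.generate_followup(lab, years=5.0, spec=spec, seed=18)
p0 = t.predict_with_abstention(clf, df).set_index("id")["label"]
p5 = t.predict_with_abstention(clf, fup.df).set_index("id")["label"]
cons = t.consistency_over_time(p0, p5)
print("baseline -> 5-year migration matrix:")
print(cons.migration.to_string())
print("\nper-subtype consistency (decided at both visits), %:")
print(cons.per_subtype.round(1).to_string())
print(f"mean consistency: {cons.mean_consistency:.1f}%  "
      f"(undecidable cluster: {cons.undecidable_consistency:.1f}%)")

events = t.generate_events(lab, spec, horizon=12.0, seed=19)
baseline = df[["id", "age", "sex"]].copy()
baseline["subtype"] = p0.loc[baseline["id"]].to_numpy()
baseline = baseline[baseline["subtype"] != t.UNDECIDABLE]
res = t.survival_by_subtype(events[events["id"].isin(baseline["id"])], baseline)
print("\nCox hazard ratios vs MARD (age- and sex-adjusted):")
for ev in ("retinopathy", "ckd"):
    print(f"  {ev}:")
    print(res.cox[ev].round(2).to_string(index=False))
# High consistency means a subtype assignment is reproducible five years on;
# the hazard ratios recover the generating risks (retinopathy ~2x in SIDD,
# kidney disease ~1.6x in SIRD).
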