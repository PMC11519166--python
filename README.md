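# t2dsub — machine-learning subtyping of type 2 diabetes

Type 2 diabetes is heterogeneous. Ahlqvist's clustering splits it into four
clinically meaningful subtypes — **SIDD** (severe insulin-deficient), **SIRD**
(severe insulin-resistant), **MOD** (mild obesity-related) and **MARD** (mild
age-related) — from five variables: age at diagnosis, BMI, HbA1c, HOMA2-B and
HOMA2-IR. Plain k-means subtyping has two practical problems: it cannot
classify a *new* individual (labels depend on the whole dataset), and it needs
the HOMA2 indices, which require fasting C-peptide measurements that most
clinics and cohorts do not have.

`t2dsub` implements a label-transfer pipeline that addresses both, for
epidemiologists and clinical researchers working with tabular cohort data:

1. **Reference labels** — sex-stratified k-means (k = 4, best of many random
   restarts on z-scored variables), subtype naming by a greedy rule on the
   standardised centres, and bootstrap Jaccard cluster-stability audits.
2. **Random-forest label transfer** — a multiclass forest (5- or 15-variable
   feature set, Boruta shadow-feature selection from 25 candidates, OOB-tuned
   hyper-parameters) predicts the subtype of any individual. Class
   probabilities are vote fractions p̂ₖ = (# trees voting k)/T, and an
   individual with max ₖ p̂ₖ < τ (default τ = 0.6) is relabelled
   **UNDECIDABLE** rather than forced into a subtype.
3. **Missing insulin-related variables** — C-peptide, HOMA2-B and HOMA2-IR are
   imputed by chained random-forest regression from routine covariates;
   training-data missingness is handled with MICE and Rubin's rules
   (T = W̄ + (1 + 1/m)·B).
4. **Audits** — per-subtype precision/recall/F1/AUC, baseline-vs-follow-up
   migration matrices with consistency percentages, and Kaplan–Meier/Cox
   analysis of complication risk (retinopathy, CKD, proteinuria, coronary
   artery disease) by subtype.
5. **Synthetic cohorts** — because the motivating clinical datasets are
   restricted, a first-class generator (`GeneratorSpec`) produces cohorts with
   the published per-cluster moments, boundary blends, configurable
   missingness, five-year drift and subtype-specific complication hazards, so
   every stage is testable end to end.

Clinical plumbing is included: a unit-checked cohort CSV format with a data
dictionary, the type 2 diabetes eligibility rule (fasting glucose ≥ 7.0
mmol/l, random glucose ≥ 11.1 mmol/l, HbA1c ≥ 48 mmol/mol, or drug use; islet
autoantibody positivity excludes), the IFCC→NGSP HbA1c master equation, the
Japanese eGFR equation, HOMA2 input capping, and event derivation (CKD =
eGFR < 60 sustained > 90 days; proteinuria = albuminuria ≥ 30 mg/g).

## Worked example

`examples/03_subtype_classifier.py` generates a 2000-individual synthetic
cohort, fits the k-means reference labels, trains the forest on a 70% split
and evaluates the held-out 30%:

```
chosen hyper-parameters: {'max_features': 'sqrt', 'n_estimators': '300', 'min_samples_leaf': '1'}
out-of-bag accuracy: 0.955

test accuracy, decided individuals: 99.0%
test accuracy, everyone forced:     95.8%
undecidable share:                  13.2%

per-subtype metrics (decided subset):
      precision  recall     f1    auc
SIDD      0.991   0.991  0.991  0.998
SIRD      0.986   0.986  0.986  0.998
MOD       0.982   0.982  0.982  0.992
MARD      0.996   0.996  0.996  0.998
```

Reading: 13.2% of test individuals sit in cluster boundary regions and are
abstained on; among the rest, 99% receive their k-means reference subtype,
with one-vs-rest AUC ≥ 0.99 for every subtype. Forcing a label on everyone
(τ = 0) costs about three accuracy points — the abstention cluster is where
the errors live. The other examples cover cohort generation, reference
labelling with Jaccard stability, imputation of deleted insulin variables,
and the consistency/survival audits.

A thin CLI wraps the same library for shell use:

```bash
t2dsub full --config config.yaml     # simulate → label → train → predict → audits
```

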