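# Methods

## The pipeline

`t2dsub` treats subtype assignment as label transfer. Unsupervised k-means on
the five clustering variables (age at diagnosis, BMI, HbA1c, HOMA2-B,
HOMA2-IR) defines reference labels on a labelled cohort; a supervised random
forest then learns those labels from a broader, routinely available feature
set and can classify new individuals one at a time — something k-means cannot
do, since its assignments depend on the whole dataset. The forest's vote
fractions provide a notion of assignment confidence, and individuals whose
maximum vote fraction falls below an abstention threshold τ are reported as
UNDECIDABLE instead of being forced into a subtype. The working assumption is
that the four subtypes are real, stable structures with genuinely ambiguous
boundary regions; abstention exists to keep boundary noise from masquerading
as subtype migration.

## Reference labelling (k-means)

* Women and men are clustered separately to remove sex effects on the
  anthropometric and insulin variables.
* Variables are z-scored within each sex stratum before clustering.
  Unstandardised clustering would be dominated by HOMA2-B (range ~10–300)
  at the expense of BMI and age. The standardisation means/SDs are stored in
  the model artifact and reused for nearest-centre assignment.
* k = 4 (fixed); `restarts` random initialisations (default 1000), lowest
  within-cluster sum of squares wins, ties broken by the first run index.
  Each sex stratum must contain at least 16 individuals (4 per cluster).
* Centre naming is a greedy rule on the standardised centres: highest HbA1c →
  SIDD; of the rest, highest HOMA2-IR → SIRD; of the rest, youngest age at
  diagnosis → MOD; remainder → MARD. The rule mirrors the published cluster
  profiles. Ties within 10⁻⁹ on a deciding variable raise an error demanding
  a manual mapping — silent arbitrary naming would corrupt every downstream
  comparison. The applied trace is recorded on the model.
* Stability: B bootstrap resamples (default 2000) per sex stratum; k-means is
  re-fitted on each resample (with a reduced restart count, default 20, as a
  compute choice) and each reference cluster is matched to the re-fitted
  cluster maximising the Jaccard index over the unique resampled ids. The
  report carries min/mean/max per sex × subtype.
* Follow-up reference labels are produced by re-fitting k-means on the
  follow-up visit (re-fitting reproduces the hard-clustering instability that
  motivates the transfer approach); nearest-centre assignment to the baseline
  model is available as an alternative mode.

## The subtype classifier

* Features: the five clustering variables (`T2D_RF5`-style) or the
  15-variable default `DEFAULT_RF15` (the five plus C-peptide, attained age,
  waist, fasting glucose, ALT, γGT, HDL, triacylglycerols, diabetes duration,
  eGFR). The candidate pool for selection is the 25-variable
  `DEFAULT_CANDIDATES` list of routine clinical measurements; both lists are
  configurable.
* Boruta selection: per round, every undecided candidate gets a shadow copy
  (column-wise permutation); a forest is fitted on [real | shadow] columns and
  a feature scores a *hit* when its impurity importance exceeds the best
  shadow importance. Cumulative hit counts are tested each round against
  Binomial(r, ½) one-sided in both directions, Bonferroni-corrected across
  the original candidates (α = 0.05 default); confirmed/rejected features
  leave the pool. At least five shadow columns are always kept (cycling over
  the undecided features) — with a thin shadow pool late in a run the
  max-shadow bar becomes too easy and false confirmations appear. α ≥ 1 is a
  documented degenerate mode: any feature that ever beats the best shadow is
  confirmed. Exhausting `max_rounds` returns the remaining features as
  tentative, flagged.
* Tuning: grid search over per-split feature count, tree count, minimum
  terminal-node size and maximum terminal nodes, scored by out-of-bag
  accuracy; ties break to the earliest grid point; the full tuning record is
  stored on the classifier.
* Probabilities are plain vote fractions over trees (not out-of-bag
  estimates, not tree-probability averages): p̂ₖ = #{trees voting k}/T.
  The abstention rule is `max_prob < τ → UNDECIDABLE` with τ = 0.6 by
  default; equality at τ counts as decided. Argmax ties between classes are
  broken by the fixed class order SIDD < SIRD < MOD < MARD and flagged.
* Proximity between two individuals is the fraction of trees in which they
  share a terminal leaf; the matrix is embedded in 2-D by UMAP on distance
  1 − proximity (precomputed metric, seeded, `n_neighbors` capped at n − 1)
  for boundary-region visualisation.
* Feature importance is permutation importance on held-out data (mean over
  repeats, with SD and rank); per-class one-vs-rest accuracy-drop importances
  are optional. Impurity importances remain available on the forest object
  (they, not permutation importances, show shared-credit splitting between
  duplicated features).

## HOMA2 handling

Inputs are capped to the calculator domain — fasting glucose to [3, 25]
mmol/l, C-peptide to [0.2, 3.5] nmol/l — with flags recording any clamping.
Two backends compute (HOMA2-B, HOMA2-IR):

* `precomputed`: pass-through for cohorts that already carry the indices
  (the common case); supplied values are never overwritten.
* `approximation`: an own-authored closed-form monotone surface,
  IR = fpg·C/(5.0·0.55) and B = 454.5·C/(fpg − 2.5), calibrated so the
  healthy reference point (fpg 5.0 mmol/l, C-peptide 0.55 nmol/l) maps to
  (B = 100%, IR = 1). The glucose offset 2.5 keeps B positive and finite on
  the whole capped domain. Against published cluster-level profiles the
  surface lands within roughly 15% — adequate for simulation and
  sanity-checking, not a replacement for the physiological solver, whose
  model is proprietary. The shipped fixture grid
  (`data/homa2_grid_synthetic.csv`) is generated from this surface and is
  synthetic; it exercises the pass-through backend and file IO only.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, so
that every stage can be tested without the restricted clinical data.

* **Mixture**: individuals are drawn per subtype with mixing weights
  proportional to the published cluster counts 116:90:109:216; a
  `boundary_blend` share (default 0.14, emulating the observed undecidable
  fraction) is drawn from components midway between two *adjacent* clusters
  and labelled BLENDED. Adjacency is the four nearest-neighbour pairs by
  standardised centre distance of the published profiles (MOD–MARD,
  SIDD–MOD, SIDD–MARD, SIRD–MOD). BLENDED is generator truth; it is compared
  against, never conflated with, the classifier's UNDECIDABLE.
* **Moments**: per-cluster means/SDs default to the published baseline
  characteristics. Right-skewed variables (triacylglycerols, AST, ALT, γGT,
  albuminuria) are lognormal from median/IQR (log-SD = ΔlogIQR/1.349);
  C-peptide is lognormal moment-matched to its published mean ± SD.
* **Within-cluster correlation** is a latent-factor model — metabolic/
  adiposity, glycaemic, liver, renal and blood-pressure factors — shared
  across clusters and sexes: corr = ΛΛᵀ + diag(1 − Σλ²), positive
  semi-definite by construction. C-peptide loads strongly on the metabolic
  factor; glucose and HbA1c on the glycaemic factor. These couplings give
  the insulin-related block the partial predictability from routine
  variables that the missing-variable workflow relies on in real data.
* **HOMA2 indices are derived, not drawn**: as in reality, where they are
  deterministic functions of the fasting measurements, HOMA2-B/IR are
  computed from (fpg, C-peptide) through the approximation surface, then
  rescaled *within each mixture component* to the component's published
  mean/SD, plus an independent noise share (`homa2_noise_frac`, default
  0.15 of the within-component variance). The per-component rescaling makes
  the cluster moments exact by construction while keeping the indices
  functions of the observed physiology. It does mean an individual's HOMA2
  values depend weakly on the co-generated sample (through the component's
  empirical surface moments) — a deliberate moment-matching device.
* **Truncation**: correlated draws are rejected against the data
  dictionary's physiological ranges (plus the constraint that attained age =
  age at diagnosis + duration stays in range), with a resample cap that
  errors rather than silently clamping; the derived HOMA2 values and
  C-peptide are clipped to their dictionary ranges (rare).
* **Binary traits** (smoking, alcohol, six drug classes) are Bernoulli with
  the published per-cluster rates; sex is Bernoulli with the per-cluster
  female shares; blends average their pair's parameters.
* **Follow-up drift**: the change of a drifting variable over the follow-up
  interval is N(shift, 2σ²) — visit-level noise σ enters at both baseline
  and follow-up — then clipped to the dictionary range. Ages and durations
  advance by the interval. The drift table (shifts and σ per variable) is a
  synthetic invention: no within-person longitudinal variances were
  available to emulate, and all drift-dependent results are labelled
  accordingly.
* **Events**: exponential proportional-hazards times per event type with
  subtype-specific hazard ratios (defaults: retinopathy HR 2.08 for SIDD vs
  MARD, CKD HR 1.58 for SIRD vs MARD; baseline yearly rates 0.020/0.025/
  0.030/0.010 for retinopathy/CKD/proteinuria/coronary disease, chosen to
  give realistic cumulative incidence over a ~12-year horizon), with
  administrative censoring at the horizon and optional independent
  exponential censoring.

What the generator does **not** emulate: sex-specific cluster moments (the
published table is not sex-stratified; per-sex overrides are possible but
default to shared moments), medication effects on trajectories, non-random
missingness, measurement batch effects, and demographic structure beyond the
cluster mixture. Passing tests therefore demonstrate the pipeline's internal
correctness and its behaviour under the published cluster geometry — not
performance on any real population.

## Imputation of the insulin-related block

One regression forest per target, chained (C-peptide → HOMA2-B → HOMA2-IR;
each later target also sees the earlier, already-imputed targets), trained on
a cohort with the targets observed. Predictors are the routine clinical
variables and medication flags. Observed cells pass through bit-exact. When
a held-out truth mask is supplied, the quality report carries per-variable R²
(coefficient of determination; for these near-unbiased predictions it agrees
with the squared observed-vs-predicted Pearson correlation to three decimals)
and the mean/SD of absolute differences.

**Attainable recovery under the shipped study conditions.** With the whole
insulin block deleted jointly for half a 6000-individual default cohort,
chained-forest recovery measures R² ≈ 0.63 (C-peptide), 0.65 (HOMA2-B),
0.58 (HOMA2-IR). This is structural, not an implementation artifact: an
oracle regression given the *true* cluster labels on top of all routine
covariates reaches only ≈ 0.76–0.84, because the severe insulin-resistant
and mild obesity-related clusters overlap in every routine covariate while
differing strongly in the deleted block — that part of the information is
simply gone. Reported real-data recovery in this literature is higher
(≈ 0.83–0.92), implying cross-variable coupling beyond what published
cluster-level moments can encode; the generator reproduces the qualitative
feature (substantial, usable recovery) at the level its moment constraints
allow. The acceptance suite keeps a stricter 0.7 bound as specified upstream
and that check fails honestly under these conditions; the module-level
regression test guards the measured behaviour (≥ 0.5 per variable, and
monotone improvement as the HOMA2 noise share shrinks).

Training-cohort missingness uses MICE: chained-equation completions are
delegated to statsmodels' `MICEData` (predictive-mean matching per column,
`m` = 10 completions by default, two update sweeps between draws), and any
per-dataset (estimate, variance) statistic is pooled with own-implemented
Rubin's rules: Q̄ = mean estimate, W̄ = mean within variance, B = between
variance (ddof 1), T = W̄ + (1 + 1/m)B, with the large-sample degrees of
freedom (m − 1)(1 + W̄/((1 + 1/m)B))²; B = 0 gives infinite df.

The step-wise omission analysis deletes variables cumulatively (insulin block
first, by contract), re-imputes the insulin variables with the chained
forests, fills other omitted variables with the classifier's training
medians (the mechanism for feeding a forest an absent column), re-predicts,
and records accuracy, undecidable share and per-class metrics per step; an
all-features-omitted step is flagged as an error state and truncates the
curve.

## Evaluation

* Metrics: overall accuracy, per-class precision/recall/F1 and one-vs-rest
  AUC from the vote-fraction vectors; macro averages. UNDECIDABLE is excluded
  from denominators by default (its share is always reported alongside), with
  an include-mode in which abstentions count as errors — both conventions are
  emitted because "overall accuracy" is ambiguous between them.
* Consistency over time: a 5 × 5 migration matrix (four subtypes +
  UNDECIDABLE). Per-subtype consistency is the percentage unchanged among
  individuals decided at *both* visits; the undecidable cluster's own
  retention is reported separately; the mean is participant-weighted over
  the four subtypes. A node/link JSON export supports Sankey diagrams.
* Survival: Kaplan–Meier per subtype with confidence bands; Cox proportional
  hazards with subtype indicators (MARD reference) adjusted for baseline age
  and sex, Efron tie handling (recorded in the result metadata). Groups or
  covariates that are constant in the data are dropped; an event type with
  zero occurrences, or fewer than two represented groups, skips the Cox fit
  with a flag rather than failing.

## Numerical choices and problem sizes

* Fixed tie-break order SIDD < SIRD < MOD < MARD everywhere a tie is
  possible (argmax ties, nearest-centre ties); ties are flagged, never
  silent.
* Centre-naming tie tolerance 10⁻⁹; nearest-centre distance tie tolerance
  10⁻¹²; probability-sum invariant asserted at 10⁻⁹.
* Truncated sampling rejects and redraws, with a cap (default 1000 rounds)
  that raises rather than clamps.
* All randomness flows from integer seeds through `numpy.random.default_rng`
  (scikit-learn components receive derived integer states); every fitted
  artifact records its seed.
* The test-suite and acceptance problem sizes — cohorts of 2000 (labelling,
  classification, consistency), 6000 (imputation recovery) and 5000
  (hazard-ratio recovery), k-means restart counts of 100–1000 and bootstrap
  sizes of 5–50 in tests — were chosen to put Monte-Carlo error well inside
  the asserted margins while keeping each check to seconds or a few minutes.

## Known limitations

* The HOMA2 approximation is a calibration surface, not the physiological
  model; cohorts with real HOMA2 values should use the pass-through backend.
* The generator's correlation structure is a five-factor simplification;
  real biomarker covariance is richer, which is exactly why real-data
  imputation can outperform the synthetic ceiling discussed above.
* Consistency results depend on the synthetic drift table, which is invented;
  they demonstrate the *mechanism* (abstention absorbs boundary churn), not a
  clinical consistency estimate.
* MICE uses predictive-mean matching throughout rather than per-type
  regression models; for the pooling arithmetic this is immaterial, but
  heavily categorical cohorts may warrant custom column models.
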