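"""Imputation of insulin-related variables, MICE/Rubin pooling, and the
step-wise variable-omission robustness analysis.

Prediction-time cohorts frequently lack C-peptide and the HOMA2 indices.
They are filled by chained random-forest regression: one regression forest
per target, fitted on a training cohort with the targets observed, in a
configured order (default C-peptide, then HOMA2-B, then HOMA2-IR, each
later target also using the earlier, already-imputed targets as
predictors).  Observed cells are never overwritten, and when a held-out
truth mask is available the module reports per-variable R-squared and the
distribution of absolute differences.

Training-data missingness is handled differently (multiple imputation):
``mice_with_rubin`` runs chained-equation completions and pools any
per-dataset (estimate, variance) statistic with Rubin's rules:

    Qbar = mean(Q_i);  W = mean(U_i);  B = var(Q_i, ddof=1)
    T = W + (1 + 1/m) * B

with Rubin's large-sample degrees of freedom (m - 1) * (1 + W / ((1+1/m)B))^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score

from .cohort import INSULIN_VARIABLES
from .subtyper import SubtypeClassifier, encode_features, predict_with_abstention

DEFAULT_CHAIN_ORDER: tuple[str, ...] = ("cpeptide", "homa2b", "homa2ir")

#: default predictors: routine clinical variables and medication flags
#: (everything a clinic records; no insulin-related targets)
DEFAULT_PREDICTORS: tuple[str, ...] = (
    "age", "age_at_diagnosis", "diabetes_duration", "bmi", "waist",
    "sbp", "dbp", "fpg", "hba1c_ifcc", "tg", "hdl", "ldl", "ast", "alt",
    "ggt", "egfr", "uric_acid", "wbc", "hb", "platelets", "sex_female",
    "sulfonylurea", "metformin", "dpp4i", "sglt2i", "glp1ra", "insulin",
)


@dataclass
class ImputationModel:
    """Chained per-target regression forests for the insulin-related block."""

    order: tuple[str, ...]
    predictors: tuple[str, ...]
    forests: dict[str, RandomForestRegressor]
    training_fingerprint: str
    seed: int
    notes: dict = field(default_factory=dict)


def fit_imputer(training: pd.DataFrame,
                predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
                order: tuple[str, ...] = DEFAULT_CHAIN_ORDER,
                n_estimators: int = 300, seed: int = 0) -> ImputationModel:
    """Fit one regression forest per insulin-related target, chained.

    Each target is fitted on training rows where it is observed, using the
    base predictors plus all *earlier* targets in the chain (their observed
    training values).
    """
    if len(predictors) == 0:
        raise ValueError("empty predictor list")
    missing = [p for p in predictors if p != "sex_female" and p not in training.columns]
    if missing:
        raise ValueError(f"predictors absent from training table: {missing}")
    X_base = encode_features(training, predictors)
    all_missing = [c for c in X_base.columns if X_base[c].isna().all()]
    if all_missing:
        raise ValueError(f"predictor columns entirely missing: {all_missing}")
    forests: dict[str, RandomForestRegressor] = {}
    for k, target in enumerate(order):
        if target not in training.columns or training[target].isna().all():
            raise ValueError(f"target {target!r} has no observed training values")
        X = pd.concat([X_base, training[list(order[:k])]], axis=1)
        obs = training[target].notna() & X.notna().all(axis=1)
        forest = RandomForestRegressor(
            n_estimators=n_estimators, random_state=seed + k, n_jobs=1)
        forest.fit(X.loc[obs].to_numpy(), training.loc[obs, target].to_numpy())
        forests[target] = forest
    fp = f"n={len(training)};cols={','.join(sorted(training.columns))}"
    return ImputationModel(order=tuple(order), predictors=tuple(predictors),
                           forests=forests, training_fingerprint=fp, seed=seed,
                           notes={"chain": " -> ".join(order)})


def impute(model: ImputationModel, df: pd.DataFrame,
           truth: pd.DataFrame | None = None
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing insulin-related targets; observed values pass through bit-exact.

    ``truth`` (optional) holds the pre-masking values of masked cells,
    indexed like ``df``, one column per target; the quality report then
    carries per-variable R-squared and the mean/SD of absolute differences
    between imputed and true values.
    """
    out = df.copy()
    X_base = encode_features(out, model.predictors)
    broken = [c for c in X_base.columns if X_base[c].isna().any()]
    if broken:
        raise ValueError(
            f"predictors with missing values break the chain: {broken}")
    report_rows = []
    for k, target in enumerate(model.order):
        X = pd.concat([X_base, out[list(model.order[:k])]], axis=1)
        if target not in out.columns:
            out[target] = np.nan
        need = out[target].isna()
        if need.any():
            pred = model.forests[target].predict(X.loc[need].to_numpy())
            out.loc[need, target] = pred
        if truth is not None and target in truth.columns:
            mask = need & truth[target].notna()
            if mask.any():
                y_true = truth.loc[mask, target].to_numpy(dtype=float)
                y_hat = out.loc[mask, target].to_numpy(dtype=float)
                diff = np.abs(y_hat - y_true)
                report_rows.append({
                    "variable": target, "n_imputed": int(mask.sum()),
                    "r2": float(r2_score(y_true, y_hat)),
                    "mean_abs_diff": float(diff.mean()),
                    "sd_abs_diff": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
                })
    report = pd.DataFrame(
        report_rows, columns=["variable", "n_imputed", "r2",
                              "mean_abs_diff", "sd_abs_diff"])
    return out, report


# ---------------------------------------------------------------------------
# MICE + Rubin's rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RubinPooled:
    """Rubin's-rule pooling of m per-imputation (estimate, variance) pairs."""

    m: int
    q_bar: float
    w_bar: float          # mean within-imputation variance
    b: float              # between-imputation variance
    t: float              # total variance = w_bar + (1 + 1/m) b
    df: float             # Rubin large-sample degrees of freedom

    @property
    def se(self) -> float:
        return float(np.sqrt(self.t))


def rubin_pool(estimates, variances) -> RubinPooled:
    """Pool estimates across completed datasets by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be 1-D and aligned")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 completed datasets")
    q_bar = float(q.mean())
    w_bar = float(u.mean())
    b = float(q.var(ddof=1))
    t = w_bar + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + w_bar / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = float(np.inf)
    return RubinPooled(m=m, q_bar=q_bar, w_bar=w_bar, b=b, t=float(t), df=float(df))


def mice_complete(df: pd.DataFrame, m: int = 10, seed: int = 0,
                  burn: int = 2) -> list[pd.DataFrame]:
    """m chained-equation completions of the numeric columns of ``df``.

    Completions are delegated to statsmodels' MICEData (predictive-mean
    matching per column); non-numeric columns pass through untouched.  With
    no missing data every completion equals the input.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    num = df.select_dtypes(include=[np.number])
    passthrough = df.drop(columns=num.columns)
    if not num.isna().any().any():
        return [df.copy() for _ in range(m)]
    from statsmodels.imputation.mice import MICEData
    np.random.seed(seed % (2 ** 32))  # MICEData uses the global numpy state
    clean = num.rename(columns=lambda c: c.replace(" ", "_"))
    mdata = MICEData(clean)
    out = []
    for _ in range(m):
        mdata.update_all(burn)
        completed = mdata.data.copy()
        completed.columns = num.columns
        completed.index = num.index
        merged = pd.concat([completed, passthrough], axis=1)[df.columns]
        out.append(merged)
    return out


def mice_with_rubin(df: pd.DataFrame, estimator, m: int = 10,
                    seed: int = 0) -> RubinPooled:
    """Run MICE completions and pool ``estimator(completed) -> (q, var)``."""
    completions = mice_complete(df, m=m, seed=seed)
    qs, us = [], []
    for comp in completions:
        q, u = estimator(comp)
        qs.append(float(q))
        us.append(float(u))
    return rubin_pool(qs, us)


# ---------------------------------------------------------------------------
# Step-wise variable omission
# ---------------------------------------------------------------------------

def stepwise_omission(classifier: SubtypeClassifier,
                      imputer: ImputationModel | None,
                      df: pd.DataFrame, reference_labels: pd.Series,
                      order: tuple[str, ...],
                      ) -> pd.DataFrame:
    """Robustness curve: omit variables cumulatively, re-impute, re-predict.

    ``order`` lists the variables to drop, one more at each step, and must
    begin with the three insulin-related variables (the evaluation protocol
    of interest).  Omitted insulin-related variables are re-imputed by the
    chained forest imputer; other omitted variables are filled with the
    classifier's training medians.  Step 0 is the untouched baseline.

    Returns one row per step: omitted list, overall accuracy on decided
    individuals, undecidable share, per-class precision/recall/F1.
    """
    unknown = [v for v in order if v not in classifier.features]
    if unknown:
        raise ValueError(f"omission order references unknown variables: {unknown}")
    if tuple(order[:3]) != tuple(DEFAULT_CHAIN_ORDER):
        raise ValueError(
            f"omission order must start with {DEFAULT_CHAIN_ORDER}")
    from .evaluate import classification_metrics  # local import avoids a cycle

    y_ref = reference_labels.loc[df["id"]].to_numpy() if "id" in df.columns and \
        not reference_labels.index.equals(df.index) else np.asarray(reference_labels)
    rows = []
    for step in range(len(order) + 1):
        omitted = list(order[:step])
        work = df.copy()
        for col in omitted:
            work[col] = np.nan
        insulin_omitted = [c for c in omitted if c in INSULIN_VARIABLES]
        other_omitted = [c for c in omitted if c not in INSULIN_VARIABLES]
        if insulin_omitted and imputer is not None:
            usable_preds = [p for p in imputer.predictors
                            if p == "sex_female" or p not in other_omitted]
            if usable_preds == list(imputer.predictors):
                work, _ = impute(imputer, work)
            else:
                # chain predictors themselves omitted: median-fill first
                for col in other_omitted:
                    work[col] = classifier.feature_medians.get(col, np.nan)
                work, _ = impute(imputer, work)
        for col in omitted:
            if work[col].isna().any():
                med = classifier.feature_medians.get(col, np.nan) \
                    if classifier.feature_medians is not None else np.nan
                if np.isnan(med):
                    rows.append({"step": step, "omitted": ",".join(omitted),
                                 "error": f"no fill value for {col}"})
                    return pd.DataFrame(rows)
                work[col] = work[col].fillna(med)
        pred = predict_with_abstention(classifier, work)
        metrics = classification_metrics(
            pd.Series(y_ref, index=pred["id"]), pred, exclude_undecidable=True)
        row = {"step": step, "omitted": ",".join(omitted),
               "accuracy": metrics.accuracy,
               "undecidable_share": metrics.undecidable_fraction,
               "error": ""}
        for c in classifier.class_order:
            row[f"precision_{c}"] = metrics.per_class.loc[c, "precision"]
            row[f"recall_{c}"] = metrics.per_class.loc[c, "recall"]
            row[f"f1_{c}"] = metrics.per_class.loc[c, "f1"]
        rows.append(row)
    return pd.DataFrame(rows)
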