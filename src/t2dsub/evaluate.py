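"""Classification metrics, temporal-consistency analysis and survival
analysis of diabetes complications by predicted subtype.

Metrics follow the usual multiclass conventions: overall accuracy, per-class
precision / recall / F1, and one-vs-rest AUC per subtype computed from the
vote-fraction probability vectors.  Undecidable individuals are excluded
from the metric denominators by default (their share is always reported
alongside), with an include-mode for audit.

Temporal consistency compares subtype labels at baseline and follow-up: a
migration matrix over {SIDD, SIRD, MOD, MARD, UNDECIDABLE}, per-subtype
consistency (the percentage whose label did not change), and the
participant-weighted mean consistency over the four subtypes.

Survival analysis produces Kaplan-Meier curves per subtype and a Cox
proportional-hazards model with subtype indicators (MARD reference)
adjusted for baseline age and sex (Efron tie handling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix, precision_recall_fscore_support, roc_auc_score,
)

from .cohort import SUBTYPES, UNDECIDABLE


@dataclass
class MetricsReport:
    accuracy: float
    per_class: pd.DataFrame        # index: subtype; precision, recall, f1, auc
    confusion: pd.DataFrame        # true x predicted counts (decided subset)
    macro_f1: float
    macro_auc: float | None
    undecidable_fraction: float
    exclude_undecidable: bool
    n_total: int
    n_decided: int


def classification_metrics(true_labels: pd.Series, predictions: pd.DataFrame,
                           exclude_undecidable: bool = True) -> MetricsReport:
    """Score predictions (from ``predict_with_abstention``) against reference labels.

    ``true_labels`` is indexed by id; ``predictions`` carries id, label and
    the four ``p_<subtype>`` columns.  With ``exclude_undecidable`` the
    decided subset forms the denominator and the excluded fraction is
    reported; otherwise undecidable predictions count as errors.
    """
    pred = predictions.set_index("id")
    common = pred.index.intersection(true_labels.index)
    if len(common) == 0:
        raise ValueError("no common ids between labels and predictions")
    pred = pred.loc[common]
    y_true = true_labels.loc[common].astype(str)
    undecidable = (pred["label"] == UNDECIDABLE)
    undec_frac = float(undecidable.mean())
    if exclude_undecidable:
        keep = ~undecidable
        if not keep.any():
            raise ValueError("decided subset is empty")
    else:
        keep = pd.Series(True, index=pred.index)
    yt = y_true[keep].to_numpy()
    yp = pred.loc[keep, "label"].to_numpy()
    accuracy = float((yt == yp).mean())

    label_space = list(SUBTYPES) + ([UNDECIDABLE] if not exclude_undecidable else [])
    prec, rec, f1, _ = precision_recall_fscore_support(
        yt, yp, labels=list(SUBTYPES), zero_division=0)
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1}, index=list(SUBTYPES))

    aucs = []
    prob_cols = [f"p_{c}" for c in SUBTYPES]
    have_probs = all(c in pred.columns for c in prob_cols)
    if have_probs:
        for c in SUBTYPES:
            y_bin = (y_true == c).astype(int).to_numpy()
            if y_bin.min() == y_bin.max():
                aucs.append(np.nan)
            else:
                aucs.append(float(roc_auc_score(y_bin, pred[f"p_{c}"].to_numpy())))
        per_class["auc"] = aucs
    cm = confusion_matrix(yt, yp, labels=label_space)
    confusion = pd.DataFrame(cm, index=label_space, columns=label_space)
    macro_auc = (float(np.nanmean(aucs))
                 if have_probs and not np.all(np.isnan(aucs)) else None)
    return MetricsReport(
        accuracy=accuracy, per_class=per_class, confusion=confusion,
        macro_f1=float(per_class["f1"].mean()), macro_auc=macro_auc,
        undecidable_fraction=undec_frac, exclude_undecidable=exclude_undecidable,
        n_total=int(len(pred)), n_decided=int(keep.sum()))


def roc_points(true_labels: pd.Series, predictions: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest ROC coordinates per subtype, for plotting/export."""
    from sklearn.metrics import roc_curve
    pred = predictions.set_index("id")
    common = pred.index.intersection(true_labels.index)
    rows = []
    for c in SUBTYPES:
        y_bin = (true_labels.loc[common].astype(str) == c).astype(int).to_numpy()
        if y_bin.min() == y_bin.max():
            continue
        fpr, tpr, thr = roc_curve(y_bin, pred.loc[common, f"p_{c}"].to_numpy())
        for f, t, th in zip(fpr, tpr, thr):
            rows.append({"subtype": c, "fpr": f, "tpr": t, "threshold": th})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Consistency over time
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    migration: pd.DataFrame        # baseline x follow-up counts
    per_subtype: pd.Series         # % unchanged, per baseline subtype
    mean_consistency: float        # participant-weighted, four subtypes only
    undecidable_consistency: float | None

    def sankey(self) -> dict:
        """Node/link JSON payload for a Sankey diagram of the migration."""
        base = [f"baseline:{s}" for s in self.migration.index]
        fup = [f"followup:{s}" for s in self.migration.columns]
        nodes = base + fup
        links = []
        for i, s in enumerate(self.migration.index):
            for j, t in enumerate(self.migration.columns):
                v = int(self.migration.iloc[i, j])
                if v > 0:
                    links.append({"source": i, "target": len(base) + j,
                                  "value": v})
        return {"nodes": [{"name": n} for n in nodes], "links": links}

    def sankey_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.sankey(), fh, indent=1)


def consistency_over_time(labels_t0: pd.Series, labels_t5: pd.Series,
                          exclude_undecidable: bool = True) -> ConsistencyReport:
    """Migration matrix and unchanged-label percentages between two visits.

    Both series are id-indexed labels over the four subtypes plus
    ``UNDECIDABLE``.  The migration matrix always covers all five
    categories.  With ``exclude_undecidable`` (the reporting convention for
    the four-subtype consistency) the per-subtype percentages are computed
    among individuals decided at *both* visits; the undecidable cluster's
    own consistency (share still undecidable at follow-up) is reported
    separately.  The mean consistency is participant-weighted over the four
    subtypes.
    """
    common = labels_t0.index.intersection(labels_t5.index)
    if len(common) == 0:
        raise ValueError("disjoint id sets between baseline and follow-up")
    space = list(SUBTYPES) + [UNDECIDABLE]
    t0 = pd.Categorical(labels_t0.loc[common].astype(str), categories=space)
    t5 = pd.Categorical(labels_t5.loc[common].astype(str), categories=space)
    migration = pd.crosstab(t0, t5, dropna=False)
    migration = migration.reindex(index=space, columns=space, fill_value=0)
    migration.index.name = "baseline"
    migration.columns.name = "followup"
    four = list(SUBTYPES)
    if exclude_undecidable:
        sub = migration.loc[four, four]       # decided at both visits
    else:
        sub = migration.loc[four, :]
    row_sums = sub.sum(axis=1)
    diag = pd.Series(np.diag(migration.loc[four, four]), index=four, dtype=float)
    with np.errstate(invalid="ignore"):
        per_subtype = 100.0 * diag / row_sums.replace(0, np.nan)
    present = [s for s in four if row_sums[s] > 0]
    weight = row_sums[present]
    mean_cons = float((per_subtype[present] * weight).sum() / weight.sum()) \
        if len(present) else float("nan")
    undec_row = migration.loc[UNDECIDABLE]
    undec = (100.0 * float(undec_row[UNDECIDABLE]) / float(undec_row.sum())
             if undec_row.sum() > 0 else None)
    return ConsistencyReport(migration=migration, per_subtype=per_subtype,
                             mean_consistency=mean_cons,
                             undecidable_consistency=undec)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResult:
    km: dict[str, dict[str, pd.DataFrame]]   # event -> subtype -> KM table
    cox: dict[str, pd.DataFrame | None]      # event -> HR table (vs MARD) or None
    flags: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=lambda: {"ties": "efron",
                                                "adjusted_for": ["age", "sex"]})


def survival_by_subtype(events: pd.DataFrame, baseline: pd.DataFrame,
                        group_col: str = "subtype",
                        reference: str = "MARD") -> SurvivalResult:
    """Kaplan-Meier curves per subtype and Cox HRs vs the MARD reference.

    ``events``: id, event_type, time, status ("occurred"/"censored").
    ``baseline``: id, age, sex and the grouping column.  The Cox model uses
    subtype indicator columns (reference omitted) plus baseline age and a
    female indicator; Efron approximation for ties.  Events with zero
    occurrences in every group skip the Cox fit with a flag.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    base = baseline.set_index("id")
    km_out: dict[str, dict[str, pd.DataFrame]] = {}
    cox_out: dict[str, pd.DataFrame | None] = {}
    flags: dict[str, str] = {}
    groups = [g for g in list(SUBTYPES) + [UNDECIDABLE]
              if (base[group_col] == g).any()]
    for ev in sorted(events["event_type"].unique()):
        sub = events[events["event_type"] == ev].set_index("id")
        joined = sub.join(base, how="inner")
        observed = (joined["status"] == "occurred").astype(int)
        km_out[ev] = {}
        for g in groups:
            sel = joined[group_col] == g
            if not sel.any():
                continue
            kmf = KaplanMeierFitter()
            kmf.fit(joined.loc[sel, "time"], observed[sel], label=g)
            tbl = kmf.survival_function_.copy()
            ci = kmf.confidence_interval_
            tbl.columns = ["survival"]
            tbl["ci_lower"] = ci.iloc[:, 0].to_numpy()
            tbl["ci_upper"] = ci.iloc[:, 1].to_numpy()
            km_out[ev][g] = tbl.reset_index().rename(columns={"timeline": "time"})
        if observed.sum() == 0:
            cox_out[ev] = None
            flags[ev] = "no events in any group; Cox skipped"
            continue
        X = pd.DataFrame({
            "time": joined["time"],
            "event": observed,
            "age": joined["age"].astype(float),
            "female": (joined["sex"] == "female").astype(float),
        })
        grp_cols = []
        for g in groups:
            if g != reference:
                col = (joined[group_col] == g).astype(float)
                if col.nunique() > 1:
                    X[f"grp_{g}"] = col
                    grp_cols.append(f"grp_{g}")
        # constant adjustment covariates carry no information and break the fit
        for col in ("age", "female"):
            if X[col].nunique() <= 1:
                X = X.drop(columns=[col])
        if not grp_cols:
            cox_out[ev] = None
            flags[ev] = "fewer than two groups represented; Cox skipped"
            continue
        cph = CoxPHFitter()
        cph.fit(X, duration_col="time", event_col="event")
        summ = cph.summary
        rows = []
        for g in groups:
            if g == reference or f"grp_{g}" not in summ.index:
                continue
            s = summ.loc[f"grp_{g}"]
            rows.append({
                "subtype": g, "reference": reference,
                "hr": float(np.exp(s["coef"])),
                "ci_lower": float(np.exp(s["coef lower 95%"])),
                "ci_upper": float(np.exp(s["coef upper 95%"])),
                "p": float(s["p"]),
            })
        cox_out[ev] = pd.DataFrame(rows)
    return SurvivalResult(km=km_out, cox=cox_out, flags=flags)
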