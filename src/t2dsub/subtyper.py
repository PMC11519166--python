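"""Random-forest subtype classifier with abstention, Boruta selection,
proximity matrix, 2-D embedding and feature importance.

The label-transfer model: a multiclass random forest trained on k-means
reference labels.  Class probabilities are plain vote fractions — the share
of trees whose leaf prediction is each subtype — and an individual whose
maximum vote fraction falls below the abstention threshold tau (default 0.6)
is relabelled ``UNDECIDABLE`` instead of being forced into a subtype.
Exactly tau counts as decided ("less than 0.6" abstains).

Feature selection uses the Boruta wrapper: each round appends shadow
features (column-wise permutations of the candidates), fits a forest, and
counts a "hit" for every real feature whose importance beats the best
shadow; features are confirmed or rejected by a Bonferroni-corrected
two-sided binomial test on the hit count.

The forest's proximity matrix — the fraction of trees in which two
individuals share a terminal leaf — is embedded in two dimensions with UMAP
(distance = 1 - proximity) for boundary-region visualisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .cohort import SUBTYPES, UNDECIDABLE

#: default candidate list for Boruta (the routinely available clinical set)
DEFAULT_CANDIDATES: tuple[str, ...] = (
    "age_at_diagnosis", "bmi", "hba1c_ifcc", "homa2b", "homa2ir",   # Ahlqvist five
    "cpeptide", "age", "waist", "fpg", "alt", "ggt", "hdl", "tg",
    "diabetes_duration", "sbp", "dbp", "ldl", "ast", "egfr", "uric_acid",
    "wbc", "hb", "platelets", "albuminuria", "sex_female",
)

#: default 15-variable feature list of the extended model
DEFAULT_RF15: tuple[str, ...] = (
    "age_at_diagnosis", "bmi", "hba1c_ifcc", "homa2b", "homa2ir",
    "cpeptide", "age", "waist", "fpg", "alt", "ggt", "hdl", "tg",
    "diabetes_duration", "egfr",
)

DEFAULT_GRID: dict[str, tuple] = {
    "max_features": ("sqrt", 0.5),
    "n_estimators": (300, 500),
    "min_samples_leaf": (1, 5),
    "max_leaf_nodes": (None, 64),
}


def encode_features(df: pd.DataFrame, features: list[str] | tuple[str, ...]
                    ) -> pd.DataFrame:
    """Numeric design matrix; ``sex_female`` is derived from ``sex`` on demand."""
    out = pd.DataFrame(index=df.index)
    for f in features:
        if f == "sex_female" and "sex_female" not in df.columns:
            out[f] = (df["sex"] == "female").astype(float)
        else:
            col = df[f]
            if col.dtype == "boolean" or col.dtype == bool:
                out[f] = col.astype("float64")
            else:
                out[f] = pd.to_numeric(col, errors="raise")
    return out


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

@dataclass
class BorutaResult:
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    history: pd.DataFrame     # per round x feature: hit indicator
    exhausted: bool           # max_rounds reached with tentative features left

    @property
    def selected(self) -> list[str]:
        return list(self.confirmed)


def select_features_boruta(df: pd.DataFrame, labels: pd.Series,
                           candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
                           max_rounds: int = 50, alpha: float = 0.05,
                           n_estimators: int = 200, seed: int = 0,
                           ) -> BorutaResult:
    """Boruta shadow-feature selection against the subtype labels.

    Per round: permute a shadow copy of every undecided candidate, fit a
    forest on [real | shadow] columns, and count a hit for each real feature
    whose impurity importance exceeds the best shadow importance.  Features
    are confirmed (rejected) when the one-sided binomial tail probability of
    their hit count under p=0.5, Bonferroni-corrected across the original
    candidates, drops below ``alpha``.  ``alpha >= 1`` is the degenerate
    documented mode: any feature that ever beats the best shadow is
    confirmed immediately.
    """
    missing = [c for c in candidates if c != "sex_female" and c not in df.columns]
    if missing:
        raise ValueError(f"candidate features absent from table: {missing}")
    X_all = encode_features(df, candidates)
    if X_all.isna().any().any():
        raise ValueError("candidate features contain missing values; impute first")
    y = labels.loc[df["id"]].to_numpy() if "id" in df.columns and \
        not labels.index.equals(df.index) else np.asarray(labels)
    rng = np.random.default_rng(seed)

    undecided = list(candidates)
    confirmed: list[str] = []
    rejected: list[str] = []
    hits = {f: 0 for f in candidates}
    rounds_seen = {f: 0 for f in candidates}
    m = len(candidates)  # Bonferroni correction factor
    hist_rows = []

    for r in range(1, max_rounds + 1):
        if not undecided:
            break
        X = X_all[undecided].to_numpy()
        # at least 5 shadows, as in the reference implementations: a thin
        # shadow pool late in the run would make the max-shadow bar too easy
        n_shadow = max(len(undecided), 5)
        shadows = np.empty((X.shape[0], n_shadow))
        for j in range(n_shadow):
            shadows[:, j] = rng.permutation(X[:, j % X.shape[1]])
        design = np.hstack([X, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2 ** 31)),
            n_jobs=1)
        forest.fit(design, y)
        imp = forest.feature_importances_
        real_imp = imp[:len(undecided)]
        best_shadow = imp[len(undecided):].max()
        for j, f in enumerate(undecided):
            hit = bool(real_imp[j] > best_shadow)
            hits[f] += hit
            rounds_seen[f] += 1
            hist_rows.append({"round": r, "feature": f, "hit": hit,
                              "importance": float(real_imp[j]),
                              "best_shadow": float(best_shadow)})
        newly_decided = []
        for f in undecided:
            k, n = hits[f], rounds_seen[f]
            if alpha >= 1.0:
                if k >= 1:
                    confirmed.append(f)
                    newly_decided.append(f)
                continue
            p_hi = binomtest(k, n, 0.5, alternative="greater").pvalue
            p_lo = binomtest(k, n, 0.5, alternative="less").pvalue
            if min(p_hi * m, 1.0) < alpha:
                confirmed.append(f)
                newly_decided.append(f)
            elif min(p_lo * m, 1.0) < alpha:
                rejected.append(f)
                newly_decided.append(f)
        undecided = [f for f in undecided if f not in newly_decided]

    return BorutaResult(
        confirmed=confirmed, rejected=rejected, tentative=undecided,
        history=pd.DataFrame(hist_rows), exhausted=bool(undecided))


# ---------------------------------------------------------------------------
# Training with OOB grid tuning
# ---------------------------------------------------------------------------

@dataclass
class SubtypeClassifier:
    """Trained forest + feature list + class order + abstention threshold."""

    forest: RandomForestClassifier
    features: tuple[str, ...]
    class_order: tuple[str, ...] = SUBTYPES
    tau: float = 0.6
    tuning_record: pd.DataFrame | None = None
    feature_medians: pd.Series | None = None   # training medians, for omission studies
    seed: int = 0
    notes: dict = field(default_factory=dict)

    def save(self, path) -> None:
        import joblib
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "SubtypeClassifier":
        import joblib
        return joblib.load(path)

    def save_manifest(self, path) -> None:
        payload = {
            "features": list(self.features), "class_order": list(self.class_order),
            "tau": self.tau, "seed": self.seed, "notes": self.notes,
            "n_estimators": self.forest.n_estimators,
            "tuning_record": (self.tuning_record.to_dict("records")
                              if self.tuning_record is not None else None),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=str)


def train_test_split_ids(ids: np.ndarray, train_fraction: float = 0.7,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random 70/30 id split (the study's training/test protocol)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.asarray(ids)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    return ids[perm[:n_train]], ids[perm[n_train:]]


def tune_and_train(df: pd.DataFrame, labels: pd.Series,
                   features: tuple[str, ...] = DEFAULT_RF15,
                   grid: dict[str, tuple] | None = None,
                   tau: float = 0.6, seed: int = 0,
                   ) -> SubtypeClassifier:
    """Grid-search forest hyper-parameters by out-of-bag accuracy, refit best.

    Grid axes: ``max_features`` (per-split feature count), ``n_estimators``
    (trees), ``min_samples_leaf`` (minimum terminal-node size) and
    ``max_leaf_nodes`` (maximum terminal nodes).  Ties break to the earliest
    grid point; everything is deterministic for a fixed seed.
    """
    grid = DEFAULT_GRID if grid is None else grid
    if any(len(v) == 0 for v in grid.values()) or not grid:
        raise ValueError("empty tuning grid")
    y = np.asarray(labels.loc[df["id"]] if "id" in df.columns and
                   not labels.index.equals(df.index) else labels)
    present = set(np.unique(y))
    absent = [c for c in SUBTYPES if c not in present]
    if absent:
        raise ValueError(f"classes absent from training labels: {absent}")
    X = encode_features(df, features)
    if X.isna().any().any():
        raise ValueError("training features contain missing values; impute first")

    axes = [a for a in ("max_features", "n_estimators", "min_samples_leaf",
                        "max_leaf_nodes") if a in grid]
    records = []
    best = None
    for combo in product(*(grid[a] for a in axes)):
        params = dict(zip(axes, combo))
        forest = RandomForestClassifier(
            oob_score=True, bootstrap=True, random_state=seed, n_jobs=1, **params)
        forest.fit(X.to_numpy(), y)
        oob = float(forest.oob_score_)
        records.append({**params, "oob_accuracy": oob})
        if best is None or oob > best[0] + 1e-12:
            best = (oob, forest, params)
    record = pd.DataFrame(records)
    oob_best, forest_best, chosen = best
    return SubtypeClassifier(
        forest=forest_best, features=tuple(features), class_order=SUBTYPES,
        tau=tau, tuning_record=record, feature_medians=X.median(), seed=seed,
        notes={"chosen": {k: str(v) for k, v in chosen.items()},
               "oob_accuracy": oob_best,
               "probability": "vote fractions over trees"})


# ---------------------------------------------------------------------------
# Prediction with abstention
# ---------------------------------------------------------------------------

def vote_fractions(model: SubtypeClassifier, X: np.ndarray) -> np.ndarray:
    """Per-class fraction of trees voting that class (n x 4, rows sum to 1)."""
    classes = list(model.forest.classes_)
    order = [classes.index(c) for c in model.class_order]
    counts = np.zeros((X.shape[0], len(classes)))
    for tree in model.forest.estimators_:
        pred = tree.predict(X.astype(np.float32))
        counts[np.arange(X.shape[0]), pred.astype(int)] += 1
    frac = counts / len(model.forest.estimators_)
    return frac[:, order]


def predict_with_abstention(model: SubtypeClassifier, df: pd.DataFrame,
                            tau: float | None = None) -> pd.DataFrame:
    """Predict subtype with the undecidable reject option.

    Returns one row per input row: four vote-fraction columns, ``max_prob``,
    ``label`` (a subtype, or ``UNDECIDABLE`` when ``max_prob < tau``) and an
    ``argmax_tie`` flag (ties broken by the canonical class order).
    """
    tau = model.tau if tau is None else tau
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must be in [0, 1]")
    missing = [f for f in model.features
               if f != "sex_female" and f not in df.columns]
    if missing:
        raise ValueError(f"model features missing from table: {missing}")
    X = encode_features(df, model.features)
    na_cols = list(X.columns[X.isna().any()])
    if na_cols:
        raise ValueError(f"features with missing values: {na_cols}; impute first")
    probs = vote_fractions(model, X.to_numpy())
    k = probs.shape[1]
    argmax = probs.argmax(axis=1)
    maxp = probs[np.arange(len(probs)), argmax]
    tie = (np.isclose(probs, maxp[:, None]).sum(axis=1) > 1)
    labels = np.array([model.class_order[j] for j in argmax], dtype=object)
    labels[maxp < tau] = UNDECIDABLE
    out = pd.DataFrame(probs, columns=[f"p_{c}" for c in model.class_order])
    out.insert(0, "id", df["id"].to_numpy() if "id" in df.columns
               else np.arange(len(df)))
    out["max_prob"] = maxp
    out["label"] = labels
    out["argmax_tie"] = tie
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    return out


# ---------------------------------------------------------------------------
# Proximity and embedding
# ---------------------------------------------------------------------------

def proximity_matrix(model: SubtypeClassifier, df: pd.DataFrame) -> np.ndarray:
    """(i, j) = fraction of trees in which i and j share a terminal leaf."""
    X = encode_features(df, model.features).to_numpy()
    leaves = model.forest.apply(X)            # (n, n_trees)
    n, T = leaves.shape
    P = np.zeros((n, n), dtype=np.float64)
    for t in range(T):
        col = leaves[:, t]
        P += (col[:, None] == col[None, :])
    P /= T
    return P


def embed_proximity(P: np.ndarray, seed: int = 0,
                    n_neighbors: int = 15) -> np.ndarray:
    """UMAP embedding of distance = 1 - proximity into two dimensions."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1] or not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("proximity matrix must be square and symmetric")
    n = P.shape[0]
    if n == 1:
        return np.zeros((1, 2))
    import umap  # deferred: numba compilation is slow at import time
    D = 1.0 - P
    np.fill_diagonal(D, 0.0)
    reducer = umap.UMAP(metric="precomputed", n_components=2,
                        n_neighbors=min(n_neighbors, n - 1),
                        random_state=seed % (2 ** 32))
    return np.asarray(reducer.fit_transform(D))


# ---------------------------------------------------------------------------
# Permutation feature importance
# ---------------------------------------------------------------------------

def feature_importance(model: SubtypeClassifier, df: pd.DataFrame,
                       labels: pd.Series, repeats: int = 10, seed: int = 0,
                       per_class: bool = False) -> pd.DataFrame:
    """Permutation importance on held-out data, averaged over ``repeats``.

    Returns per feature: mean importance, SD, rank (1 = most important); with
    ``per_class`` additionally one one-vs-rest accuracy-drop column per
    subtype.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = encode_features(df, model.features)
    y = np.asarray(labels.loc[df["id"]] if "id" in df.columns and
                   not labels.index.equals(df.index) else labels)
    res = permutation_importance(model.forest, X.to_numpy(), y,
                                 n_repeats=repeats, random_state=seed, n_jobs=1)
    out = pd.DataFrame({
        "feature": list(model.features),
        "importance": res.importances_mean,
        "importance_sd": res.importances_std,
    })
    out["rank"] = out["importance"].rank(ascending=False, method="first").astype(int)
    if per_class:
        rng = np.random.default_rng(seed)
        Xv = X.to_numpy()
        base_pred = model.forest.predict(Xv)
        for c in model.class_order:
            base = ((base_pred == c) == (y == c)).mean()
            drops = np.zeros(len(model.features))
            for j in range(len(model.features)):
                acc = []
                for _ in range(repeats):
                    Xp = Xv.copy()
                    Xp[:, j] = rng.permutation(Xp[:, j])
                    pred = model.forest.predict(Xp)
                    acc.append(((pred == c) == (y == c)).mean())
                drops[j] = base - float(np.mean(acc))
            out[f"importance_{c}"] = drops
    return out.sort_values("rank").reset_index(drop=True)
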