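"""Sex-stratified k-means reference labelling of type 2 diabetes subtypes.

The reference ("true") labels for the classifier are produced by k-means with
k = 4 on the five Ahlqvist variables — age at diagnosis, BMI, HbA1c, HOMA2-B
and HOMA2-IR — run separately for women and men to remove sex effects, with
many random restarts (default 1000) keeping the lowest within-cluster sum of
squares.  Variables are z-scored within each sex stratum before clustering so
no single variable dominates the Euclidean metric.

Cluster indices are mapped to subtype names by a greedy rule on the
standardised centres: the centre with the highest HbA1c is SIDD (severe
insulin-deficient); among the rest the highest HOMA2-IR is SIRD (severe
insulin-resistant); among the rest the youngest age at diagnosis is MOD
(mild obesity-related); the remainder is MARD (mild age-related).

Cluster stability is audited with a bootstrap Jaccard index: the data are
resampled with replacement, k-means is re-fitted, each reference cluster is
matched to the re-fitted cluster with which it shares the largest
intersection-over-union of ids, and the per-subtype Jaccard values are
aggregated over resamples (default 2000).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort import AHLQVIST_VARIABLES, SUBTYPES

_SEXES = ("female", "male")


@dataclass
class SexClusterModel:
    means: pd.Series          # per-variable standardisation mean
    sds: pd.Series            # per-variable standardisation SD
    centres: np.ndarray       # (4, 5) in z-space, original k-means index order
    name_map: dict[int, str]  # centre index -> subtype
    inertia: float

    def standardise(self, X: pd.DataFrame) -> np.ndarray:
        return ((X[list(self.means.index)] - self.means) / self.sds).to_numpy()


@dataclass
class ClusterModel:
    """Per-sex standardisation + 4 centres + subtype naming; reloadable artifact."""

    variables: tuple[str, ...]
    per_sex: dict[str, SexClusterModel]
    restarts: int
    seed: int
    notes: dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {
            "variables": list(self.variables),
            "restarts": self.restarts,
            "seed": self.seed,
            "notes": self.notes,
            "per_sex": {
                sex: {
                    "means": m.means.to_dict(),
                    "sds": m.sds.to_dict(),
                    "centres": m.centres.tolist(),
                    "name_map": {str(k): v for k, v in m.name_map.items()},
                    "inertia": m.inertia,
                } for sex, m in self.per_sex.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        per_sex = {
            sex: SexClusterModel(
                means=pd.Series(d["means"]), sds=pd.Series(d["sds"]),
                centres=np.asarray(d["centres"], dtype=float),
                name_map={int(k): v for k, v in d["name_map"].items()},
                inertia=d["inertia"])
            for sex, d in payload["per_sex"].items()}
        return cls(variables=tuple(payload["variables"]), per_sex=per_sex,
                   restarts=payload["restarts"], seed=payload["seed"],
                   notes=payload.get("notes", {}))


def assign_subtype_names(centres: np.ndarray,
                         variables: tuple[str, ...] = AHLQVIST_VARIABLES,
                         tol: float = 1e-9) -> tuple[dict[int, str], list[str]]:
    """Greedy naming of four standardised centres; returns (name_map, rule trace).

    Ties within ``tol`` on a deciding variable abort with an error demanding a
    manual mapping — silent arbitrary naming would corrupt every downstream
    comparison.
    """
    if centres.shape != (4, len(variables)):
        raise ValueError(f"expected centres of shape (4, {len(variables)})")
    cols = {v: i for i, v in enumerate(variables)}
    remaining = list(range(4))
    name_map: dict[int, str] = {}
    trace: list[str] = []

    def pick(var: str, how: str, subtype: str) -> None:
        vals = centres[remaining, cols[var]]
        order = np.argsort(vals)
        j = order[-1] if how == "max" else order[0]
        runner = order[-2] if how == "max" else order[1]
        if abs(vals[j] - vals[runner]) < tol:
            raise ValueError(
                f"tie on {var} while naming {subtype}; manual mapping required")
        idx = remaining[int(j)]
        name_map[idx] = subtype
        trace.append(f"{subtype} := arg{how} {var} over centres {remaining} -> {idx}")
        remaining.remove(idx)

    pick("hba1c_ifcc", "max", "SIDD")
    pick("homa2ir", "max", "SIRD")
    pick("age_at_diagnosis", "min", "MOD")
    name_map[remaining[0]] = "MARD"
    trace.append(f"MARD := remaining centre {remaining[0]}")
    return name_map, trace


def _fit_stratum(X: pd.DataFrame, restarts: int, seed: int) -> SexClusterModel:
    means = X.mean()
    sds = X.std(ddof=0)
    if (sds <= 0).any():
        bad = list(sds.index[sds <= 0])
        raise ValueError(f"zero variance in clustering variables: {bad}")
    Z = ((X - means) / sds).to_numpy()
    km = KMeans(n_clusters=4, init="random", n_init=restarts,
                random_state=seed % (2 ** 32))
    km.fit(Z)
    name_map, trace = assign_subtype_names(km.cluster_centers_,
                                           tuple(X.columns))
    model = SexClusterModel(means=means, sds=sds, centres=km.cluster_centers_,
                            name_map=name_map, inertia=float(km.inertia_))
    model.trace = trace
    return model


def fit_kmeans_by_sex(df: pd.DataFrame, seed: int, restarts: int = 1000,
                      variables: tuple[str, ...] = AHLQVIST_VARIABLES,
                      ) -> tuple[ClusterModel, pd.Series]:
    """Fit the reference k-means model per sex and label every individual.

    ``df`` must hold the five clustering variables complete (impute upstream)
    plus ``id`` and ``sex``.  Each sex stratum needs at least 16 individuals
    (4 per cluster).  Deterministic for a fixed seed.
    """
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValueError(f"clustering variables absent: {missing}")
    if df[list(variables)].isna().any().any():
        raise ValueError("clustering variables contain missing values; impute first")
    per_sex: dict[str, SexClusterModel] = {}
    labels = pd.Series(index=df["id"].to_numpy(), dtype=object, name="kmeans_subtype")
    for i, sex in enumerate(_SEXES):
        stratum = df[df["sex"] == sex]
        if len(stratum) < 16:
            raise ValueError(
                f"stratum {sex!r} has {len(stratum)} individuals; >=16 required")
        model = _fit_stratum(stratum[list(variables)], restarts, seed + i)
        per_sex[sex] = model
        Z = model.standardise(stratum[list(variables)])
        idx = np.argmin(
            ((Z[:, None, :] - model.centres[None, :, :]) ** 2).sum(-1), axis=1)
        labels.loc[stratum["id"].to_numpy()] = [model.name_map[j] for j in idx]
    cm = ClusterModel(variables=tuple(variables), per_sex=per_sex,
                      restarts=restarts, seed=seed,
                      notes={"standardisation": "z-score within sex",
                             "naming": "greedy: SIDD=max HbA1c, SIRD=max HOMA2-IR, "
                                       "MOD=min age at diagnosis, MARD=rest"})
    return cm, labels


def assign_by_nearest_centre(model: ClusterModel, df: pd.DataFrame) -> pd.DataFrame:
    """Label individuals by the nearest standardised centre of their sex stratum.

    Returns a frame with ``subtype`` and a ``tie`` flag (equidistant centres are
    broken deterministically by the canonical subtype order SIDD<SIRD<MOD<MARD).
    """
    missing = [v for v in model.variables if v not in df.columns]
    if missing:
        raise ValueError(f"variables absent: {missing}")
    if df[list(model.variables)].isna().any().any():
        raise ValueError("missing clustering variables; route to imputation")
    out = pd.DataFrame(index=df["id"].to_numpy(),
                       columns=["subtype", "tie"], dtype=object)
    prec = {s: k for k, s in enumerate(SUBTYPES)}
    for sex, m in model.per_sex.items():
        stratum = df[df["sex"] == sex]
        if stratum.empty:
            continue
        Z = m.standardise(stratum[list(model.variables)])
        d2 = ((Z[:, None, :] - m.centres[None, :, :]) ** 2).sum(-1)
        for row, pid in enumerate(stratum["id"].to_numpy()):
            dmin = d2[row].min()
            cand = [m.name_map[j] for j in range(4)
                    if np.isclose(d2[row, j], dmin, rtol=0, atol=1e-12)]
            cand.sort(key=prec.__getitem__)
            out.loc[pid, "subtype"] = cand[0]
            out.loc[pid, "tie"] = len(cand) > 1
    return out


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def best_match_jaccard(reference_sets: list[set],
                       candidate_sets: list[set]) -> list[float]:
    """Per reference cluster, the Jaccard index of its best-matching candidate."""
    return [max((_jaccard(r, c) for c in candidate_sets), default=0.0)
            for r in reference_sets]


@dataclass
class JaccardReport:
    """Per sex x subtype bootstrap Jaccard summary (min / mean / max over B)."""

    table: pd.DataFrame   # columns: sex, subtype, min, mean, max, n_resamples

    def overall_range(self) -> tuple[float, float]:
        return float(self.table["min"].min()), float(self.table["max"].max())


def jaccard_stability(df: pd.DataFrame, model: ClusterModel,
                      reference_labels: pd.Series, B: int = 2000,
                      seed: int = 0, restarts: int = 20) -> JaccardReport:
    """Bootstrap cluster-stability audit.

    For each of ``B`` resamples (with replacement, per sex stratum) k-means is
    re-fitted and every reference cluster is matched to the re-fitted cluster
    maximising the Jaccard index over the unique resampled ids.  Bootstrap
    refits use ``restarts`` random starts (a compute choice; the reference fit
    used ``model.restarts``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    records = {sex: {s: [] for s in SUBTYPES} for sex in model.per_sex}
    for sex, m in model.per_sex.items():
        stratum = df[df["sex"] == sex].reset_index(drop=True)
        ids = stratum["id"].to_numpy()
        ref = reference_labels.loc[ids]
        X = stratum[list(model.variables)]
        for b in range(B):
            take = rng.integers(0, len(stratum), size=len(stratum))
            boot = stratum.iloc[take]
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            means = boot[list(model.variables)].mean()
            sds = boot[list(model.variables)].std(ddof=0)
            if (sds <= 0).any():
                continue
            Z = ((boot[list(model.variables)] - means) / sds).to_numpy()
            km = KMeans(n_clusters=4, init="random", n_init=restarts,
                        random_state=sub_seed % (2 ** 32)).fit(Z)
            boot_ids = boot["id"].to_numpy()
            new_sets = [set(boot_ids[km.labels_ == j]) for j in range(4)]
            ref_sets = [set(ids[(ref == s).to_numpy()]) & set(boot_ids)
                        for s in SUBTYPES]
            for s, jac in zip(SUBTYPES, best_match_jaccard(ref_sets, new_sets)):
                records[sex][s].append(jac)
    rows = []
    for sex in model.per_sex:
        for s in SUBTYPES:
            vals = np.array(records[sex][s], dtype=float)
            rows.append({"sex": sex, "subtype": s,
                         "min": float(vals.min()), "mean": float(vals.mean()),
                         "max": float(vals.max()), "n_resamples": len(vals)})
    return JaccardReport(pd.DataFrame(rows))
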