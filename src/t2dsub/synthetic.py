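"""Synthetic cohort generator emulating a four-cluster type 2 diabetes mixture.

Every downstream stage of the pipeline (k-means pre-labelling, random-forest
label transfer, imputation, consistency and survival audits) is exercised on
cohorts produced here, because the clinical study data are restricted.  The
generator draws individuals from a per-subtype truncated multivariate normal
whose default per-cluster means and SDs are the published baseline
characteristics of the four subtypes (SIDD / SIRD / MOD / MARD), with

* mixing weights proportional to the published cluster counts 116:90:109:216,
* a ``boundary_blend`` fraction (default 0.14, emulating the share of
  boundary individuals the classifier later abstains on) drawn midway
  between two cluster centres and labelled ``BLENDED`` — a generator-truth
  category deliberately distinct from the classifier's ``UNDECIDABLE``,
* right-skewed variables (triacylglycerols, transaminases, gamma-GT,
  albuminuria) drawn lognormally from their published median/IQR, and
  C-peptide drawn lognormally moment-matched to its published cluster
  mean/SD,
* HOMA2-B and HOMA2-IR derived from (glucose, C-peptide) through the HOMA2
  approximation surface — as in reality, where they are deterministic
  functions of the fasting measurements — rescaled within each mixture
  component to match the published cluster moments exactly, plus a small
  independent noise term.  This makes the insulin-related block imputable
  from routine variables, the property the missing-variable classification
  workflow relies on,
* configurable missing-at-random rates, a joint "insulin block" missingness
  pattern, five-year within-person drift, and subtype-specific exponential
  complication hazards (defaults: retinopathy HR 2.08 for SIDD vs MARD,
  CKD HR 1.58 for SIRD vs MARD).

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    BLENDED, DRUG_FLAGS, SUBTYPES, CohortTable, DataDictionary,
    default_dictionary,
)
from .homa2 import approximation_surface

CONTINUOUS_VARIABLES: tuple[str, ...] = (
    "age_at_diagnosis", "diabetes_duration", "bmi", "waist", "sbp", "dbp",
    "fpg", "hba1c_ifcc", "cpeptide", "homa2b", "homa2ir", "tg", "hdl", "ldl",
    "ast", "alt", "ggt", "egfr", "uric_acid", "wbc", "hb", "platelets",
    "albuminuria",
)

#: derived from (fpg, cpeptide) through the HOMA2 surface, not drawn
DERIVED_HOMA2: tuple[str, ...] = ("homa2b", "homa2ir")

DRAWN_VARIABLES: tuple[str, ...] = tuple(
    v for v in CONTINUOUS_VARIABLES if v not in DERIVED_HOMA2)

#: variables sampled on the log scale from published median [IQR]
LOGNORMAL_VARIABLES: frozenset[str] = frozenset(
    {"tg", "ast", "alt", "ggt", "albuminuria"})

#: sampled on the log scale, moment-matched to a published mean +- SD
MOMENT_LOGNORMAL_VARIABLES: frozenset[str] = frozenset({"cpeptide"})

BINARY_VARIABLES: tuple[str, ...] = ("smoker", "alcohol", *DRUG_FLAGS)

# per-subtype (mean, sd) for normal variables, (median, q1, q3) for lognormal,
# in the order SIDD, SIRD, MOD, MARD
_CLUSTER_MOMENTS: dict[str, tuple] = {
    "age_at_diagnosis": ((44, 10), (48, 12), (41, 7), (60, 7)),
    "diabetes_duration": ((24, 11), (14, 8), (19, 9), (16, 8)),
    "bmi": ((24.5, 4.7), (32.9, 8.5), (30.7, 5.3), (22.5, 2.7)),
    "waist": ((90, 13), (106, 17), (100, 12), (84, 9)),
    "sbp": ((128, 18), (132, 18), (134, 19), (131, 18)),
    "dbp": ((72, 12), (75, 13), (77, 11), (71, 11)),
    "fpg": ((8.9, 2.4), (7.3, 1.6), (7.3, 2.0), (7.4, 1.5)),
    "hba1c_ifcc": ((72, 11), (49, 6), (49, 6), (49, 5)),
    "cpeptide": ((0.54, 0.29), (1.59, 0.65), (0.73, 0.29), (0.64, 0.28)),
    "homa2b": ((37.4, 11.2), (132.2, 39.9), (69.6, 18.3), (56.0, 15.8)),
    "homa2ir": ((1.31, 0.53), (3.86, 0.97), (1.59, 0.47), (1.39, 0.48)),
    "tg": ((1.2, 0.9, 2.0), (1.7, 1.3, 2.3), (1.3, 0.9, 1.8), (1.0, 0.7, 1.4)),
    "hdl": ((1.4, 0.4), (1.3, 0.3), (1.4, 0.3), (1.5, 0.4)),
    "ldl": ((2.6, 0.8), (2.7, 0.7), (2.7, 0.7), (2.6, 0.8)),
    "ast": ((21, 17, 28), (23, 17, 36), (20, 16, 28), (21, 17, 26)),
    "alt": ((21, 15, 31), (26, 15, 47), (20, 15, 35), (17, 12, 24)),
    "ggt": ((26, 18, 44), (38, 23, 59), (24, 16, 36), (22, 17, 35)),
    "egfr": ((66, 21), (56, 22), (70, 19), (62, 16)),
    "uric_acid": ((308, 81), (359, 75), (315, 70), (308, 74)),
    "wbc": ((6.4, 1.9), (6.7, 1.9), (6.5, 1.7), (5.7, 1.9)),
    "hb": ((139, 17), (141, 20), (138, 17), (132, 17)),
    "platelets": ((22.2, 5.7), (21.9, 6.1), (23.2, 6.7), (21.3, 7.0)),
    "albuminuria": ((28, 8, 155), (35, 10, 165), (18, 7, 69), (16, 7, 44)),
}

_CLUSTER_COUNTS = {"SIDD": 116, "SIRD": 90, "MOD": 109, "MARD": 216}
_FEMALE_SHARE = {"SIDD": 0.37, "SIRD": 0.49, "MOD": 0.53, "MARD": 0.47}

_BINARY_RATES: dict[str, tuple[float, float, float, float]] = {
    "smoker": (0.16, 0.23, 0.17, 0.13),
    "alcohol": (0.26, 0.30, 0.28, 0.30),
    "sulfonylurea": (0.16, 0.04, 0.10, 0.07),
    "metformin": (0.60, 0.40, 0.62, 0.34),
    "dpp4i": (0.56, 0.42, 0.67, 0.61),
    "sglt2i": (0.35, 0.31, 0.28, 0.15),
    "glp1ra": (0.17, 0.21, 0.10, 0.01),
    "insulin": (0.62, 0.09, 0.26, 0.23),
}

# Within-cluster correlation structure, shared across clusters and sexes,
# expressed as a latent-factor model (metabolic/adiposity M, glycaemia G,
# liver L, renal R, blood pressure P): corr = Lambda Lambda' + diag(1 - sum
# of squared loadings).  Positive semi-definite by construction.  The strong
# couplings of the HOMA2 indices to the metabolic and glycaemic factors make
# the insulin-related block imputable from routine variables — the real-data
# feature the missing-variable classification workflow depends on.
# Lognormal variables correlate on the log scale.
_FACTOR_LOADINGS: dict[str, dict[str, float]] = {
    # var: {factor: loading}
    "diabetes_duration": {"R": 0.25},
    "bmi": {"M": 0.80},
    "waist": {"M": 0.85},
    "sbp": {"P": 0.70, "M": 0.15},
    "dbp": {"P": 0.75},
    "fpg": {"G": 0.85},
    "hba1c_ifcc": {"G": 0.70},
    "cpeptide": {"M": 0.80, "G": -0.10},
    "tg": {"M": 0.50, "L": 0.25},
    "hdl": {"M": -0.45},
    "ast": {"L": 0.70},
    "alt": {"L": 0.75, "M": 0.25},
    "ggt": {"L": 0.55, "M": 0.20},
    "egfr": {"R": -0.70},
    "uric_acid": {"R": 0.45, "M": 0.25},
    "wbc": {"M": 0.20},
    "albuminuria": {"R": 0.40, "G": 0.15, "P": 0.20},
}
_FACTORS = ("M", "G", "L", "R", "P")

# five-year drift: per-variable (mean shift, per-visit noise SD sigma); the
# five-year change is N(shift, 2*sigma^2) — two visit-level noise draws
_DEFAULT_DRIFT: dict[str, tuple[float, float]] = {
    "bmi": (0.0, 1.2), "waist": (0.0, 3.0), "sbp": (2.0, 8.0), "dbp": (0.0, 5.0),
    "fpg": (0.0, 1.0), "hba1c_ifcc": (0.0, 5.0), "homa2b": (-4.0, 10.0),
    "homa2ir": (0.0, 0.45), "cpeptide": (0.0, 0.12), "tg": (0.0, 0.3),
    "hdl": (0.0, 0.12), "ldl": (0.0, 0.4), "ast": (0.0, 5.0), "alt": (0.0, 6.0),
    "ggt": (0.0, 10.0), "egfr": (-4.0, 6.0), "uric_acid": (0.0, 40.0),
    "wbc": (0.0, 0.8), "hb": (-2.0, 8.0), "platelets": (0.0, 2.5),
    "albuminuria": (5.0, 30.0),
}


@dataclass(frozen=True)
class Hazard:
    """Exponential baseline rate (per year, MARD reference) and HRs per label."""

    baseline_rate: float
    hazard_ratios: dict[str, float]

    def rate_for(self, label: str) -> float:
        return self.baseline_rate * self.hazard_ratios.get(label, 1.0)


_DEFAULT_HAZARDS: dict[str, Hazard] = {
    "retinopathy": Hazard(0.020, {"SIDD": 2.08, "SIRD": 1.30, "MOD": 1.20,
                                  "MARD": 1.0, BLENDED: 1.50}),
    "ckd": Hazard(0.025, {"SIDD": 1.20, "SIRD": 1.58, "MOD": 0.90,
                          "MARD": 1.0, BLENDED: 1.25}),
    "proteinuria": Hazard(0.030, {"SIDD": 1.40, "SIRD": 1.50, "MOD": 1.10,
                                  "MARD": 1.0, BLENDED: 1.25}),
    "coronary_artery_disease": Hazard(0.010, {"SIDD": 1.30, "SIRD": 1.40,
                                              "MOD": 1.10, "MARD": 1.0,
                                              BLENDED: 1.20}),
}


def default_correlation() -> pd.DataFrame:
    """Within-cluster correlation of the drawn variables (factor structure)."""
    p = len(DRAWN_VARIABLES)
    lam = np.zeros((p, len(_FACTORS)))
    for i, v in enumerate(DRAWN_VARIABLES):
        for f, w in _FACTOR_LOADINGS.get(v, {}).items():
            lam[i, _FACTORS.index(f)] = w
    corr = lam @ lam.T
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=DRAWN_VARIABLES, columns=DRAWN_VARIABLES)


def _internal_loc_scale(var: str, moments: tuple) -> tuple[float, float]:
    """(loc, scale) on the sampling scale.

    Median/IQR-published variables use log-median and IQR-derived log-SD;
    moment-matched lognormal variables (C-peptide) convert mean +- SD to the
    exact lognormal parameters; everything else is plain normal.
    """
    if var in LOGNORMAL_VARIABLES:
        med, q1, q3 = moments
        return float(np.log(med)), float((np.log(q3) - np.log(q1)) / 1.349)
    mean, sd = moments
    if var in MOMENT_LOGNORMAL_VARIABLES:
        mu = np.log(mean ** 2 / np.sqrt(mean ** 2 + sd ** 2))
        sig = np.sqrt(np.log(1.0 + sd ** 2 / mean ** 2))
        return float(mu), float(sig)
    return float(mean), float(sd)


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic cohort: moments, mixing, blend, missingness,
    drift and hazards.  ``default()`` returns the shipped study conditions."""

    variables: tuple[str, ...] = CONTINUOUS_VARIABLES
    loc: dict[str, dict[str, float]] = field(default_factory=dict)    # subtype -> var -> loc
    scale: dict[str, dict[str, float]] = field(default_factory=dict)  # subtype -> var -> scale
    correlation: pd.DataFrame = field(default_factory=default_correlation)
    weights: dict[str, float] = field(
        default_factory=lambda: {k: v / sum(_CLUSTER_COUNTS.values())
                                 for k, v in _CLUSTER_COUNTS.items()})
    female_share: dict[str, float] = field(default_factory=lambda: dict(_FEMALE_SHARE))
    binary_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    boundary_blend: float = 0.14
    #: adjacent cluster pairs (nearest neighbours by standardised centre
    #: distance of the published profiles); blends are drawn between these
    blend_pairs: tuple[tuple[str, str], ...] = (
        ("MOD", "MARD"), ("SIDD", "MOD"), ("SIDD", "MARD"), ("SIRD", "MOD"))
    missingness: dict[str, float] = field(default_factory=dict)
    insulin_block_fraction: float = 0.0
    #: share of within-cluster HOMA2 variance not explained by (fpg, C-peptide)
    homa2_noise_frac: float = 0.15
    drift: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DRIFT))
    hazards: dict[str, Hazard] = field(default_factory=lambda: dict(_DEFAULT_HAZARDS))
    censoring_rate: float = 0.0
    max_resample: int = 1000
    dictionary: DataDictionary = field(default_factory=default_dictionary)

    @classmethod
    def default(cls) -> "GeneratorSpec":
        loc = {s: {} for s in SUBTYPES}
        scale = {s: {} for s in SUBTYPES}
        for var, per_cluster in _CLUSTER_MOMENTS.items():
            for s, moments in zip(SUBTYPES, per_cluster):
                loc[s][var], scale[s][var] = _internal_loc_scale(var, moments)
        rates = {s: {} for s in SUBTYPES}
        for flag, per_cluster in _BINARY_RATES.items():
            for s, r in zip(SUBTYPES, per_cluster):
                rates[s][flag] = r
        return cls(loc=loc, scale=scale, binary_rates=rates)

    def validate(self) -> None:
        w = np.array([self.weights[s] for s in SUBTYPES], dtype=float)
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("mixing weights must be positive and sum to 1")
        if not (0.0 <= self.boundary_blend < 1.0):
            raise ValueError("boundary_blend must be in [0, 1)")
        for col, r in self.missingness.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"missingness rate for {col!r} outside [0, 1]")
        if not (0.0 <= self.insulin_block_fraction <= 1.0):
            raise ValueError("insulin_block_fraction outside [0, 1]")
        if not (0.0 <= self.homa2_noise_frac < 1.0):
            raise ValueError("homa2_noise_frac outside [0, 1)")
        drawn = [v for v in self.variables if v not in DERIVED_HOMA2]
        C = self.correlation.loc[drawn, drawn].to_numpy()
        if not np.allclose(C, C.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        for s in SUBTYPES:
            for var in self.variables:
                if var not in self.loc.get(s, {}) or var not in self.scale.get(s, {}):
                    raise ValueError(f"missing moments for {s}/{var}")
                if self.scale[s][var] <= 0:
                    raise ValueError(f"non-positive scale for {s}/{var}")
        for ev, hz in self.hazards.items():
            if hz.baseline_rate <= 0 or any(h <= 0 for h in hz.hazard_ratios.values()):
                raise ValueError(f"hazard rates for {ev!r} must be positive")

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        payload = dataclasses.asdict(self)
        payload.pop("dictionary")
        payload["correlation"] = {
            "index": list(self.correlation.index),
            "values": self.correlation.to_numpy().tolist(),
        }
        payload["hazards"] = {
            ev: {"baseline_rate": hz.baseline_rate,
                 "hazard_ratios": dict(hz.hazard_ratios)}
            for ev, hz in self.hazards.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(plain(payload), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorSpec":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        corr = payload.pop("correlation")
        payload["correlation"] = pd.DataFrame(
            corr["values"], index=corr["index"], columns=corr["index"])
        payload["hazards"] = {
            ev: Hazard(d["baseline_rate"], d["hazard_ratios"])
            for ev, d in payload.pop("hazards").items()}
        payload["variables"] = tuple(payload["variables"])
        payload["blend_pairs"] = tuple(tuple(p) for p in payload["blend_pairs"])
        payload["drift"] = {k: tuple(v) for k, v in payload["drift"].items()}
        return cls(**payload)


@dataclass
class LabelledCohort:
    """A generated cohort with its generator-truth labels and (optional) events."""

    cohort: CohortTable
    true_subtype: pd.Series          # indexed by id; values in SUBTYPES + BLENDED
    events: pd.DataFrame | None = None


def _component_params(spec: GeneratorSpec, component,
                      vars_: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """loc/scale vectors for a pure subtype or an equal-weight blend pair."""
    if isinstance(component, str):
        loc = np.array([spec.loc[component][v] for v in vars_])
        scale = np.array([spec.scale[component][v] for v in vars_])
    else:
        a, b = component
        loc = np.array([(spec.loc[a][v] + spec.loc[b][v]) / 2 for v in vars_])
        scale = np.array([(spec.scale[a][v] + spec.scale[b][v]) / 2 for v in vars_])
    return loc, scale


def _internal_bounds(spec: GeneratorSpec,
                     vars_: list[str]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for v in vars_:
        cs = spec.dictionary[v]
        l = cs.lo if cs.lo is not None else -np.inf
        h = cs.hi if cs.hi is not None else np.inf
        if v in LOGNORMAL_VARIABLES or v in MOMENT_LOGNORMAL_VARIABLES:
            l, h = np.log(max(l, 1e-12)), np.log(h)
        lo.append(l)
        hi.append(h)
    return np.array(lo), np.array(hi)


def _sample_truncated(rng: np.random.Generator, n: int, loc: np.ndarray,
                      scale: np.ndarray, L: np.ndarray, lo: np.ndarray,
                      hi: np.ndarray, max_resample: int,
                      age_cols: tuple[int, int] | None = None,
                      age_bounds: tuple[float, float] = (-np.inf, np.inf),
                      ) -> np.ndarray:
    """Correlated truncated-normal draws by rejection; error on cap breach.

    ``age_cols`` optionally names the (age-at-diagnosis, duration) columns so
    their sum — attained age — is truncated to ``age_bounds`` as well.
    """
    p = len(loc)
    out = np.empty((n, p))
    todo = np.arange(n)
    for _ in range(max_resample):
        z = rng.standard_normal((len(todo), p))
        x = loc + (z @ L.T) * scale
        ok = np.all((x >= lo) & (x <= hi), axis=1)
        if age_cols is not None:
            age = x[:, age_cols[0]] + x[:, age_cols[1]]
            ok &= (age >= age_bounds[0]) & (age <= age_bounds[1])
        out[todo[ok]] = x[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise RuntimeError(
        f"truncated sampling failed to converge for {todo.size} draws; "
        "check spec ranges against moments")


def generate_cohort(spec: GeneratorSpec, n: int, seed: int) -> LabelledCohort:
    """Draw a baseline cohort of ``n`` individuals; fully seed-reproducible."""
    spec.validate()
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    vars_ = list(spec.variables)
    drawn = [v for v in vars_ if v not in DERIVED_HOMA2]
    derived = [v for v in vars_ if v in DERIVED_HOMA2]
    dict_cols = ["id", "sex", "visit_time", "age"] + vars_ + list(BINARY_VARIABLES)
    if n == 0:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in dict_cols})
        df["id"] = df["id"].astype("string")
        df["sex"] = df["sex"].astype("string")
        empty = CohortTable(df, spec.dictionary, provenance="synthetic(empty)")
        return LabelledCohort(empty, pd.Series(dtype=object), None)

    # component assignment: pure subtype or blend pair
    blended = rng.random(n) < spec.boundary_blend
    w = np.array([spec.weights[s] for s in SUBTYPES])
    sub_idx = rng.choice(len(SUBTYPES), size=n, p=w / w.sum())
    pair_idx = rng.integers(0, len(spec.blend_pairs), size=n)
    labels = np.array([
        BLENDED if blended[i] else SUBTYPES[sub_idx[i]] for i in range(n)],
        dtype=object)
    components: list = [
        spec.blend_pairs[pair_idx[i]] if blended[i] else SUBTYPES[sub_idx[i]]
        for i in range(n)]

    # sex per component female share
    fshare = np.array([
        (spec.female_share[c] if isinstance(c, str)
         else (spec.female_share[c[0]] + spec.female_share[c[1]]) / 2)
        for c in components])
    sex = np.where(rng.random(n) < fshare, "female", "male")

    corr = spec.correlation.loc[drawn, drawn].to_numpy()
    # tiny jitter guards exact semidefiniteness
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(len(drawn)))
    lo, hi = _internal_bounds(spec, drawn)

    X = np.empty((n, len(drawn)))
    keys = sorted({c if isinstance(c, str) else "+".join(c) for c in components})
    comp_of = np.array([c if isinstance(c, str) else "+".join(c)
                        for c in components])
    age_spec = spec.dictionary["age"]
    age_cols = (drawn.index("age_at_diagnosis"), drawn.index("diabetes_duration")) \
        if {"age_at_diagnosis", "diabetes_duration"} <= set(drawn) else None
    for key in keys:
        mask = comp_of == key
        comp = key if "+" not in key else tuple(key.split("+"))
        cloc, cscale = _component_params(spec, comp, drawn)
        X[mask] = _sample_truncated(
            rng, int(mask.sum()), cloc, cscale, L, lo, hi, spec.max_resample,
            age_cols=age_cols,
            age_bounds=(age_spec.lo if age_spec.lo is not None else -np.inf,
                        age_spec.hi if age_spec.hi is not None else np.inf))

    data = {v: X[:, j] for j, v in enumerate(drawn)}
    for v in (LOGNORMAL_VARIABLES | MOMENT_LOGNORMAL_VARIABLES) & set(drawn):
        data[v] = np.exp(data[v])

    # HOMA2 indices: deterministic surface of (fpg, C-peptide), rescaled within
    # each mixture component to the component's published moments, plus an
    # independent noise share (homa2_noise_frac of the within variance)
    if derived:
        surf_b, surf_ir = approximation_surface(data["fpg"], data["cpeptide"])
        surfaces = {"homa2b": surf_b, "homa2ir": surf_ir}
        nu = float(np.sqrt(spec.homa2_noise_frac))
        for v in derived:
            data[v] = np.empty(n)
        for key in keys:
            mask = comp_of == key
            comp = key if "+" not in key else tuple(key.split("+"))
            vloc, vscale = _component_params(spec, comp, derived)
            for j, v in enumerate(derived):
                f = surfaces[v][mask]
                z = (f - f.mean()) / f.std() if mask.sum() > 1 and f.std() > 0 \
                    else np.zeros(int(mask.sum()))
                eps = rng.standard_normal(int(mask.sum()))
                vals = vloc[j] + vscale[j] * (np.sqrt(1 - nu ** 2) * z + nu * eps)
                cs = spec.dictionary[v]
                data[v][mask] = np.clip(
                    vals, cs.lo if cs.lo is not None else -np.inf,
                    cs.hi if cs.hi is not None else np.inf)

    df = pd.DataFrame({v: data[v] for v in vars_})
    df.insert(0, "id", pd.array([f"P{i:06d}" for i in range(n)], dtype="string"))
    df.insert(1, "sex", pd.array(sex, dtype="string"))
    df.insert(2, "visit_time", 0.0)
    df.insert(3, "age", df["age_at_diagnosis"] + df["diabetes_duration"])

    for flag in BINARY_VARIABLES:
        rates = np.array([
            (spec.binary_rates[c][flag] if isinstance(c, str)
             else (spec.binary_rates[c[0]][flag] + spec.binary_rates[c[1]][flag]) / 2)
            for c in components])
        df[flag] = pd.array(rng.random(n) < rates, dtype="boolean")

    cohort = CohortTable(df, spec.dictionary, provenance=f"synthetic(seed={seed})")
    truth = pd.Series(labels, index=df["id"].to_numpy(), name="true_subtype")
    return LabelledCohort(cohort, truth, None)


def generate_followup(base: LabelledCohort, years: float,
                      spec: GeneratorSpec, seed: int) -> CohortTable:
    """One follow-up visit at ``visit_time = years`` with within-person drift.

    The five-year change of a drifting variable is N(shift, 2*sigma^2):
    visit-level noise enters at both baseline and follow-up.  Values are
    clipped to the dictionary range; age and diabetes duration advance by
    ``years``; sex and age at diagnosis are fixed.
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    if len(base.cohort) == 0:
        raise ValueError("base cohort is empty")
    rng = np.random.default_rng(seed)
    df = base.cohort.baseline().copy()
    df["visit_time"] = float(years)
    df["age"] = df["age"] + years
    df["diabetes_duration"] = df["diabetes_duration"] + years
    for var in sorted(spec.drift):
        if var not in df.columns:
            continue
        shift, sigma = spec.drift[var]
        change = shift + rng.normal(0.0, 1.0, size=len(df)) * sigma * np.sqrt(2.0)
        vals = df[var].to_numpy(dtype=float) + change
        cs = spec.dictionary[var]
        df[var] = np.clip(vals,
                          cs.lo if cs.lo is not None else -np.inf,
                          cs.hi if cs.hi is not None else np.inf)
    return CohortTable(df, spec.dictionary,
                       provenance=base.cohort.provenance + f"+followup({years}y)")


def inject_missingness(cohort: CohortTable, spec: GeneratorSpec,
                       seed: int) -> CohortTable:
    """Mask cells missing-at-random per column rate; optionally mask the
    insulin block (C-peptide, HOMA2-B, HOMA2-IR) jointly for a fraction of ids."""
    spec.validate()
    rng = np.random.default_rng(seed)
    df = cohort.df.copy()
    for col in sorted(spec.missingness):
        rate = spec.missingness[col]
        if col not in df.columns or rate == 0:
            continue
        if col in ("id", "sex", "visit_time"):
            raise ValueError(f"cannot mask structural column {col!r}")
        mask = rng.random(len(df)) < rate
        df.loc[mask, col] = pd.NA if df[col].dtype == "boolean" else np.nan
    if spec.insulin_block_fraction > 0:
        ids = df["id"].unique()
        chosen = ids[rng.random(len(ids)) < spec.insulin_block_fraction] \
            if spec.insulin_block_fraction < 1.0 else ids
        rows = df["id"].isin(chosen)
        for col in ("cpeptide", "homa2b", "homa2ir"):
            if col in df.columns:
                df.loc[rows, col] = np.nan
    return CohortTable(df, cohort.dictionary, cohort.provenance + "+missingness")


def generate_events(base: LabelledCohort, spec: GeneratorSpec, horizon: float,
                    seed: int) -> pd.DataFrame:
    """Exponential proportional-hazards event times per subtype, censored at
    ``horizon`` (plus optional independent exponential censoring)."""
    spec.validate()
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    rng = np.random.default_rng(seed)
    ids = base.cohort.baseline()["id"].to_numpy()
    labels = base.true_subtype.loc[ids].to_numpy()
    rows = []
    for ev in sorted(spec.hazards):
        hz = spec.hazards[ev]
        rates = np.array([hz.rate_for(lab) for lab in labels])
        t_event = rng.exponential(1.0 / rates)
        t_cens = np.full(len(ids), float(horizon))
        if spec.censoring_rate > 0:
            t_cens = np.minimum(
                t_cens, rng.exponential(1.0 / spec.censoring_rate, size=len(ids)))
        occurred = t_event <= t_cens
        time = np.where(occurred, t_event, t_cens)
        for pid, t, occ in zip(ids, time, occurred):
            rows.append({"id": pid, "event_type": ev, "time": float(t),
                         "status": "occurred" if occ else "censored"})
    return pd.DataFrame(rows, columns=["id", "event_type", "time", "status"])
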