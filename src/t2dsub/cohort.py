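"""Cohort data model, CSV IO, unit conversions and clinical definitions.

The package works on longitudinal tabular cohorts: one row per individual per
visit, identified by ``(id, visit_time)`` with ``visit_time`` in years since
baseline.  A :class:`DataDictionary` carries the unit and plausible range of
every column so that range violations are *reported*, never silently altered,
and so downstream stages can truncate synthetic draws to physiological ranges.

Clinical definitions implemented here:

* type 2 diabetes eligibility (fasting glucose >= 7.0 mmol/l, random glucose
  >= 11.1 mmol/l, HbA1c >= 48 mmol/mol, or glucose-lowering drug use; a
  positive islet autoantibody overrides to type 1),
* the IFCC -> NGSP HbA1c master equation,
* the Japanese serum-creatinine eGFR equation,
* event derivation for retinopathy, CKD (eGFR < 60 sustained > 90 days) and
  proteinuria (albuminuria >= 30 mg/g creatinine).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Canonical subtype order, used for deterministic tie-breaking everywhere.
SUBTYPES: tuple[str, ...] = ("SIDD", "SIRD", "MOD", "MARD")
UNDECIDABLE = "UNDECIDABLE"
#: Generator-truth label for individuals drawn between two cluster centres.
BLENDED = "BLENDED"

#: The five Ahlqvist clustering variables, in canonical order.
AHLQVIST_VARIABLES: tuple[str, ...] = (
    "age_at_diagnosis", "bmi", "hba1c_ifcc", "homa2b", "homa2ir",
)

INSULIN_VARIABLES: tuple[str, ...] = ("cpeptide", "homa2b", "homa2ir")

DRUG_FLAGS: tuple[str, ...] = (
    "sulfonylurea", "metformin", "dpp4i", "sglt2i", "glp1ra", "insulin",
)

EVENT_TYPES: tuple[str, ...] = (
    "retinopathy", "ckd", "proteinuria", "coronary_artery_disease",
)

RETINOPATHY_GRADES: tuple[str, ...] = ("none", "non_proliferative", "proliferative")


@dataclass(frozen=True)
class ColumnSpec:
    """Unit and plausible-range contract for one cohort column."""

    name: str
    unit: str = ""
    kind: str = "float"          # float | bool | str | category
    lo: float | None = None
    hi: float | None = None
    categories: tuple[str, ...] | None = None


class DataDictionary:
    """Mapping of column name -> :class:`ColumnSpec`, serialisable to YAML."""

    def __init__(self, specs: list[ColumnSpec]):
        self.specs: dict[str, ColumnSpec] = {s.name: s for s in specs}

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def __getitem__(self, name: str) -> ColumnSpec:
        return self.specs[name]

    def columns(self) -> list[str]:
        return list(self.specs)

    def to_yaml(self, path) -> None:
        payload = {
            s.name: {
                "unit": s.unit, "kind": s.kind, "lo": s.lo, "hi": s.hi,
                **({"categories": list(s.categories)} if s.categories else {}),
            }
            for s in self.specs.values()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DataDictionary":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        specs = [
            ColumnSpec(
                name=name, unit=d.get("unit", ""), kind=d.get("kind", "float"),
                lo=d.get("lo"), hi=d.get("hi"),
                categories=tuple(d["categories"]) if d.get("categories") else None,
            )
            for name, d in payload.items()
        ]
        return cls(specs)


def default_dictionary() -> DataDictionary:
    """Shipped column dictionary covering the full clinical variable inventory.

    Ranges are physiological-plausibility bounds (used for range reporting and
    for truncating synthetic draws), not diagnostic thresholds.
    """
    f = ColumnSpec
    return DataDictionary([
        f("id", kind="str"),
        f("sex", kind="category", categories=("female", "male")),
        f("visit_time", "years", lo=0.0, hi=60.0),
        f("age", "years", lo=18.0, hi=100.0),
        f("age_at_diagnosis", "years", lo=15.0, hi=95.0),
        f("diabetes_duration", "years", lo=0.0, hi=70.0),
        f("bmi", "kg/m^2", lo=13.0, hi=60.0),
        f("waist", "cm", lo=50.0, hi=170.0),
        f("sbp", "mmHg", lo=70.0, hi=240.0),
        f("dbp", "mmHg", lo=35.0, hi=140.0),
        f("fpg", "mmol/l", lo=3.0, hi=30.0),
        f("random_glucose", "mmol/l", lo=2.0, hi=45.0),
        f("hba1c_ifcc", "mmol/mol", lo=20.0, hi=160.0),
        f("cpeptide", "nmol/l", lo=0.01, hi=8.0),
        f("homa2b", "%", lo=1.0, hi=500.0),
        f("homa2ir", "", lo=0.1, hi=15.0),
        f("tg", "mmol/l", lo=0.1, hi=20.0),
        f("hdl", "mmol/l", lo=0.3, hi=4.0),
        f("ldl", "mmol/l", lo=0.3, hi=10.0),
        f("ast", "U/l", lo=5.0, hi=500.0),
        f("alt", "U/l", lo=3.0, hi=500.0),
        f("ggt", "U/l", lo=3.0, hi=1000.0),
        f("egfr", "ml/min/1.73m^2", lo=2.0, hi=180.0),
        f("serum_creatinine", "mg/dl", lo=0.1, hi=15.0),
        f("uric_acid", "umol/l", lo=60.0, hi=900.0),
        f("wbc", "10^3/ul", lo=1.0, hi=30.0),
        f("hb", "g/l", lo=50.0, hi=220.0),
        f("platelets", "10^4/ul", lo=2.0, hi=100.0),
        f("albuminuria", "mg/gCr", lo=0.5, hi=10000.0),
        f("retinopathy_grade", kind="category", categories=RETINOPATHY_GRADES),
        f("smoker", kind="bool"),
        f("alcohol", kind="bool"),
        *(f(flag, kind="bool") for flag in DRUG_FLAGS),
        f("autoantibody_positive", kind="bool"),
    ])


@dataclass
class CohortTable:
    """A typed cohort: DataFrame plus data dictionary plus provenance tag.

    Missing cells are pandas ``NA``/``NaN``.  Rows are one individual-visit;
    ids must be unique within a ``visit_time``.
    """

    df: pd.DataFrame
    dictionary: DataDictionary = field(default_factory=default_dictionary)
    provenance: str = ""

    def __post_init__(self) -> None:
        unknown = [c for c in self.df.columns if c not in self.dictionary]
        if unknown:
            raise ValueError(f"columns not covered by the data dictionary: {unknown}")
        for col in ("id", "sex", "visit_time"):
            if col not in self.df.columns:
                raise ValueError(f"required column missing: {col!r}")
            if self.df[col].isna().any():
                raise ValueError(f"column {col!r} may not contain missing values")
        dup = self.df.duplicated(subset=["id", "visit_time"])
        if dup.any():
            raise ValueError("duplicate (id, visit_time) rows present")

    def __len__(self) -> int:
        return len(self.df)

    def baseline(self) -> pd.DataFrame:
        return self.df[self.df["visit_time"] == 0.0].reset_index(drop=True)

    def at_time(self, t: float) -> pd.DataFrame:
        return self.df[np.isclose(self.df["visit_time"], t)].reset_index(drop=True)

    def range_violations(self) -> pd.DataFrame:
        """Report out-of-range cells (never altered): id, visit, column, value, bound."""
        rows = []
        for col in self.df.columns:
            spec = self.dictionary[col]
            if spec.kind != "float":
                continue
            vals = pd.to_numeric(self.df[col], errors="coerce")
            for bound, op in ((spec.lo, "lo"), (spec.hi, "hi")):
                if bound is None:
                    continue
                bad = vals < bound if op == "lo" else vals > bound
                for i in self.df.index[bad.fillna(False)]:
                    rows.append({
                        "id": self.df.at[i, "id"],
                        "visit_time": self.df.at[i, "visit_time"],
                        "column": col, "value": vals[i],
                        "bound": bound, "violation": op,
                    })
        return pd.DataFrame(rows, columns=[
            "id", "visit_time", "column", "value", "bound", "violation"])

    def to_csv(self, path) -> None:
        """UTF-8 comma-separated; missing cells written as empty strings."""
        out = self.df.copy()
        for col in out.columns:
            if self.dictionary[col].kind == "bool":
                out[col] = out[col].map(
                    lambda v: "" if pd.isna(v) else ("true" if v else "false"))
        out.to_csv(path, index=False, na_rep="")


def _coerce_column(raw: pd.Series, spec: ColumnSpec) -> pd.Series:
    if spec.kind == "float":
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            logger.warning(
                "column %r: %d unparseable cells recorded as missing",
                spec.name, int(bad.sum()))
        return vals.astype(float)
    if spec.kind == "bool":
        mapping = {"true": True, "false": False, "1": True, "0": False,
                   "yes": True, "no": False}
        def parse(v):
            if pd.isna(v) or str(v).strip() == "":
                return pd.NA
            out = mapping.get(str(v).strip().lower())
            if out is None:
                logger.warning("column %r: unparseable boolean %r -> missing",
                               spec.name, v)
                return pd.NA
            return out
        return raw.map(parse).astype("boolean")
    # str / category: empty string means missing
    out = raw.astype("string")
    out = out.mask(out.str.strip() == "")
    if spec.categories is not None:
        bad = out.notna() & ~out.isin(spec.categories)
        if bad.any():
            logger.warning("column %r: %d values outside categories -> missing",
                           spec.name, int(bad.sum()))
            out = out.mask(bad)
    return out


def read_cohort(path, dictionary: DataDictionary | None = None,
                provenance: str = "") -> CohortTable:
    """Read a cohort CSV against a data dictionary.

    Unknown columns are a hard error; unparseable cells become missing with a
    logged warning; out-of-range values load untouched (see
    :meth:`CohortTable.range_violations`).
    """
    dictionary = dictionary or default_dictionary()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    unknown = [c for c in raw.columns if c not in dictionary]
    if unknown:
        raise ValueError(f"unknown columns in {path}: {unknown}")
    cols = {c: _coerce_column(raw[c], dictionary[c]) for c in raw.columns}
    return CohortTable(pd.DataFrame(cols), dictionary, provenance or str(path))


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.to_csv(path)


# ---------------------------------------------------------------------------
# Clinical definitions
# ---------------------------------------------------------------------------

FPG_THRESHOLD = 7.0          # mmol/l
RANDOM_GLUCOSE_THRESHOLD = 11.1  # mmol/l
HBA1C_THRESHOLD = 48.0       # mmol/mol (6.5%)


def is_type2_diabetes(record) -> tuple[bool | None, str]:
    """Type 2 diabetes eligibility for one record (mapping or pandas row).

    Returns ``(status, reason)``.  ``status`` is ``True``/``False`` or ``None``
    when all four criteria fields are missing (reason ``"undeterminable"``).
    A positive islet autoantibody is indicative of type 1 and overrides any
    glycaemic criterion.
    """
    def get(k):
        try:
            v = record[k]
        except (KeyError, IndexError):
            return None
        return None if pd.isna(v) else v

    if get("autoantibody_positive") is True:
        return False, "type1_autoantibody"

    fpg = get("fpg")
    rg = get("random_glucose")
    a1c = get("hba1c_ifcc")
    drugs = [get(fl) for fl in DRUG_FLAGS]
    any_drug_known = any(d is not None for d in drugs)
    if fpg is None and rg is None and a1c is None and not any_drug_known:
        return None, "undeterminable"
    if fpg is not None and fpg >= FPG_THRESHOLD:
        return True, "fpg"
    if rg is not None and rg >= RANDOM_GLUCOSE_THRESHOLD:
        return True, "random_glucose"
    if a1c is not None and a1c >= HBA1C_THRESHOLD:
        return True, "hba1c"
    if any(d is True for d in drugs):
        return True, "glucose_lowering_drug"
    return False, "below_thresholds"


def exclusion_flow(enrolled: int, exclusions: dict[str, int]) -> pd.DataFrame:
    """Bookkeeping of a study flow: enrolled total minus named exclusion counts.

    Returns one row per stage with the remaining count after each exclusion;
    the last row's ``remaining`` is the eligible sample size.
    """
    if enrolled < 0 or any(v < 0 for v in exclusions.values()):
        raise ValueError("counts must be non-negative")
    rows = [{"stage": "enrolled", "excluded": 0, "remaining": enrolled}]
    remaining = enrolled
    for stage, n in exclusions.items():
        remaining -= n
        rows.append({"stage": stage, "excluded": n, "remaining": remaining})
    if remaining < 0:
        raise ValueError("exclusions exceed enrolment")
    return pd.DataFrame(rows)


def hba1c_ifcc_to_ngsp(value):
    """IFCC mmol/mol -> NGSP % by the standard master equation.

    percent = 0.09148 * value + 2.152; rounding is left to display code.
    """
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("HbA1c (IFCC) must be non-negative")
    out = 0.09148 * value + 2.152
    return float(out) if out.ndim == 0 else out


def egfr_japanese(creatinine, age, sex):
    """eGFR (ml/min per 1.73 m^2) from the Japanese coefficient equation.

    194 * Cr^-1.094 * age^-0.287, times 0.739 for women.  ``sex`` is
    ``"female"``/``"male"`` (scalar or array-like).
    """
    creatinine = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(creatinine <= 0) or np.any(age <= 0):
        raise ValueError("creatinine and age must be strictly positive")
    sex_arr = np.asarray(sex)
    factor = np.where(sex_arr == "female", 0.739, 1.0)
    out = 194.0 * creatinine ** -1.094 * age ** -0.287 * factor
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Event derivation
# ---------------------------------------------------------------------------

CKD_EGFR_THRESHOLD = 60.0     # ml/min per 1.73 m^2
CKD_PERSISTENCE_DAYS = 90.0   # strictly greater than
PROTEINURIA_THRESHOLD = 30.0  # mg/g creatinine
_DAYS_PER_YEAR = 365.25


def _first_event_time(times: np.ndarray, flags: np.ndarray) -> float | None:
    idx = np.nonzero(flags)[0]
    return float(times[idx[0]]) if idx.size else None


def _ckd_event_time(times: np.ndarray, egfr: np.ndarray) -> float | None:
    """First visit of a low-eGFR run sustained > 90 days with no recovery between."""
    ok = ~np.isnan(egfr)
    times, egfr = times[ok], egfr[ok]
    low = egfr < CKD_EGFR_THRESHOLD
    i = 0
    n = len(times)
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            if (times[j] - times[i]) * _DAYS_PER_YEAR > CKD_PERSISTENCE_DAYS:
                return float(times[i])
            i = j + 1
        else:
            i += 1
    return None


def derive_events(cohort: CohortTable) -> pd.DataFrame:
    """Derive retinopathy / CKD / proteinuria events from longitudinal visits.

    One row per (id, event_type): ``status`` is ``"occurred"`` (with the event
    time) or ``"censored"`` at the last visit.  Individuals with a single
    visit get CKD status ``"censored"`` and ``flag="ckd_undetermined"``
    (persistence cannot be checked).  Order-independent w.r.t. row shuffling.
    """
    df = cohort.df.sort_values(["id", "visit_time"], kind="mergesort")
    rows = []
    for pid, g in df.groupby("id", sort=True):
        times = g["visit_time"].to_numpy(dtype=float)
        last = float(times[-1])

        # retinopathy: graded severity non-proliferative or proliferative
        if "retinopathy_grade" in g.columns:
            grade = g["retinopathy_grade"].astype("string")
            flags = grade.isin(["non_proliferative", "proliferative"]).to_numpy()
            t = _first_event_time(times, flags)
            rows.append({"id": pid, "event_type": "retinopathy",
                         "time": t if t is not None else last,
                         "status": "occurred" if t is not None else "censored",
                         "flag": ""})

        if "egfr" in g.columns:
            egfr = pd.to_numeric(g["egfr"]).to_numpy(dtype=float)
            if len(times) < 2:
                rows.append({"id": pid, "event_type": "ckd", "time": last,
                             "status": "censored", "flag": "ckd_undetermined"})
            else:
                t = _ckd_event_time(times, egfr)
                rows.append({"id": pid, "event_type": "ckd",
                             "time": t if t is not None else last,
                             "status": "occurred" if t is not None else "censored",
                             "flag": ""})

        if "albuminuria" in g.columns:
            alb = pd.to_numeric(g["albuminuria"]).to_numpy(dtype=float)
            flags = np.nan_to_num(alb, nan=-np.inf) >= PROTEINURIA_THRESHOLD
            t = _first_event_time(times, flags)
            rows.append({"id": pid, "event_type": "proteinuria",
                         "time": t if t is not None else last,
                         "status": "occurred" if t is not None else "censored",
                         "flag": ""})
    return pd.DataFrame(rows, columns=["id", "event_type", "time", "status", "flag"])


def read_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path, dtype={"id": str})
    required = {"id", "event_type", "time", "status"}
    missing = required - set(ev.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    bad = set(ev["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    return ev


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)
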