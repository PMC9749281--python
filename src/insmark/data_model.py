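"""Cohort data model: canonical units, CSV ingestion and validation.

A cohort is a patient-level table with demographics, fasting blood labs,
tumor/treatment covariates and a right-censored overall-survival outcome.
All downstream index formulas consume one canonical unit per field (see
:data:`CANONICAL_UNITS`); ``read_cohort`` converts from whatever units the
source file declares in its schema config, so unit handling lives in exactly
one layer.

Canonical units
---------------
* cell counts (WBC, neutrophils, lymphocytes, platelets): 1e9/L
* red blood cells: 1e12/L
* hemoglobin, albumin, total protein: g/L
* CRP: mg/L
* glucose, cholesterol: mmol/L
* height cm, weight kg, survival time months
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PatientRecord",
    "Cohort",
    "ValidationReport",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "load_schema_config",
]


class SchemaError(ValueError):
    """A required column is absent or the schema config is malformed."""


class CohortValidationError(ValueError):
    """Row-level validation failed; ``.issues`` lists (row, reason) pairs."""

    def __init__(self, issues: Sequence[tuple[int, str]]):
        self.issues = list(issues)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.issues[:20])
        more = "" if len(self.issues) <= 20 else f" (+{len(self.issues) - 20} more)"
        super().__init__(f"cohort validation failed: {lines}{more}")


#: canonical field -> unit string (documentation + schema validation)
CANONICAL_UNITS: dict[str, str] = {
    "age": "years",
    "height": "cm",
    "weight": "kg",
    "wbc": "1e9/L",
    "neutrophils": "1e9/L",
    "lymphocytes": "1e9/L",
    "platelets": "1e9/L",
    "rbc": "1e12/L",
    "hemoglobin": "g/L",
    "albumin": "g/L",
    "total_protein": "g/L",
    "cholesterol": "mmol/L",
    "crp": "mg/L",
    "glucose": "mmol/L",
    "os_time": "months",
}

#: per-field accepted source units -> multiplicative factor to canonical
UNIT_FACTORS: dict[str, dict[str, float]] = {
    "height": {"cm": 1.0, "m": 100.0},
    "weight": {"kg": 1.0, "lb": 0.45359237},
    "wbc": {"1e9/L": 1.0, "per_uL": 1e-3},
    "neutrophils": {"1e9/L": 1.0, "per_uL": 1e-3},
    "lymphocytes": {"1e9/L": 1.0, "per_uL": 1e-3},
    "platelets": {"1e9/L": 1.0, "per_uL": 1e-3},
    "rbc": {"1e12/L": 1.0, "per_uL": 1e-6},
    "hemoglobin": {"g/L": 1.0, "g/dL": 10.0},
    "albumin": {"g/L": 1.0, "g/dL": 10.0},
    "total_protein": {"g/L": 1.0, "g/dL": 10.0},
    "cholesterol": {"mmol/L": 1.0, "mg/dL": 1.0 / 38.67},
    "crp": {"mg/L": 1.0, "mg/dL": 10.0},
    "glucose": {"mmol/L": 1.0, "mg/dL": 1.0 / 18.0182},
    "os_time": {"months": 1.0, "days": 1.0 / 30.4375, "years": 12.0},
    "age": {"years": 1.0},
}

LAB_FIELDS = (
    "wbc", "neutrophils", "lymphocytes", "platelets", "rbc",
    "hemoglobin", "albumin", "crp", "glucose",
)
OPTIONAL_LAB_FIELDS = ("total_protein", "cholesterol")
BOOL_FIELDS = (
    "surgery", "radiotherapy", "chemotherapy", "hypertension",
    "diabetes", "smoking", "drinking", "family_history",
)
REQUIRED_FIELDS = (
    ("patient_id", "sex", "age", "height", "weight")
    + LAB_FIELDS
    + ("tnm_stage", "tumor_type")
    + BOOL_FIELDS
    + ("os_time", "event")
)
OPTIONAL_FIELDS = OPTIONAL_LAB_FIELDS

TNM_STAGES = ("I", "II", "III", "IV")

#: the four labs every INS component formula draws on (plus anthropometry)
INS_REQUIRED_LABS = ("lymphocytes", "crp", "albumin", "neutrophils")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics, canonical-unit labs and outcome."""

    patient_id: str
    sex: str
    age: float
    height: float
    weight: float
    wbc: float
    neutrophils: float
    lymphocytes: float
    platelets: float
    rbc: float
    hemoglobin: float
    albumin: float
    crp: float
    glucose: float
    tnm_stage: str
    tumor_type: str
    surgery: bool
    radiotherapy: bool
    chemotherapy: bool
    hypertension: bool
    diabetes: bool
    smoking: bool
    drinking: bool
    family_history: bool
    os_time: float
    event: int
    total_protein: float = float("nan")
    cholesterol: float = float("nan")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


@dataclass
class Cohort:
    """An ordered collection of patients backed by a pandas DataFrame.

    ``data`` holds one row per patient in canonical units, with a derived
    ``bmi`` column. ``provenance`` records the source path or simulation seed.
    """

    data: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("cohort must be non-empty")
        if self.data["patient_id"].duplicated().any():
            dup = self.data.loc[self.data["patient_id"].duplicated(), "patient_id"]
            raise ValueError(f"duplicate patient_id values: {sorted(set(dup))[:5]}")
        if "bmi" not in self.data.columns:
            self.data = self.data.assign(
                bmi=self.data["weight"] / (self.data["height"] / 100.0) ** 2
            )
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[PatientRecord]:
        cols = [f.name for f in PatientRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
        for _, row in self.data.iterrows():
            kwargs = {}
            for c in cols:
                v = row.get(c, np.nan)
                kwargs[c] = v
            kwargs["event"] = int(row["event"])
            yield PatientRecord(**kwargs)

    def record(self, i: int) -> PatientRecord:
        return next(iter(Cohort(self.data.iloc[[i]], self.provenance)))


def load_schema_config(source: str | Path | Mapping) -> dict:
    """Load a schema config mapping user column names/units to canonical fields.

    The config is a mapping with two keys: ``columns`` (canonical field ->
    source column name; identity for omitted fields) and ``units`` (canonical
    field -> source unit from the enumerated list in :data:`UNIT_FACTORS`).
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("columns", {})
    cfg.setdefault("units", {})
    for fld, unit in cfg["units"].items():
        allowed = UNIT_FACTORS.get(fld)
        if allowed is None:
            raise SchemaError(f"units declared for unknown field {fld!r}")
        if unit not in allowed:
            raise SchemaError(
                f"unit {unit!r} not recognized for {fld!r}; allowed: {sorted(allowed)}"
            )
    return cfg


_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _coerce_bool(series: pd.Series, name: str, issues: list[tuple[int, str]]) -> pd.Series:
    out = pd.Series(index=series.index, dtype="float")
    for i, v in series.items():
        s = str(v).strip().lower()
        if s in _TRUTHY:
            out[i] = 1.0
        elif s in _FALSY or s in {"nan", "none"}:
            out[i] = 0.0
        else:
            issues.append((int(i), f"{name}: {v!r} is not a recognized boolean"))
    return out.astype(bool)


def read_cohort(
    path: str | Path | io.IOBase,
    schema_config: str | Path | Mapping | None = None,
) -> Cohort:
    """Read and validate a cohort CSV/TSV, converting to canonical units.

    Rows failing validation are reported with row number and reason via
    :class:`CohortValidationError`. Records with missing CRP are retained but
    will be flagged ineligible for INS scoring by :func:`validate_cohort`
    (the score requires CRP).
    """
    cfg = load_schema_config(schema_config or {})
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if len(raw) == 0:
        raise SchemaError("empty cohort file")
    raw.columns = [c.strip() for c in raw.columns]

    colmap = {fld: cfg["columns"].get(fld, fld) for fld in REQUIRED_FIELDS + OPTIONAL_FIELDS}
    missing = [src for fld, src in colmap.items()
               if fld in REQUIRED_FIELDS and src not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    df = pd.DataFrame(index=raw.index)
    issues: list[tuple[int, str]] = []

    df["patient_id"] = raw[colmap["patient_id"]].astype(str)
    sex = raw[colmap["sex"]].astype(str).str.strip().str.lower()
    bad_sex = ~sex.isin(["male", "female", "m", "f"])
    for i in raw.index[bad_sex]:
        issues.append((int(i), f"sex: {raw.loc[i, colmap['sex']]!r} not in {{male, female}}"))
    df["sex"] = sex.map({"m": "male", "f": "female"}).fillna(sex)

    numeric_fields = ("age", "height", "weight") + LAB_FIELDS + ("os_time",)
    for fld in numeric_fields + OPTIONAL_LAB_FIELDS:
        src = colmap[fld]
        if src not in raw.columns:
            df[fld] = np.nan
            continue
        vals = pd.to_numeric(raw[src].replace("", np.nan), errors="coerce")
        bad = vals.isna() & raw[src].notna() & (raw[src].astype(str).str.strip() != "")
        for i in raw.index[bad]:
            issues.append((int(i), f"{fld}: non-numeric value {raw.loc[i, src]!r}"))
        if cfg["units"].get(fld) is not None:
            vals = vals * UNIT_FACTORS[fld][cfg["units"][fld]]
        df[fld] = vals

    # labs must be strictly positive when present
    for fld in ("age", "height", "weight") + LAB_FIELDS + OPTIONAL_LAB_FIELDS:
        bad = df[fld].notna() & (df[fld] <= 0)
        for i in df.index[bad]:
            issues.append((int(i), f"{fld}: non-positive value {df.loc[i, fld]}"))

    stage = raw[colmap["tnm_stage"]].astype(str).str.strip().str.upper()
    bad_stage = ~stage.isin(TNM_STAGES)
    for i in raw.index[bad_stage]:
        issues.append((int(i), f"tnm_stage: {stage[i]!r} not in {TNM_STAGES}"))
    df["tnm_stage"] = stage
    df["tumor_type"] = raw[colmap["tumor_type"]].astype(str).str.strip()

    for fld in BOOL_FIELDS:
        df[fld] = _coerce_bool(raw[colmap[fld]], fld, issues)

    ev = pd.to_numeric(raw[colmap["event"]], errors="coerce")
    bad_ev = ~ev.isin([0, 1])
    for i in raw.index[bad_ev]:
        issues.append((int(i), f"event: {raw.loc[i, colmap['event']]!r} not in allowed codes {{0, 1}}"))
    df["event"] = ev.fillna(-1).astype(int)

    if issues:
        raise CohortValidationError(issues)

    return Cohort(df, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV in canonical units (inverse of read_cohort)."""
    out = cohort.data.drop(columns=["bmi"], errors="ignore")
    out.to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Deterministic eligibility and missingness summary; never mutates."""

    n: int
    eligible: int
    ineligible: int
    missingness: dict[str, int] = field(default_factory=dict)
    outcome_violations: list[dict] = field(default_factory=list)
    ineligible_reasons: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"cohort size          : {self.n}",
            f"eligible for scoring : {self.eligible}",
            f"ineligible           : {self.ineligible}",
            "per-field missingness:",
        ]
        for fld, cnt in sorted(self.missingness.items()):
            if cnt:
                lines.append(f"  {fld}: {cnt}")
        if self.outcome_violations:
            lines.append("outcome violations:")
            for v in self.outcome_violations:
                lines.append(f"  row {v['row']}: {v['reason']}")
        return "\n".join(lines)


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Report eligibility for INS scoring and per-field missingness.

    A patient is eligible when all four INS component indices are computable
    (lymphocytes, CRP, albumin, neutrophils, height, weight present) and the
    survival outcome is usable (os_time >= 0, event in {0, 1}). Patients with
    missing CRP are the canonical ineligible case: the score cannot be
    computed without the inflammation axis.
    """
    df = cohort.data
    missingness = {
        fld: int(df[fld].isna().sum())
        for fld in ("age", "height", "weight") + LAB_FIELDS + OPTIONAL_LAB_FIELDS
    }
    outcome_violations = []
    bad_time = df["os_time"].isna() | (df["os_time"] < 0)
    for i in df.index[bad_time]:
        outcome_violations.append(
            {"row": int(i), "reason": f"os_time invalid: {df.loc[i, 'os_time']}"}
        )
    bad_event = ~df["event"].isin([0, 1])
    for i in df.index[bad_event]:
        outcome_violations.append(
            {"row": int(i), "reason": f"event code invalid: {df.loc[i, 'event']}"}
        )

    reasons: dict[str, list[str]] = {}
    needed = list(INS_REQUIRED_LABS) + ["height", "weight"]
    for i in df.index:
        why = [f"missing {fld}" for fld in needed if pd.isna(df.loc[i, fld])]
        if bad_time[i] or bad_event[i]:
            why.append("invalid outcome")
        if why:
            reasons[str(df.loc[i, "patient_id"])] = why
    eligible = len(df) - len(reasons)
    return ValidationReport(
        n=len(df),
        eligible=eligible,
        ineligible=len(reasons),
        missingness=missingness,
        outcome_violations=outcome_violations,
        ineligible_reasons=reasons,
    )
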