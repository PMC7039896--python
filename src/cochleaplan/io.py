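"""Readers/writers for the tabular study formats.

CSV dialect: comma-separated, UTF-8, header required, '.' decimal separator.
Column names carry units (A_mm, actual_deg); degrees and millimetres never
share a column.  Validation collects *all* violations before raising, and
reports them with 1-based file line numbers (header = line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .electrode import ElectrodeSpec

__all__ = [
    "SchemaError",
    "read_measurements",
    "validate_measurements",
    "read_observations",
    "validate_observations",
    "read_electrode_spec",
    "MEASUREMENT_COLUMNS",
    "OBSERVATION_COLUMNS",
    "METHODS",
]

MEASUREMENT_COLUMNS = ("subject_id", "ear", "observer", "observation", "method",
                       "A_mm", "B_mm")
OBSERVATION_COLUMNS = ("subject_id", "observer", "observation", "reference",
                       "actual_deg")
METHODS = ("software-3d", "2d-oblique")


class SchemaError(ValueError):
    """Input table violates the schema; message lists every violation."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "schema validation failed:\n  " + "\n  ".join(self.violations)
        )


def _line(idx: int) -> int:
    # pandas index -> 1-based CSV line (header occupies line 1)
    return int(idx) + 2


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a measurement table; returns a typed copy or raises SchemaError."""
    violations: list[str] = []
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing columns: {missing}"])
    df = df.copy()
    for col in ("A_mm", "B_mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            violations.append(f"line {_line(i)}: non-numeric {col}={df.loc[i, col]!r}")
        df[col] = coerced
    for col in ("observer", "observation"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~coerced.isin([1, 2])]
        for i in bad:
            violations.append(
                f"line {_line(i)}: {col} must be 1 or 2, got {df.loc[i, col]!r}"
            )
        df[col] = coerced.astype("Int64")
    bad = df.index[~df["method"].isin(METHODS)]
    for i in bad:
        violations.append(
            f"line {_line(i)}: unknown method {df.loc[i, 'method']!r}; "
            f"expected one of {METHODS}"
        )
    bad = df.index[df["A_mm"].notna() & (df["A_mm"] <= 0)]
    for i in bad:
        violations.append(f"line {_line(i)}: A_mm must be positive")
    bad = df.index[df["A_mm"].isna()]
    for i in bad:
        violations.append(f"line {_line(i)}: A_mm is required")
    bad = df.index[df["B_mm"].notna() & (df["B_mm"] <= 0)]
    for i in bad:
        violations.append(f"line {_line(i)}: B_mm must be positive")
    # B may be missing only for the 2D-oblique workflow (A-only measurement)
    bad = df.index[df["B_mm"].isna() & (df["method"] == "software-3d")]
    for i in bad:
        violations.append(
            f"line {_line(i)}: B_mm missing for method=software-3d "
            f"(subject {df.loc[i, 'subject_id']})"
        )
    key = ["subject_id", "observer", "observation", "method"]
    dup = df.index[df.duplicated(subset=key, keep="first")]
    for i in dup:
        violations.append(
            f"line {_line(i)}: duplicate key "
            f"{tuple(df.loc[i, key])}"
        )
    if violations:
        raise SchemaError(violations)
    return df


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a measurement CSV (units: mm)."""
    df = pd.read_csv(path)
    return validate_measurements(df)


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a postoperative observation table (angles in degrees)."""
    violations: list[str] = []
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing columns: {missing}"])
    df = df.copy()
    coerced = pd.to_numeric(df["actual_deg"], errors="coerce")
    bad = df.index[coerced.isna()]
    for i in bad:
        violations.append(
            f"line {_line(i)}: non-numeric actual_deg={df.loc[i, 'actual_deg']!r}"
        )
    df["actual_deg"] = coerced
    bad = df.index[(coerced <= 0) | (coerced > 900)]
    for i in bad:
        violations.append(
            f"line {_line(i)}: actual_deg must lie in (0, 900], got {coerced[i]}"
        )
    bad = df.index[~df["reference"].isin(["c1", "tip"])]
    for i in bad:
        violations.append(
            f"line {_line(i)}: reference must be 'c1' or 'tip', "
            f"got {df.loc[i, 'reference']!r}"
        )
    for col in ("observer", "observation"):
        c = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~c.isin([1, 2])]
        for i in bad:
            violations.append(
                f"line {_line(i)}: {col} must be 1 or 2, got {df.loc[i, col]!r}"
            )
        df[col] = c.astype("Int64")
    dup = df.index[df.duplicated(
        subset=["subject_id", "observer", "observation", "reference"], keep="first")]
    for i in dup:
        violations.append(f"line {_line(i)}: duplicate observation key")
    if violations:
        raise SchemaError(violations)
    return df


def read_observations(path) -> pd.DataFrame:
    """Read and validate a postoperative observation CSV."""
    return validate_observations(pd.read_csv(path))


def read_electrode_spec(path) -> ElectrodeSpec:
    """Load an electrode spec from a flat key=value text file.

    Expected keys: name, total_length_mm, c1_to_stopper_mm, tip_to_c1_mm.
    Blank lines and '#' comments are ignored.
    """
    kv: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError([f"electrode spec line not key=value: {raw!r}"])
        k, v = (s.strip() for s in line.split("=", 1))
        kv[k] = v
    required = {"name", "total_length_mm", "c1_to_stopper_mm", "tip_to_c1_mm"}
    missing = required - kv.keys()
    if missing:
        raise SchemaError([f"electrode spec missing keys: {sorted(missing)}"])
    try:
        return ElectrodeSpec(
            name=kv["name"],
            total_length=float(kv["total_length_mm"]),
            c1_to_stopper=float(kv["c1_to_stopper_mm"]),
            tip_to_c1=float(kv["tip_to_c1_mm"]),
        )
    except ValueError as exc:
        raise SchemaError([f"invalid electrode spec: {exc}"]) from exc
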