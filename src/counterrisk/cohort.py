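"""Cohort tables: column schemas, validation, and delimited-text round-tripping.

The package represents a cohort as two pandas DataFrames:

``baseline``
    one row per participant at their index risk assessment, carrying the
    mandatory CVD risk-factor profile plus the observed outcome
    (``event_time`` in months since baseline and ``event_type``).

``followups``
    zero or more re-measurement visits per participant (``visit_time`` in
    months since baseline) with the re-measured, potentially changed risk
    factors.

Binary indicators are stored as 0/1 integers; categorical fields are plain
strings with closed vocabularies (see ``SMOKING_LEVELS`` etc.).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

SEX_LEVELS = ("female", "male")
ETHNICITY_LEVELS = ("European", "Other")
SMOKING_LEVELS = ("never", "ex", "current")
EVENT_TYPES = ("cvd", "death_other", "admin_censor")

#: column -> (kind, constraint) for the baseline table
BASELINE_SCHEMA = {
    "id": ("int", None),
    "age": ("float", (30.0, 74.0)),
    "sex": ("cat", SEX_LEVELS),
    "ethnicity": ("cat", ETHNICITY_LEVELS),
    "nzdep": ("int", (1, 5)),
    "smoking": ("cat", SMOKING_LEVELS),
    "family_history": ("bin", None),
    "diabetes": ("bin", None),
    "af": ("bin", None),
    "sbp": ("float", (0.0, None)),
    "tchdl": ("float", (0.0, None)),
    "bplm": ("bin", None),
    "llm": ("bin", None),
    "atm": ("bin", None),
    "event_time": ("float", (0.0, None)),
    "event_type": ("cat", EVENT_TYPES),
}

FOLLOWUP_SCHEMA = {
    "id": ("int", None),
    "visit_time": ("float", (0.0, None)),
    "smoking": ("cat", SMOKING_LEVELS),
    "sbp": ("float", (0.0, None)),
    "tchdl": ("float", (0.0, None)),
    "bplm": ("bin", None),
    "llm": ("bin", None),
    "atm": ("bin", None),
}

BASELINE_COLUMNS = list(BASELINE_SCHEMA)
FOLLOWUP_COLUMNS = list(FOLLOWUP_SCHEMA)


class CohortValidationError(ValueError):
    """A cohort table violates the schema; the message names row and column."""


def _validate_table(df: pd.DataFrame, schema: dict, name: str) -> pd.DataFrame:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{name} table is missing columns {missing}")
    out = {}
    for col, (kind, constraint) in schema.items():
        s = df[col]
        if kind in ("int", "float", "bin"):
            coerced = pd.to_numeric(s, errors="coerce")
            bad = coerced.isna() & s.notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"{name} table row {row}, column '{col}': "
                    f"non-numeric value {s.iloc[row]!r}"
                )
            if coerced.isna().any():
                row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
                raise CohortValidationError(
                    f"{name} table row {row}, column '{col}': missing value"
                )
            if kind == "bin":
                vals = coerced.to_numpy()
                bad = ~np.isin(vals, (0, 1))
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise CohortValidationError(
                        f"{name} table row {row}, column '{col}': "
                        f"expected 0/1, got {vals[row]!r}"
                    )
                out[col] = coerced.astype(np.int64)
            elif kind == "int":
                out[col] = coerced.astype(np.int64)
            else:
                out[col] = coerced.astype(np.float64)
            if kind != "bin" and constraint is not None:
                lo, hi = constraint
                vals = out[col].to_numpy()
                bad = np.zeros(len(vals), dtype=bool)
                if lo is not None:
                    bad |= vals < lo
                if hi is not None:
                    bad |= vals > hi
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise CohortValidationError(
                        f"{name} table row {row}, column '{col}': value "
                        f"{vals[row]!r} outside [{lo}, {hi}]"
                    )
        else:  # categorical
            vals = s.astype(str)
            bad = ~vals.isin(constraint)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"{name} table row {row}, column '{col}': "
                    f"{s.iloc[row]!r} not in {constraint}"
                )
            out[col] = vals
    return pd.DataFrame(out, index=df.index)[list(schema)]


def validate_baseline(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a baseline table; raise on schema violations."""
    return _validate_table(df, BASELINE_SCHEMA, "baseline")


def validate_followups(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a follow-up table (may be empty)."""
    if len(df) == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in FOLLOWUP_SCHEMA})
    return _validate_table(df, FOLLOWUP_SCHEMA, "follow-up")


def write_cohort(baseline: pd.DataFrame, followups: pd.DataFrame, directory: str,
                 prefix: str = "cohort") -> tuple[str, str]:
    """Write baseline and follow-up tables as headered CSV files.

    Returns the two file paths. Floats round-trip exactly (default pandas
    ``repr`` formatting).
    """
    os.makedirs(directory, exist_ok=True)
    bpath = os.path.join(directory, f"{prefix}_baseline.csv")
    fpath = os.path.join(directory, f"{prefix}_followups.csv")
    baseline[BASELINE_COLUMNS].to_csv(bpath, index=False)
    if len(followups):
        followups[FOLLOWUP_COLUMNS].to_csv(fpath, index=False)
    else:
        pd.DataFrame(columns=FOLLOWUP_COLUMNS).to_csv(fpath, index=False)
    return bpath, fpath


def read_cohort(directory: str, prefix: str = "cohort") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort written by :func:`write_cohort`."""
    bpath = os.path.join(directory, f"{prefix}_baseline.csv")
    fpath = os.path.join(directory, f"{prefix}_followups.csv")
    baseline = validate_baseline(pd.read_csv(bpath))
    raw = pd.read_csv(fpath)
    followups = validate_followups(raw)
    return baseline, followups
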