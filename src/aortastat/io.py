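"""Cohort CSV reading and writing.

The cohort schema is a UTF-8, decimal-point CSV with one row per patient
and the exact header:

    id,age,sex,height,body_mass,sbp,dbp,ao_diastolic_diameter,
    ao_systolic_diameter,eat_thickness,eat_volume
"""

from __future__ import annotations

import pandas as pd

from .errors import CohortValidationError
from .records import COHORT_COLUMNS, NUMERIC_COLUMNS, PatientRecord, records_to_frame, validate_frame


def read_cohort_frame(path, skip_invalid: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortValidationError` listing every bad row (1-based
    body row numbers) unless ``skip_invalid`` is set, in which case invalid
    rows are dropped.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([(0, f"missing column(s) {missing}")])
    df = df[COHORT_COLUMNS]

    errors = []
    for col in NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        for pos in df.index[coerced.isna() & df[col].notna()]:
            errors.append((int(pos) + 1, f"non-numeric value in {col!r}: {df.at[pos, col]!r}"))
        for pos in df.index[df[col].isna()]:
            errors.append((int(pos) + 1, f"missing value in {col!r}"))
        df[col] = coerced
    if errors:
        raise CohortValidationError(sorted(errors))

    errors = validate_frame(df)
    if errors and not skip_invalid:
        raise CohortValidationError(errors)
    if errors:
        bad = sorted({i - 1 for i, _ in errors})
        df = df.drop(index=df.index[bad]).reset_index(drop=True)
    return df


def read_cohort(path, skip_invalid: bool = False) -> list[PatientRecord]:
    from .records import frame_to_records

    return frame_to_records(read_cohort_frame(path, skip_invalid=skip_invalid))


def write_cohort(records_or_frame, path) -> None:
    """Write records (or a cohort frame) as a cohort CSV, full precision."""
    if isinstance(records_or_frame, pd.DataFrame):
        frame = records_or_frame[COHORT_COLUMNS]
    else:
        frame = records_to_frame(records_or_frame)
    frame.to_csv(path, index=False, float_format="%.12g")


__all__ = ["read_cohort", "read_cohort_frame", "write_cohort"]
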