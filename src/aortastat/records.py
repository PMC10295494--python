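"""Patient-level domain types.

A :class:`PatientRecord` holds the raw per-patient measurements a CT
angiography reading yields (anthropometrics, brachial pressures, ascending
aortic diameters, epicardial adipose tissue thickness and volume).
:class:`DerivedIndices` holds everything computed from them.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

SEXES = ("male", "female")

#: Column order of the cohort CSV schema.
COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "height",
    "body_mass",
    "sbp",
    "dbp",
    "ao_diastolic_diameter",
    "ao_systolic_diameter",
    "eat_thickness",
    "eat_volume",
]

NUMERIC_COLUMNS = [c for c in COHORT_COLUMNS if c not in ("id", "sex")]

#: Columns appended by index derivation, in output order.
DERIVED_COLUMNS = [
    "bsa",
    "bmi",
    "pulse_pressure",
    "ao_strain",
    "ao_distensibility",
    "ao_stiffness_index",
    "eat_thickness_index",
    "eat_volume_index",
]


@dataclass(frozen=True)
class PatientRecord:
    """Raw measurements for one patient.

    Units: age [years], height [m], body_mass [kg], sbp/dbp [mmHg],
    aortic diameters [mm], eat_thickness [mm], eat_volume [mL].
    """

    id: str
    age: float
    sex: str
    height: float
    body_mass: float
    sbp: float
    dbp: float
    ao_diastolic_diameter: float
    ao_systolic_diameter: float
    eat_thickness: float
    eat_volume: float

    def validation_errors(self) -> list[str]:
        """Return human-readable invariant violations (empty list if valid)."""
        errs = []
        if self.sex not in SEXES:
            errs.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.height > 0:
            errs.append(f"height must be > 0, got {self.height}")
        if not self.body_mass > 0:
            errs.append(f"body_mass must be > 0, got {self.body_mass}")
        if not (self.sbp > self.dbp > 0):
            errs.append(f"requires sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}")
        if not self.ao_diastolic_diameter > 0:
            errs.append(
                f"ao_diastolic_diameter must be > 0, got {self.ao_diastolic_diameter}"
            )
        elif not self.ao_systolic_diameter >= self.ao_diastolic_diameter:
            errs.append(
                "ao_systolic_diameter must be >= ao_diastolic_diameter, got "
                f"{self.ao_systolic_diameter} < {self.ao_diastolic_diameter}"
            )
        if self.eat_thickness < 0:
            errs.append(f"eat_thickness must be >= 0, got {self.eat_thickness}")
        if self.eat_volume < 0:
            errs.append(f"eat_volume must be >= 0, got {self.eat_volume}")
        return errs

    def validate(self) -> "PatientRecord":
        errs = self.validation_errors()
        if errs:
            from .errors import DomainError

            raise DomainError(f"record {self.id!r}: " + "; ".join(errs))
        return self


@dataclass(frozen=True)
class DerivedIndices:
    """Per-patient computed quantities.

    ``ao_distensibility`` is carried in the study's nominal units
    (labelled cm^2/dyn): numerically 2 * strain[%] / pulse_pressure[mmHg].
    """

    bsa: float  # m^2
    bmi: float  # kg/m^2
    pulse_pressure: float  # mmHg
    ao_strain: float  # percent
    ao_distensibility: float  # nominal cm^2/dyn
    ao_stiffness_index: float  # dimensionless
    eat_thickness_index: float  # mm/m^2
    eat_volume_index: float  # mL/m^2


def records_to_frame(records) -> pd.DataFrame:
    """Stack PatientRecords into a DataFrame in the cohort CSV column order."""
    rows = [{f.name: getattr(r, f.name) for f in fields(PatientRecord)} for r in records]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    return [
        PatientRecord(
            id=str(row.id),
            age=float(row.age),
            sex=str(row.sex),
            height=float(row.height),
            body_mass=float(row.body_mass),
            sbp=float(row.sbp),
            dbp=float(row.dbp),
            ao_diastolic_diameter=float(row.ao_diastolic_diameter),
            ao_systolic_diameter=float(row.ao_systolic_diameter),
            eat_thickness=float(row.eat_thickness),
            eat_volume=float(row.eat_volume),
        )
        for row in frame.itertuples(index=False)
    ]


def validate_frame(frame: pd.DataFrame) -> list[tuple[int, str]]:
    """Validate every row; return (1-based row number, message) pairs."""
    out = []
    for i, rec in enumerate(frame_to_records(frame), start=1):
        for msg in rec.validation_errors():
            out.append((i, msg))
    return out
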