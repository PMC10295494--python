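"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input violates a formula's mathematical domain (e.g. non-positive
    height, SBP <= DBP, zero strain for the stiffness index)."""


class CohortValidationError(ValueError):
    """A cohort table contains rows violating patient-record invariants.

    Carries ``row_errors``: a list of (row_number, message) pairs, row
    numbers being 1-based positions in the CSV body.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.row_errors[:10])
        extra = "" if len(self.row_errors) <= 10 else f" (+{len(self.row_errors) - 10} more)"
        super().__init__(f"{len(self.row_errors)} invalid row(s): {lines}{extra}")


class DegenerateSplitError(ValueError):
    """A median split produced an empty subgroup (all mass at the median)."""


class CalibrationError(RuntimeError):
    """The simulator calibration is unusable (e.g. correlation matrix too far
    from positive semi-definite, or unattainable marginal moments)."""
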