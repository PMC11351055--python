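"""Exception hierarchy shared across the package.

All tpmtox-specific failures derive from :class:`TpmToxError` so callers
(and the CLI) can map them onto a small set of exit conditions.
"""

from __future__ import annotations


class TpmToxError(Exception):
    """Base class for all tpmtox errors."""


class SchemaError(TpmToxError):
    """A required column or field is missing from an input table."""


class TableValidationError(TpmToxError):
    """Parsed values violate a domain invariant (duplicate ids, negative A, ...)."""


class TableParseError(TpmToxError):
    """A cell could not be parsed; message names the row and column."""


class RegistryError(TpmToxError):
    """A phase-system registry is malformed or contains duplicates."""


class DescriptorMissingError(TpmToxError):
    """An LFER system needs a solute descriptor the record does not carry."""


class PartitionError(TpmToxError):
    """Partition-table construction failed for one or more (chemical, phase) cells.

    Attributes
    ----------
    failures : list of (chemical_id, phase, reason)
    """

    def __init__(self, failures):
        self.failures = list(failures)
        pairs = ", ".join(f"({cid}, {phase})" for cid, phase, _ in self.failures)
        super().__init__(
            f"{len(self.failures)} partition cell(s) could not be evaluated: {pairs}"
        )


class CalibrationError(TpmToxError):
    """Burden calibration is impossible (too few points, wrong mode, ...)."""


class DataError(TpmToxError):
    """Input data are structurally valid but unusable (missing LC50, NaN logK, ...)."""


class DegenerateColumnError(TpmToxError):
    """A column is constant where variance is required (standardization, Pearson r)."""

    def __init__(self, columns, context=""):
        self.columns = list(columns)
        msg = f"zero-variance column(s): {', '.join(map(str, self.columns))}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class MixedModeWarning(UserWarning):
    """Toxic units were summed across different modes of toxic action."""
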