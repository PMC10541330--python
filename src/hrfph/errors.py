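"""Exception hierarchy.

Everything raised on bad clinical input derives from :class:`ValidationError`
(itself a ``ValueError``) so callers can catch one class at the CLI boundary.
"""

from __future__ import annotations


class ScoringError(Exception):
    """Base class for all package errors."""


class ValidationError(ScoringError, ValueError):
    """An input violates a structural precondition."""


class DomainError(ValidationError):
    """A value is outside its physiologic/mathematical domain (e.g. PaO2 <= 0)."""


class UnitError(ValidationError):
    """A value appears to be on the wrong scale (e.g. percent-scale FiO2 > 1.0)."""


class MissingDataError(ScoringError):
    """A required measurement is absent and no fallback applies."""


class ConsistencyError(ValidationError):
    """A cohort specification violates an internal counting identity."""


class DegenerateTableError(ValidationError):
    """A contingency table has no information (zero total)."""


class ConfigError(ValidationError):
    """A score configuration is malformed."""


class RecordParseError(ScoringError):
    """One or more rows of a patient-record file failed validation.

    ``row_errors`` is a list of ``(row_number, message)`` pairs, 1-based and
    counting the header as row 1, so every offending row is reported at once.
    """

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.row_errors)
        super().__init__(f"{len(self.row_errors)} invalid record row(s): {lines}")
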