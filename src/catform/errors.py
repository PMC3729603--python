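"""Exception hierarchy and the machine-readable violation record.

Structural problems found while checking an already-built instrument are
reported as :class:`Violation` values (data, not exceptions); operations that
cannot proceed at all raise a :class:`CatformError` subclass.
"""

from __future__ import annotations

from dataclasses import dataclass


class CatformError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(CatformError):
    """An instrument document violates the dialect.

    Carries the list of violations that made the document unacceptable.
    """

    def __init__(self, violations: list["Violation"]):
        self.violations = list(violations)
        msg = "; ".join(f"{v.code} at {v.path}: {v.message}" for v in self.violations)
        super().__init__(f"instrument document invalid: {msg}")


class ExpressionError(CatformError):
    """Syntax or unknown-construct error in a mapping/scoring expression."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class EvaluationError(CatformError):
    """Arithmetic failure (division by zero) while evaluating an expression."""


class IntractableError(CatformError):
    """The requested enumeration or tree exceeds the configured size cap."""


class UnscorablePatternError(CatformError):
    """A response pattern has no entry in the lookup table."""


class MissingMediaError(CatformError):
    """A media key has no entry in the manifest."""


class PolicyError(CatformError):
    """A session operation violates an instrument policy.

    ``policy`` names the offending policy key in SCREAMING_SNAKE form,
    e.g. ``REQUIRE_RESPONDENT_ID``.
    """

    def __init__(self, policy: str, message: str):
        self.policy = policy
        super().__init__(f"{policy}: {message}")


class SessionStateError(CatformError):
    """A session operation was attempted in the wrong lifecycle state."""


class StoreError(CatformError):
    """The session store file cannot be read; names the newest backup if any."""

    def __init__(self, message: str, backup: str | None = None):
        self.backup = backup
        if backup:
            message = f"{message} (newest backup: {backup})"
        super().__init__(message)


class TreeFileError(CatformError):
    """A serialized CAT tree file is malformed."""


class BankFileError(CatformError):
    """An item-parameter bank file is malformed."""


class TableFileError(CatformError):
    """A lookup-table file is malformed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Violation:
    """One structural defect in an instrument or CAT tree.

    code: stable machine-readable identifier (e.g. ``DUPLICATE_ITEM_ID``)
    path: element path or object id locating the defect
    message: human-readable detail
    """

    code: str
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code} at {self.path}: {self.message}"
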