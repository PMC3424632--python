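"""Exception hierarchy for abpmine."""


class ABPMineError(Exception):
    """Base class for all abpmine errors."""


class FormatError(ABPMineError):
    """A table is structurally invalid (e.g. a required column is absent)."""


class ParseError(ABPMineError):
    """A cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ValidationError(ABPMineError):
    """A value violates a domain invariant."""


class ImputationError(ABPMineError):
    """Too few complete cases to fit the imputation regression."""


class UndefinedIndexError(ABPMineError):
    """An index (WBP/ARV) is undefined for the given series (n < 2)."""


class DegenerateAttributeError(ABPMineError):
    """An attribute cannot be screened (zero variance); callers skip it."""


class EmptySelectionError(ABPMineError):
    """No attribute passed the significance screen."""
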