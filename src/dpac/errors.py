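"""Exception hierarchy.

User-facing errors (bad input, bad configuration) derive from
:class:`UserInputError` so the command-line layer can map them to exit
code 1; anything else is treated as an internal error (exit code 2).
"""


class DpacError(Exception):
    """Base class for all package errors."""


class UserInputError(DpacError):
    """Invalid data, schema, or configuration supplied by the caller."""


class SchemaError(UserInputError):
    """A variable, state label, or column does not match the schema."""


class ConfigError(UserInputError):
    """An invalid configuration value."""


class IncompleteDataError(UserInputError):
    """An operation requiring complete data received missing cells."""


class ImpossibleEvidenceError(DpacError):
    """Evidence has probability zero under the model."""


class BudgetError(UserInputError):
    """A combinatorial cap was exceeded."""


class ImputationError(UserInputError):
    """Imputation cannot proceed (e.g. a record with no observed cell)."""


class NumericError(DpacError):
    """A numeric failure (non-finite likelihood) during fitting."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
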