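"""Exception types shared across the package."""


class TrialCuaError(Exception):
    """Base class for all package errors."""


class ConfigError(TrialCuaError):
    """A configuration value violates its declared invariant."""


class DatasetValidationError(TrialCuaError):
    """A dataset file or frame violates the schema.

    Carries ``row`` / ``column`` context when the violation comes from a
    parsed file.
    """

    def __init__(self, message, row=None, column=None):
        self.row = row
        self.column = column
        if row is not None or column is not None:
            message = f"{message} (row={row}, column={column})"
        super().__init__(message)


class TrajectoryError(TrialCuaError):
    """A utility trajectory cannot be integrated (e.g. entirely missing)."""


class UnknownResourceError(TrialCuaError):
    """A resource item has no entry in the unit-cost table."""

    def __init__(self, item):
        self.item = item
        super().__init__(f"unknown resource item: {item!r}")


class InsufficientDataError(TrialCuaError):
    """Too few complete cases to run an operation (e.g. PMM donors)."""


class ConvergenceError(TrialCuaError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        self.trace = trace
        super().__init__(message)


class EstimationError(TrialCuaError):
    """A model could not be estimated (singular design, invalid outcome)."""
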