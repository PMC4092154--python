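"""Exception hierarchy for zicpue."""


class ZicpueError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ZicpueError):
    """A required column is missing or a schema mapping is invalid."""


class RowParseError(ZicpueError):
    """A data cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int):
        super().__init__(message)
        self.row = row


class ValidationError(ZicpueError):
    """An input violates a structural invariant (e.g. mis-keyed cruise)."""


class BasisError(ZicpueError):
    """A spline basis cannot be built with the requested dimension."""


class ConvergenceError(ZicpueError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


class ConfigurationError(ZicpueError):
    """A scenario or run configuration is infeasible or incomplete."""


class SelectionError(ZicpueError):
    """Every candidate fit in a model-selection step failed."""


class ReconstructionError(ZicpueError):
    """Integer sex counts cannot be recovered uniquely from a rounded ratio."""


class UndefinedTestError(ZicpueError):
    """A statistical test is undefined for the given input (e.g. all zero)."""
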