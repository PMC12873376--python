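"""Exception hierarchy shared across the package."""


class CondxError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CondxError, ValueError):
    """A model or config parameter violates its constraints."""


class DomainError(CondxError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SchemaError(CondxError, ValueError):
    """An event table is missing required columns or violates the schema."""


class ChannelMappingError(CondxError, KeyError):
    """A logical channel cannot be resolved to a file parameter."""


class FormatError(CondxError, ValueError):
    """A file is malformed for its declared format."""


class EmptyGateError(CondxError, ValueError):
    """A gate selected zero events where at least one is required."""


class FitFailureError(CondxError, RuntimeError):
    """Optimization failed to converge from every start."""


class NonTerminationError(CondxError, RuntimeError):
    """A stochastic simulation exceeded its step cap."""

    def __init__(self, message: str, n_steps: int):
        super().__init__(message)
        self.n_steps = n_steps
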