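"""Exception hierarchy.

Validation problems (bad inputs, contract violations) derive from
:class:`ValidationError`; failures of the numerical machinery (singular
kriging systems, non-positive-definite covariances) derive from
:class:`NumericalError`.  The CLI maps the former to exit code 2 and the
latter to exit code 3.
"""


class PaddygeoError(Exception):
    """Base class for all package errors."""


class ValidationError(PaddygeoError, ValueError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A required column is missing from a tabular input."""


class ParseError(ValidationError):
    """A cell could not be parsed as a number."""


class InsufficientDataError(ValidationError):
    """Too few observations (or bins) for the requested operation."""


class DomainError(ValidationError):
    """Scalar argument outside its mathematical domain."""


class CapacityError(ValidationError):
    """More sample positions requested than the layout can hold."""


class NumericalError(PaddygeoError, RuntimeError):
    """Linear-algebra or optimization failure."""


class PipelineError(PaddygeoError):
    """Error raised by a pipeline stage; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
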