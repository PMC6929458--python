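"""Exception hierarchy shared across the package."""


class Ms2predError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(Ms2predError, ValueError):
    """An argument violates an operation's precondition."""


class InvalidSpecError(InvalidInputError):
    """A model specification is internally inconsistent or infeasible."""


class InvalidStateError(Ms2predError, RuntimeError):
    """An object is not in the state an operation requires."""


class UndefinedMetricError(Ms2predError, ValueError):
    """A similarity metric is undefined for the given vectors."""


class TrainingFailureError(Ms2predError, RuntimeError):
    """Optimisation produced a non-finite loss or otherwise diverged."""
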