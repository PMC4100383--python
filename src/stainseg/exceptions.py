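"""Exception hierarchy for the stainseg pipeline."""


class StainSegError(Exception):
    """Base class for all stainseg errors."""


class InvalidInputError(StainSegError, ValueError):
    """An input violates a structural precondition (shape, range, emptiness)."""


class DegenerateDataError(StainSegError, ValueError):
    """Data carry too little variation for the requested operation."""


class InsufficientDataError(StainSegError, ValueError):
    """Not enough samples (per class, per fold, ...) for the requested operation."""


class ConsistencyError(StainSegError, ValueError):
    """Two inputs that must agree (e.g. a DAB mask and cluster posteriors) do not."""


class NotFittedError(StainSegError, RuntimeError):
    """A model was used before being fitted."""


class NumericError(StainSegError, ArithmeticError):
    """A numerical operation failed (e.g. a covariance stayed singular)."""
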