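"""Exception hierarchy."""


class ConsortiaLogicError(Exception):
    """Base class for all errors raised by this package."""


class InputDimensionError(ConsortiaLogicError):
    """An assignment's length does not match the function's arity."""


class UnsupportedArityError(ConsortiaLogicError):
    """Requested input count outside the supported 1..4 range."""


class InvalidCircuitError(ConsortiaLogicError):
    """A circuit violates a structural invariant (cycle, bad fan-in, dead gate)."""


class DanglingReferenceError(InvalidCircuitError):
    """A gate references a signal that is neither an input nor a gate id."""


class WrongBasisError(ConsortiaLogicError):
    """An operation restricted to AND/OR/NOT received another gate kind."""


class BoundExceededError(ConsortiaLogicError):
    """A bounded exhaustive search ran out of budget before finding the target."""

    def __init__(self, message, bound=None):
        super().__init__(message)
        self.bound = bound


class UnreachableError(ConsortiaLogicError):
    """The target function is not expressible over the given basis."""


class ConfigurationError(ConsortiaLogicError):
    """Missing or inconsistent run configuration (e.g. unbounded 4-input sweep)."""


class ParameterError(ConsortiaLogicError):
    """A simulation parameter is outside its admissible domain."""


class ParseError(ConsortiaLogicError):
    """A serialized object violates the JSON schema."""

    def __init__(self, message, pointer=""):
        super().__init__(f"{message} (at {pointer or '/'})")
        self.pointer = pointer
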