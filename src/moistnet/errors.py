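"""Exception types shared across moistnet."""


class MoistnetError(Exception):
    """Base class for all moistnet errors."""


class ParameterError(MoistnetError, ValueError):
    """An argument is outside its documented domain (e.g. rho not in (0, 1))."""


class ValidationError(MoistnetError, ValueError):
    """Input data violates an invariant (negative flow, mask/grid mismatch, ...)."""


class FormatError(MoistnetError, ValueError):
    """A file could not be parsed; the message names the offending variable/field."""


class DegenerateInputError(MoistnetError, ValueError):
    """The operation is undefined for this input (e.g. thresholding zero total flow)."""
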