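"""Typed exceptions shared across the package."""


class GenebufferError(Exception):
    """Base class for all package errors."""


class ValidationError(GenebufferError, ValueError):
    """An input fails a precondition (non-finite value, bad enum, ...)."""


class UndefinedParameterError(GenebufferError, ValueError):
    """Arithmetic was attempted on an UNDEFINED buffering parameter.

    Perfect transfer leaves B's denominator at zero and perfect buffering
    does the same to T; these are meaningful states, not NaNs, so using
    them in arithmetic is an error rather than silent propagation.
    """


class DivergenceError(GenebufferError, ValueError):
    """A conversion hits a genuine singularity (e.g. B = -1, alpha = 135 deg)."""


class DegenerateInputError(GenebufferError, ValueError):
    """An input makes the requested quantity ill-posed (e.g. total = 0)."""


class InsufficientDataError(GenebufferError, ValueError):
    """Too few records to compute the requested statistic."""


class SchemaError(GenebufferError, ValueError):
    """A delimited input file is missing a mapped column."""
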