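"""Exception types raised by the package."""


class ExsyError(Exception):
    """Base class for all package errors."""


class ValidationError(ExsyError, ValueError):
    """A domain object or argument violates its invariants."""


class DimensionError(ExsyError, ValueError):
    """Operator or state dimensions are inconsistent or out of range."""


class GeneratorInstabilityError(ExsyError, RuntimeError):
    """A Liouvillian has growing modes; propagation would be unstable."""


class SpectrumFormatError(ExsyError, ValueError):
    """A spectrum text file could not be parsed."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class RegionError(ExsyError, ValueError):
    """Integration regions are invalid (outside axes or overlapping)."""


class FitError(ExsyError, RuntimeError):
    """Least-squares fitting failed."""
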