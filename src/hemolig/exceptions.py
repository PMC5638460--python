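"""Exception hierarchy.

Every error raised by hemolig derives from :class:`HemoligError`, so callers
(and the CLI) can map error classes onto exit codes without catching bare
``Exception``.
"""


class HemoligError(Exception):
    """Base class for all hemolig errors."""


class InputError(HemoligError, ValueError):
    """Malformed or inconsistent user input (files, metadata, arguments)."""


class DomainError(HemoligError, ValueError):
    """Argument outside the mathematical domain of a model function."""


class OutOfRangeError(HemoligError, ValueError):
    """A requested point lies outside the span of the available data."""


class DegenerateBasisError(HemoligError, ValueError):
    """Reference spectra are collinear (identical up to scale)."""


class UndefinedSaturationError(HemoligError, ZeroDivisionError):
    """Oxy + deoxy coefficients are both zero; saturation is undefined."""


class InsufficientDataError(HemoligError, ValueError):
    """Too few points to perform the requested computation."""


class FitError(HemoligError, RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics.

    Attributes
    ----------
    diagnostics : dict
        Last iterate / solver message, for post-mortem inspection.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
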