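"""Exception hierarchy shared across the package."""


class QscommError(Exception):
    """Base class for all package-specific errors."""


class DomainError(QscommError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class InsufficientDataError(QscommError, ValueError):
    """Too few usable observations for the requested estimate."""


class FitError(QscommError, RuntimeError):
    """A nonlinear fit failed to converge or produced unusable estimates."""


class QuantificationError(QscommError, RuntimeError):
    """Calibration and sample curves cannot be compared reliably."""
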