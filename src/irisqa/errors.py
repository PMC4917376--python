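"""Exception hierarchy for irisqa.

All errors raised by the package derive from :class:`IrisQAError` so callers
can catch package failures with a single except clause. ``DomainError`` and
``RangeError`` subclass ``ValueError`` as well, matching how numpy/scipy
signal bad scalar arguments.
"""


class IrisQAError(Exception):
    """Base class for all irisqa errors."""


class DomainError(IrisQAError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class RangeError(IrisQAError, ValueError):
    """A value falls outside the supported tabulated/interpolation range."""


class ValidationError(IrisQAError, ValueError):
    """Structured input (session, baseline, config, file) failed validation.

    ``details`` optionally carries a list of individual offender messages,
    e.g. one per malformed CSV row.
    """

    def __init__(self, message: str, details: list[str] | None = None):
        self.details = list(details or [])
        if self.details:
            message = message + "\n  - " + "\n  - ".join(self.details)
        super().__init__(message)


class IntegrationError(IrisQAError, ArithmeticError):
    """Numerical quadrature failed to reach the requested tolerance."""
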