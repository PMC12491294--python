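"""Exception hierarchy.

Validation problems (bad parameters, malformed scenario files) and numerical
problems (degenerate spectra, integration blow-up) are kept on separate
branches so the command-line layer can map them to distinct exit codes.
"""


class PhagedynError(Exception):
    """Base class for all package errors."""


class ValidationError(PhagedynError):
    """Invalid parameters, states, or scenario configuration."""

    def __init__(self, message, items=None):
        super().__init__(message)
        #: itemized list of individual violations, when available
        self.items = list(items) if items else [message]


class DomainError(ValidationError):
    """An argument lies outside the mathematical domain of an operation."""


class NumericalError(PhagedynError):
    """Base class for run-time numerical failures."""


class DegeneracyError(NumericalError):
    """The eigenproblem is degenerate and the eigenbasis construction unsafe."""


class ThresholdError(NumericalError):
    """The system sits exactly on the epidemic threshold (lambda_2 = 0)."""


class IntegrationError(NumericalError):
    """The integrator produced a non-finite state."""

    def __init__(self, message, step=None):
        super().__init__(message)
        self.step = step
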