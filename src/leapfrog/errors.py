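"""Exception hierarchy for the leapfrog package.

Validation problems (bad designs, degenerate data, malformed configs or
scripts) raise :class:`LeapfrogValidationError`; failures of the numerical
machinery (quadrature non-convergence) raise :class:`LeapfrogNumericalError`.
The CLI maps these to exit codes 2 and 3 respectively.
"""


class LeapfrogError(Exception):
    """Base class for all package-specific errors."""


class LeapfrogValidationError(LeapfrogError, ValueError):
    """Invalid input: design parameters, data, configs or replay scripts."""


class InsufficientDataError(LeapfrogValidationError):
    """A group has fewer observations than the statistic requires."""


class DegenerateDataError(LeapfrogValidationError):
    """Data admit no valid test statistic (e.g. zero pooled variance)."""


class InvalidPriorError(LeapfrogValidationError):
    """Prior specification violates its constraints (e.g. rscale <= 0)."""


class ScriptError(LeapfrogValidationError):
    """A replay script step is infeasible under the trial's decision rules."""


class LeapfrogNumericalError(LeapfrogError, ArithmeticError):
    """Quadrature failed to reach the requested tolerance.

    Carries diagnostic attributes ``estimate`` and ``abserr`` when available.
    """

    def __init__(self, message, estimate=None, abserr=None):
        super().__init__(message)
        self.estimate = estimate
        self.abserr = abserr
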