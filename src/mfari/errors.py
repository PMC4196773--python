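"""Exception hierarchy for manoeuvre analysis failures.

Every error carries enough context (channel, window, offending value) for a
caller to report which stage of the pipeline rejected a recording.
"""


class MfariError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MfariError, ValueError):
    """A parameter is outside its documented domain (e.g. cutoff >= Nyquist)."""


class NoDropError(MfariError):
    """No pressure/velocity drop of usable amplitude after cuff release."""


class InsufficientDataError(MfariError):
    """Recording too short, or too few beats/pairs, for the requested analysis."""


class NumericInstabilityError(MfariError):
    """Model state diverged (non-finite), typically time constant << sample period."""


class DegenerateInputError(MfariError):
    """Input admits no defined answer (flat signal correlation, rank-deficient design)."""


class UndefinedCovError(DegenerateInputError):
    """Coefficient of variation undefined because the mean is (near) zero."""
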