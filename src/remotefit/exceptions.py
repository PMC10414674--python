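"""Exception hierarchy.

Every domain error raised by the toolkit derives from :class:`RemoteFitError`
so callers (and the CLI) can catch one type and turn it into a diagnostic.
"""


class RemoteFitError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(RemoteFitError, ValueError):
    """An argument violates its documented domain (non-finite coordinate,
    negative variance, coefficient outside [-1, 1], ...)."""


class InsufficientDataError(RemoteFitError):
    """Too few records to compute the requested quantity."""


class InvalidTrackError(RemoteFitError):
    """A GPS track violates its invariants (non-increasing timestamps)."""


class UnusableTrackError(RemoteFitError):
    """A GPS track where every interval was flagged as an outlier."""


class UnusableSequenceError(RemoteFitError):
    """A pose sequence in which no frame yields a usable posture."""


class DegenerateDesignError(RemoteFitError):
    """A repeated-measures design with a single subject or single session."""


class EstimationFailureError(RemoteFitError):
    """A model fit did not converge; the message carries diagnostics."""


class InfeasibleDesignError(RemoteFitError):
    """A sample-size specification with no solution (e.g. rho0 == rho1)."""


class UndefinedStatisticError(RemoteFitError):
    """A statistic undefined for the given data (zero-variance margin,
    zero gold score in a relative error, coincident angle points)."""


class VocabularyError(RemoteFitError):
    """A joint name outside the COCO-17 vocabulary."""


class ParseError(RemoteFitError):
    """A malformed input file; the message names the offending element."""
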