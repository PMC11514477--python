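"""Exception types raised by the pipeline.

Every anticipated failure mode has its own class so callers can distinguish
a degenerate input (constant image, empty mask) from a violated contract
(ratio with a zero denominator, Xi run split in two) without string
matching.
"""


class XirepError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(XirepError, ValueError):
    """A parameter violates its documented invariant."""


class DegenerateHistogramError(XirepError):
    """Automatic thresholding on a (near-)constant image; no silent
    full/empty mask is produced."""


class PlacementError(XirepError):
    """No admissible placement found for a control region."""


class InsufficientPopulationError(XirepError):
    """Too few cells to fit a population histogram mode."""


class UndefinedRatioError(XirepError, ZeroDivisionError):
    """A ratio or density metric with a zero denominator."""


class UndefinedCvError(XirepError, ZeroDivisionError):
    """Coefficient of variation undefined (zero mean) or not normalisable
    (zero pretreatment cV)."""


class AmbiguityError(XirepError):
    """A quantity that must be unique is not (e.g. two disjoint Xi-pattern
    runs in one live sequence); reported rather than silently merged."""


class NormalizationAnchorError(XirepError):
    """The control condition / anchor time point needed for normalisation is
    missing."""


class InconsistencyError(XirepError):
    """Measured quantities violate a structural invariant (e.g. scaffold
    area exceeding total halo area)."""
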