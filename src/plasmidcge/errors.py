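"""Exception hierarchy for the plasmid-topology quantification pipeline."""


class PlasmidCGEError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PlasmidCGEError):
    """A file could not be parsed at all (empty table, wrong layout)."""


class ValidationError(PlasmidCGEError):
    """Parsed content violates a structural invariant (grids, headers, roles)."""


class InsufficientBaselineError(PlasmidCGEError):
    """Too few samples remain outside the exclusion windows to fit a baseline."""


class AlignmentError(PlasmidCGEError):
    """A buffer trace's time grid does not overlap the sample grid."""


class NoiseEstimationError(PlasmidCGEError):
    """No samples outside the isoform windows, so noise cannot be estimated."""


class MarkerNotFoundError(PlasmidCGEError):
    """The alignment-marker lane contains no peak above the noise floor."""


class WindowRangeError(PlasmidCGEError):
    """An integration window extends beyond the trace's time grid."""


class UndefinedFractionError(PlasmidCGEError):
    """Total integrated intensity is zero; isoform fractions are undefined."""


class LadderMatchError(PlasmidCGEError):
    """Detected ladder peak count does not equal the ladder specification."""


class InsufficientDesignError(PlasmidCGEError):
    """A study analysis was requested with too few levels or a missing reference."""


class AnnotationError(PlasmidCGEError):
    """Sample lanes are missing required metadata annotations."""
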