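"""Exception hierarchy shared across the package."""


class GGMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GGMError):
    """Bad run configuration: missing roles, invalid thresholds, bad paths."""


class AlignmentError(GGMError):
    """Sequences of unequal length or otherwise unusable alignment."""


class AlphabetError(AlignmentError):
    """Character outside {A, C, G, T, N, -} in an input alignment."""


class AnnotationError(GGMError):
    """Malformed region annotation (overlapping exons, missing features...)."""


class FrameError(AnnotationError):
    """Ungapped reference coding length not a positive multiple of 3."""


class EstimationError(GGMError):
    """A rate or duration estimate cannot be formed from the given data."""


class InsufficientSignalError(GGMError):
    """Too few informative sites to run a classification or a scan."""
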