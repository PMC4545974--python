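"""Exception hierarchy for the speechkin pipeline.

Every stage raises a subclass of :class:`SpeechKinError`, so orchestration
code can drop a single trial (or participant) on any stage failure while
letting programming errors propagate.
"""


class SpeechKinError(Exception):
    """Base class for all speechkin errors."""


class FormatError(SpeechKinError):
    """A file does not conform to the documented table layout."""


class SamplingError(SpeechKinError):
    """Time axis is non-uniform or disagrees with the declared rate."""


class InputError(SpeechKinError):
    """An argument violates an operation's precondition."""


class ValidationError(SpeechKinError):
    """Metadata fails validation (unknown codes, duplicate ids, ...)."""


class GeometryError(SpeechKinError):
    """Degenerate marker geometry (e.g. collinear head markers)."""


class ParameterError(SpeechKinError):
    """A configuration parameter is out of its valid range."""


class SegmentationError(SpeechKinError):
    """An utterance could not be segmented (wrong peak count, ...)."""


class ExtractionError(SpeechKinError):
    """A movement cycle could not be delimited within the segment."""


class ComputationError(SpeechKinError):
    """A kinematic measure is undefined for the given input."""


class NormalizationError(SpeechKinError):
    """Amplitude normalization impossible (zero-variance trial)."""


class GenerationError(SpeechKinError):
    """The simulator could not realise a trial (e.g. jitter overlap)."""
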