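"""Exception hierarchy for the pipeline.

Everything raised deliberately by this package derives from :class:`AepMapError`
so callers can catch pipeline failures without masking programming errors.
"""


class AepMapError(Exception):
    """Base class for all errors raised by aepmap."""


class ArgumentError(AepMapError, ValueError):
    """A caller-supplied argument violates an operation's precondition."""


class EmptyPartError(AepMapError):
    """An epoch-averaging request found no events in the requested part."""


class UndefinedSimilarityError(AepMapError):
    """Similarity requested between waveforms where one has zero variance."""


class DegenerateFeatureError(AepMapError):
    """Cohort normalization hit a feature with zero spread."""


class FitError(AepMapError):
    """A classifier could not be fitted (e.g. a class with too few points)."""


class FoldError(AepMapError):
    """A cross-validation fold is invalid (e.g. a training set lost a class)."""

    def __init__(self, message: str, patient_id: str | None = None):
        super().__init__(message)
        self.patient_id = patient_id


class UndefinedMetricError(AepMapError):
    """A confusion-matrix metric has a zero denominator."""


class LoadError(AepMapError):
    """An input recording could not be loaded or lacks required content."""
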