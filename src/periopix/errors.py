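"""Exception hierarchy shared across the pipeline."""


class PeriopixError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PeriopixError, ValueError):
    """Invalid parameters, ranges, or domain-type invariant violations."""


class LayoutError(PeriopixError):
    """Scene geometry does not fit inside the requested image frame."""


class EncodingError(PeriopixError):
    """A landmark could not be encoded as a heatmap (e.g. out of bounds)."""

    def __init__(self, message: str, landmark_index: int | None = None):
        super().__init__(message)
        self.landmark_index = landmark_index


class DecodingError(PeriopixError):
    """A heatmap could not be decoded to coordinates (e.g. all-NaN map)."""

    def __init__(self, message: str, landmark_index: int | None = None):
        super().__init__(message)
        self.landmark_index = landmark_index


class CalibrationNotFoundError(PeriopixError):
    """No qualifying green fiducial component was found in the image."""


class ConfigurationError(PeriopixError):
    """Inconsistent training or pipeline configuration."""


class EvaluationError(PeriopixError):
    """Evaluation is impossible for an image (e.g. zero inter-pupil distance)."""


class SchemaError(PeriopixError):
    """An annotation file violates the JSON schema; names the offending key."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key


class DegenerateIccError(PeriopixError):
    """ICC is undefined (no between-subject variance)."""
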