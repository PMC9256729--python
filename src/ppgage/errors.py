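"""Exception hierarchy shared across the pipeline stages."""


class PPGAgeError(Exception):
    """Base class for all package errors."""


class DomainError(PPGAgeError, ValueError):
    """A physiological quantity is outside its admissible domain."""


class ParameterError(PPGAgeError, ValueError):
    """Waveform-model parameters are inconsistent (e.g. pulse too short)."""


class ConfigurationError(PPGAgeError, ValueError):
    """Invalid filter/model/pipeline configuration."""


class InputError(PPGAgeError, ValueError):
    """Malformed input data (wrong shape, range, or columns)."""


class SegmentationError(PPGAgeError, RuntimeError):
    """Pulse segmentation could not proceed (e.g. fewer than two onsets)."""


class UnusableRecordingError(PPGAgeError, RuntimeError):
    """A recording yields no usable pulse segments after quality gating."""


class NormalizationError(PPGAgeError, ValueError):
    """A degenerate (flat) waveform cannot be min-max normalized."""


class TrainingError(PPGAgeError, RuntimeError):
    """Model training failed (e.g. non-finite loss)."""
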