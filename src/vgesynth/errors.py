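"""Exception types shared across the pipeline."""


class VgesynthError(Exception):
    """Base class for all package errors."""


class AudioFormatError(VgesynthError):
    """A file could not be read or written as WAV audio."""


class DegenerateInputError(VgesynthError, ValueError):
    """An input is structurally valid but carries no usable signal."""


class CycleDetectionError(VgesynthError):
    """Heart-period estimation or cycle-peak detection failed."""


class InvalidGradeError(VgesynthError, ValueError):
    """A Kisman-Masurel code outside the conversion chart was supplied."""


class ConfigError(VgesynthError, ValueError):
    """An invalid generation configuration was supplied."""
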