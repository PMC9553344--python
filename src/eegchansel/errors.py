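"""Exception hierarchy.

``ConfigError`` covers bad parameters/configuration (CLI exit code 2);
``DataError`` covers unreadable or inconsistent input data (CLI exit code 3).
"""


class EegChanSelError(Exception):
    """Base class for all package errors."""


class ConfigError(EegChanSelError):
    """Invalid parameter or configuration value."""


class DataError(EegChanSelError):
    """Problem with input data."""


class MontageMismatchError(DataError):
    """File channel names do not cover the requested montage."""


class DataQualityError(DataError):
    """Non-finite samples in a recording; message names the channel."""


class UpsamplingError(ConfigError):
    """Requested sampling rate exceeds the recording's rate."""


class EmptyEpochsError(DataError):
    """Recording shorter than a single epoch."""


class FusionError(DataError):
    """Feature matrices are not alignable for fusion."""
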