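"""Exception hierarchy."""


class TelebpError(Exception):
    """Base class for all package errors."""


class ConfigError(TelebpError):
    """Invalid configuration or parameters."""


class DataError(TelebpError):
    """Malformed or unusable input data."""


class NoBeatsError(DataError):
    """No pressure pulses could be detected in a waveform."""


class UnknownPresetError(ConfigError):
    """Requested strain preset is not registered."""
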