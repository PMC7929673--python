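"""Exception types shared across the pipeline."""


class PCGQAError(ValueError):
    """Base class for all pipeline errors."""


class DegenerateSignalError(PCGQAError):
    """Raised for constant, all-zero or otherwise information-free input."""


class UnsupportedRateError(PCGQAError):
    """Raised when the sampling rate is below the supported minimum."""


class TooShortError(PCGQAError):
    """Raised when a signal is too short for the requested analysis."""
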