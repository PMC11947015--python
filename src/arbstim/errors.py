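"""Exception hierarchy shared across the stimulator toolkit."""


class StimulatorError(Exception):
    """Base class for all errors raised by this package."""


class PayloadRangeError(StimulatorError, ValueError):
    """Command code or 12-bit payload outside its representable range."""


class SampleRangeError(StimulatorError, ValueError):
    """Stimulus sample outside the signed 12-bit range [-2048, 2047]."""


class CapacityError(StimulatorError):
    """Stimulus exceeds the 32768-sample-per-channel memory capacity."""


class ConfigurationError(StimulatorError):
    """Invalid device configuration (unknown frequency index, readback mismatch)."""


class TransportError(StimulatorError):
    """Byte-level link failure: short read, echo mismatch, unavailable port."""


class ResolutionError(StimulatorError, ValueError):
    """Requested waveform feature is shorter than one sampling period."""


class AliasingError(StimulatorError, ValueError):
    """Requested frequency exceeds the Nyquist limit of the sampling rate."""


class NormalizationError(StimulatorError, ValueError):
    """Waveform amplitude leaves the normalized [-1, 1] range."""


class CsvFormatError(StimulatorError, ValueError):
    """Malformed stimulus CSV file (non-integer or out-of-range line)."""


class LengthMismatchError(StimulatorError, ValueError):
    """The two channel stimuli do not have equal length."""


class UploadError(StimulatorError):
    """Device memory readback differs from the uploaded stimulus."""
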