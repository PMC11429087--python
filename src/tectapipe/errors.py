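"""Exception hierarchy shared across the pipeline stages."""


class TectapipeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TectapipeError, ValueError):
    """A configuration object violates its invariants."""


class SamplingError(TectapipeError, ValueError):
    """A sampling rate cannot represent the requested frequency content."""


class PlacementError(TectapipeError, RuntimeError):
    """Requested event load does not fit into the recording."""

class InputError(TectapipeError, ValueError):
    """Invalid data passed to an analysis operation."""


class FormatError(TectapipeError, ValueError):
    """An on-disk artifact does not conform to the expected format."""
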