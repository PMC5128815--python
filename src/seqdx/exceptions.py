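"""Exception hierarchy shared across the package."""


class SeqdxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SeqdxError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataFormatError(SeqdxError, ValueError):
    """A malformed input file or table."""


class DegenerateDataError(SeqdxError, ValueError):
    """Input that is formally valid but statistically degenerate
    (single-class labels, zero-variance groups, zero-total samples)."""
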