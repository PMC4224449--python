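"""Exception hierarchy shared across the pipeline stages.

Exit-code mapping for the CLI: ConfigurationError -> 2, ParseError -> 3,
ComputationError -> 4, anything else -> 1.
"""


class ToxmodError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ToxmodError):
    """Invalid configuration value; the message names the offending field."""


class ParseError(ToxmodError):
    """Malformed input file; the message carries the path and line number."""


class ComputationError(ToxmodError):
    """A stage received inputs it cannot compute on (empty result, missing mapping...)."""
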