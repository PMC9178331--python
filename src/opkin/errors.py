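"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, I/O errors (OSError,
VcfParseError) -> 3, ComputationError and UndefinedValueError -> 4.
"""


class OpkinError(Exception):
    """Base class for all package errors."""


class ConfigError(OpkinError):
    """Invalid configuration, manifest or preconditions."""


class VcfParseError(OpkinError):
    """Malformed VCF input; message names the offending line where known."""


class ComputationError(OpkinError):
    """A stage failed mid-computation."""


class UndefinedValueError(ComputationError):
    """A statistic is undefined for the given data (e.g. zero informative loci)."""
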