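"""Exception hierarchy.

Parse, configuration, and data errors are distinguished so the CLI can map
them to the conventional exit codes (usage -> 2, data -> 1).
"""


class MspScanError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(MspScanError):
    """A malformed input file (bad column count, type, or value)."""


class ConfigError(MspScanError):
    """Inconsistent parameters or an invalid sample manifest."""


class DataError(MspScanError):
    """Structurally valid input that violates a data contract
    (e.g. duplicate observation keys)."""
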