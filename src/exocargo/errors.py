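"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
ParseError / AlignmentError -> 3, InvariantError -> 4.
"""


class ExocargoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExocargoError):
    """An invalid parameter or configuration value, naming the offending field."""


class ParseError(ExocargoError):
    """A malformed input file; the message names the row and column involved."""


class AlignmentError(ExocargoError):
    """Label mismatch between files that must share row/column labels."""


class InvariantError(ExocargoError):
    """An internal consistency check failed."""
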