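"""Exception hierarchy.

All user-facing failures derive from :class:`SenoconvergeError` so callers
(and the CLI) can distinguish pipeline errors from programming bugs.
"""


class SenoconvergeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SenoconvergeError):
    """A file does not conform to its expected tabular format."""


class DataError(SenoconvergeError):
    """Input values violate an invariant (range, sign, uniqueness...)."""


class ParameterError(SenoconvergeError):
    """An argument is outside its valid domain."""
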