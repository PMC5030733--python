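"""Exception hierarchy.

All library errors derive from :class:`GravicalError` so callers (and the CLI)
can distinguish validation problems from programming errors.
"""


class GravicalError(Exception):
    """Base class for all errors raised by this package."""


class InvariantError(GravicalError, ValueError):
    """A domain object violates one of its structural invariants."""


class RangeError(GravicalError, ValueError):
    """A volume falls outside the span covered by a liquid class."""


class ConfigurationError(GravicalError, ValueError):
    """A criteria table or instrument configuration is missing or malformed."""


class XMLFormatError(GravicalError, ValueError):
    """A liquid-class XML document does not conform to the documented schema.

    The message includes the path of the offending element where applicable.
    """
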