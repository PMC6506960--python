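"""Exception hierarchy for the cometh package."""


class CoMethError(Exception):
    """Base class for all package errors."""


class ParseError(CoMethError):
    """A methylation table could not be parsed; the message names the line."""


class ValidationError(CoMethError):
    """Input data violate a structural invariant (ordering, ranges, schema)."""


class UsageError(CoMethError):
    """An operation was called with arguments that make no sense for it."""
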