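"""Exception hierarchy shared across the package."""


class CSNError(Exception):
    """Base class for all csnet errors."""


class ParseError(CSNError):
    """A file could not be parsed; the message names the file and, where
    available, the offending line."""


class ValidationError(CSNError):
    """Input violates a documented contract (negative values, duplicate
    identifiers, misaligned label sets, ...)."""


class DegenerateBoxError(CSNError):
    """A neighborhood box spans zero or all non-focal cells, so the null
    standard deviation of the statistic is zero."""


class SizeCapError(CSNError):
    """A requested materialization exceeds the configured size cap."""
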