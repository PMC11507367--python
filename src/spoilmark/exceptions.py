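"""Exception hierarchy for spoilmark."""


class SpoilmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpoilmarkError, ValueError):
    """Invalid parameter value (negative tolerance, probability outside [0,1], ...)."""


class ParseError(SpoilmarkError, ValueError):
    """Malformed input file; the message names the offending row/column/position."""


class DegenerateClassError(SpoilmarkError, ValueError):
    """A discriminant step received fewer than two classes."""


class DegenerateDataError(SpoilmarkError, ValueError):
    """A statistic is undefined for the given data (constant target, zero variance, ...)."""
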