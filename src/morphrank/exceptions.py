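"""Exception hierarchy."""


class MorphrankError(Exception):
    """Base class for all package errors."""


class ValidationError(MorphrankError):
    """Structural problem in an input (duplicate ids, conflicting assignments)."""


class ParseError(MorphrankError):
    """Malformed input file content."""


class ParameterError(MorphrankError, ValueError):
    """Out-of-range or inconsistent parameter value."""


class EmptyScorableSet(MorphrankError):
    """No bait gene falls in any scorable module of any configuration."""
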