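"""Exception hierarchy shared across the package."""


class AutoregError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AutoregError, ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(AutoregError, ValueError):
    """In-memory structure violates a documented invariant."""


class CapacityError(AutoregError, ValueError):
    """A simulation request does not fit in the requested coordinate space."""


class StageError(AutoregError, ValueError):
    """A time point falls outside the differentiation protocol."""


class EmptyResultError(AutoregError, ValueError):
    """A filtering step removed everything."""
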