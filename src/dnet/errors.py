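"""Exception types shared across the pipeline."""


class DnetError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(DnetError):
    """A configuration object violates one of its invariants."""


class QCError(DnetError):
    """Quality control removed every gene; names the rule that did it."""


class ParseError(DnetError):
    """A file could not be parsed; message carries the offending line."""


class DegenerateInputError(DnetError):
    """Input is structurally valid but degenerate (e.g. all correlations equal)."""
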