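"""Exception types shared across the package."""


class TlgrnError(Exception):
    """Base class for all package errors."""


class ParseError(TlgrnError):
    """Malformed input file (carries a line number where possible)."""


class ValidationError(TlgrnError):
    """Input violates a documented precondition or invariant."""


class InternalConsistencyError(TlgrnError):
    """A computed quantity violated a mathematical invariant (bug guard)."""
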