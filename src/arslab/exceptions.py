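"""Exception hierarchy used across the package."""


class ArslabError(Exception):
    """Base class for all package errors."""


class ValidationError(ArslabError, ValueError):
    """An argument or object violates a documented precondition."""


class ParseError(ArslabError, ValueError):
    """A text file could not be parsed; the message names the offending line."""


class GenerationError(ArslabError, RuntimeError):
    """Random generation could not satisfy its constraints."""
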