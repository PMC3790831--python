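"""Exception hierarchy."""


class SoftDockError(Exception):
    """Base class for all softdock errors."""


class ParseError(SoftDockError):
    """A structure or config file could not be parsed."""


class TypingError(SoftDockError):
    """An atom could not be mapped to a solvation parameter type."""
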