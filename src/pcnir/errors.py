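"""Exception types shared across the package."""


class PcnirError(ValueError):
    """Base class for all domain errors raised by pcnir."""


class ParseError(PcnirError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(PcnirError):
    """Input data or parameters violate a documented contract."""
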