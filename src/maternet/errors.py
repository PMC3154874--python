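"""Exception hierarchy shared across the package."""


class MaternetError(Exception):
    """Base class for all package errors."""


class FormatError(MaternetError):
    """A file does not conform to the expected dialect (missing columns, bad tokens)."""


class ValidationError(MaternetError):
    """Parsed content violates a domain invariant (bounds, duplicates, emptiness)."""
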