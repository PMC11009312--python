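"""Exception types shared across the package."""


class MifqcError(Exception):
    """Base class for all package errors."""


class FormatError(MifqcError):
    """A file does not conform to the expected table/manifest layout."""


class ValidationError(MifqcError):
    """Data is well-formed but violates a domain invariant."""


class DegenerateInputError(MifqcError):
    """An operation received input it cannot meaningfully process
    (e.g. a constant intensity channel handed to Otsu thresholding)."""
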