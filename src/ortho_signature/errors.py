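"""Exception hierarchy shared across the package."""


class OrthoSignatureError(Exception):
    """Base class for all package errors."""


class FormatError(OrthoSignatureError):
    """A file could not be parsed in its declared format."""


class ValidationError(OrthoSignatureError):
    """Input content violates a documented invariant."""


class LookupMissingError(OrthoSignatureError, KeyError):
    """A requested id (row, leaf, group) is absent from the container."""


class UndefinedDistanceError(OrthoSignatureError):
    """A pairwise distance is undefined (no shared residue columns)."""
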