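"""Exception hierarchy for the reaction-funnel package."""


class FunnelError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FunnelError):
    """A required column is missing or malformed in a SURF table."""


class ValidationError(FunnelError):
    """A record violates a field-level invariant (e.g. negative yield)."""


class StructureError(FunnelError):
    """A structure line notation (SMILES) failed to parse or sanitize."""


class UnsupportedAtomError(FunnelError):
    """An element outside the supported atom-type alphabet was encountered."""


class VocabularyError(FunnelError):
    """A categorical condition label is absent from the vocabulary."""


class ConformerError(FunnelError):
    """3D embedding failed after the documented retry policy."""


class SplitError(FunnelError):
    """A cross-validation split request cannot be satisfied."""


class EnumerationError(FunnelError):
    """Virtual product enumeration failed for a scaffold or acid."""


class SiteError(FunnelError):
    """No valid C-H alkylation site could be resolved on a scaffold."""


class RegistrationError(FunnelError):
    """Duplicate or invalid scorer registration."""


class EmptyInputError(FunnelError):
    """An operation requiring non-empty input received an empty one."""
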