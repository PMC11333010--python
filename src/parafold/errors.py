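"""Exception types shared across the package."""


class SchemaError(ValueError):
    """Malformed input: bad topology string, inconsistent record, length mismatch."""


class UnsupportedOrientationError(SchemaError):
    """A sheet record or topology string contains a non-parallel (down) strand."""


class ResourceLimitError(RuntimeError):
    """An exhaustive enumeration was requested beyond the configured size limit."""


class TemplateValidationError(ValueError):
    """A motif template set failed the frustration-verification checks."""


class CriterionRejection(Exception):
    """A domain sheet record failed one of the topology-extraction criteria.

    Attributes
    ----------
    criterion : str
        One of "i" (non-parallel pairing), "ii" (barrel), "iii" (multiple
        sheets), "iv" (inter-strand loop too long).
    """

    def __init__(self, criterion: str, message: str):
        self.criterion = criterion
        super().__init__(f"criterion {criterion}: {message}")


class DataError(ValueError):
    """A classification table violates its invariants (e.g. an empty F-group)."""
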