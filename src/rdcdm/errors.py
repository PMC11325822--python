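"""Exception hierarchy shared across the package."""


class RdcdmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RdcdmError):
    """A required resource/configuration item is missing or unusable."""


class CatalogValidationError(RdcdmError):
    """A bundled catalog row violates a type invariant.

    Carries enough context (file, row, field) to locate the offender.
    """

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | None = None, field: str | None = None) -> None:
        loc = ", ".join(f"{k}={v}" for k, v in
                        (("file", file), ("row", row), ("field", field)) if v is not None)
        super().__init__(f"{message} ({loc})" if loc else message)
        self.file = file
        self.row = row
        self.field = field


class BundleParseError(RdcdmError):
    """A bundle file does not match the expected delimited layout."""


class StoreIntegrityError(RdcdmError):
    """A relational constraint (PK/FK) was violated at insert time."""


class EtlOrderingError(RdcdmError):
    """An ETL stage ran before the stage it depends on."""
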