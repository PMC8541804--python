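"""Exception hierarchy shared across the package.

Every error a pipeline stage can raise maps onto one of the CLI exit
codes documented in :mod:`cladehouse.cli`.
"""


class CladehouseError(Exception):
    """Base class for all package errors."""


class ParseError(CladehouseError):
    """A source file (or a line/record of it) could not be interpreted."""

    def __init__(self, message: str, *, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class LocationParseError(ParseError):
    """A GenBank feature-location expression is outside the accepted grammar.

    ``kind`` distinguishes structural failures ("syntax", "nested_complement",
    "inverted_span") from the deliberate rejection of external-reference
    locations ("external_reference"), which callers count as warnings.
    """

    def __init__(self, message: str, *, kind: str = "syntax"):
        super().__init__(message)
        self.kind = kind


class TaxdumpError(ParseError):
    """Malformed taxdump line or inconsistent node/name tables."""


class OrganismNotFoundError(CladehouseError):
    """The queried organism name matched no taxon."""

    def __init__(self, query: str):
        super().__init__(f"organism not found: {query!r}")
        self.query = query


class IntegrityError(CladehouseError):
    """Duplicate natural key with conflicting payload, or a dangling FK."""


class SchemaError(CladehouseError):
    """The target store does not hold (or already holds) the expected schema."""


class ConfigurationError(CladehouseError):
    """The run configuration is missing or names an unknown source."""


class AcquisitionError(CladehouseError):
    """Required source files could not be obtained within the retry budget."""

    def __init__(self, missing: list[str]):
        super().__init__("missing after retries: " + ", ".join(sorted(missing)))
        self.missing = list(missing)


class SelectorError(CladehouseError):
    """An export selector did not match ``taxid:N``, ``go:GO:NNNNNNN`` or ``pfam:PFNNNNN``."""
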