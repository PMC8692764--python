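"""Exception hierarchy shared across the package.

Every error raised by oceanpack derives from :class:`OceanpackError` so
callers can catch the package's failures with a single except clause.
"""


class OceanpackError(Exception):
    """Base class for all oceanpack errors."""


class DescriptorParseError(OceanpackError):
    """Descriptor text is not well-formed JSON; carries the byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class SchemaError(OceanpackError):
    """Descriptor violates the data-package schema (missing/invalid key)."""


class CurieFormatError(OceanpackError):
    """String does not match the PREFIX:LOCALID compact-identifier shape."""


class UnsupportedNamespaceError(OceanpackError):
    """IRI does not live under the OBO PURL base, or a term's prefix is
    outside the namespace an operation requires."""


class MissingResourceError(OceanpackError):
    """A declared resource file could not be found or read."""


class HeaderMismatchError(OceanpackError):
    """Resource header row does not match the declared field names."""

    def __init__(self, message: str, expected=None, found=None):
        super().__init__(message)
        self.expected = list(expected or [])
        self.found = list(found or [])


class UnknownTermError(OceanpackError):
    """CURIE or label absent from the term graph."""


class AmbiguousTermError(OceanpackError):
    """A label resolves to more than one term."""

    def __init__(self, message: str, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)


class CyclicHierarchyError(OceanpackError):
    """The is-a hierarchy contains a cycle."""

    def __init__(self, message: str, cycle=()):
        super().__init__(message)
        self.cycle = list(cycle)


class DuplicateTermError(OceanpackError):
    """The same CURIE appears twice in a term table."""


class IncompatibleUnitsError(OceanpackError):
    """Conversion requested between units in disjoint dimension groups."""


class DuplicateSampleError(OceanpackError):
    """The same sample identifier occurs twice within one resource."""


class ColumnError(OceanpackError):
    """An attribute/column referenced by a query or filter does not exist,
    or a predicate on it is self-contradictory."""


class DegenerateInputError(OceanpackError):
    """Statistical input is degenerate (constant predictor, empty matrix,
    undefined distance, ...)."""


class ParameterError(OceanpackError):
    """Invalid or contradictory generator/analysis parameters."""
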