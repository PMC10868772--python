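"""Exception hierarchy for leaftda.

Errors are grouped by the contract they violate so callers can catch a
whole family (``LeafTDAError``) or a specific failure mode.
"""


class LeafTDAError(Exception):
    """Base class for all leaftda errors."""


class SchemaError(LeafTDAError):
    """A table or dataset does not match the declared landmark scheme."""


class IntegrityError(LeafTDAError):
    """Duplicate identifiers or otherwise inconsistent metadata."""


class ParseError(LeafTDAError):
    """A value in an input table could not be parsed."""


class GeometryError(LeafTDAError):
    """A geometric precondition is violated (degenerate shape, coincident axis)."""


class StateError(LeafTDAError):
    """An operation was called before a required annotation was assigned."""


class InsufficientDataError(LeafTDAError):
    """Too few observations (or classes) for the requested computation."""


class DegenerateRangeError(LeafTDAError):
    """A lens has zero range but more than one cover interval was requested."""


class EmptyResultError(LeafTDAError):
    """A filtering operation removed everything."""
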