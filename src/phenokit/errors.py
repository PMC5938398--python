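"""Exception hierarchy shared across the toolkit.

All phenokit errors derive from :class:`PhenokitError` so callers can catch
one base class; data-level problems (bad rows, unmapped codes) are reported
as data, not raised, and do not appear here.
"""


class PhenokitError(Exception):
    """Base class for all phenokit exceptions."""


class CatalogError(PhenokitError):
    """Base class for trait-catalog construction and lookup failures."""


class DuplicateTermError(CatalogError):
    """A term identifier was declared more than once."""


class UnresolvedReferenceError(CatalogError):
    """A subclass/parthood/trait link points at an undeclared term."""


class CycleError(CatalogError):
    """The structure subclass graph contains a cycle."""


class AlreadyDerivedError(CatalogError):
    """Presence classes were already derived for this catalog."""


class UnknownTermError(CatalogError, KeyError):
    """A term or presence-class id is not in the catalog."""


class RangeError(PhenokitError, ValueError):
    """A measurement range violates its bounds (lower > upper, negative
    values, percent outside [0, 100], fractional counts)."""


class SchemaError(PhenokitError):
    """An input file is missing a mandatory column."""


class InsufficientDataError(PhenokitError, ValueError):
    """Too few values for the requested statistic (e.g. bandwidth at n < 2)."""


class DegenerateDataError(PhenokitError, ValueError):
    """All values identical: no spread to estimate a bandwidth from."""


class ParameterError(PhenokitError, ValueError):
    """Simulation parameters are invalid or mutually infeasible."""
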