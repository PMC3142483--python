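"""Exception hierarchy.

Every error raised on bad scientific input derives from :class:`AomQuantError`
and from :class:`ValueError`, so callers may catch either.
"""


class AomQuantError(ValueError):
    """Base class for all aomquant input/validation errors."""


class InvalidInputError(AomQuantError):
    """A numeric argument violates its precondition (negative diameter, ...)."""


class InvalidGeometryError(AomQuantError):
    """Microscope/filtration geometry is unusable (zero areas or volume)."""


class SchemaError(AomQuantError):
    """A table is missing columns or contains rows the schema forbids."""


class DataIntegrityError(AomQuantError):
    """Internally inconsistent data, e.g. probe-positive counts exceeding DAPI."""


class UndefinedFractionError(AomQuantError):
    """A probe fraction is requested where the DAPI denominator is all zero."""


class UndefinedBaselineError(AomQuantError):
    """A relative increase is requested with a zero baseline biovolume."""


class NoGrowthError(AomQuantError):
    """A doubling time is requested where the biovolume did not increase."""


class NotApplicableError(AomQuantError):
    """A detection bound is requested although positives were observed."""


class MappingError(AomQuantError):
    """No shared group labels between two composition tables."""
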