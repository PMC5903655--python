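"""Exception hierarchy shared by all hbcube modules.

Every anticipated failure mode raises a subclass of :class:`HbcubeError`
so callers (and the CLI) can distinguish pipeline errors from bugs.
"""


class HbcubeError(Exception):
    """Base class for all hbcube errors."""


class InvalidParameterError(HbcubeError, ValueError):
    """A numeric parameter violates its domain (e.g. non-positive P50)."""


class InsufficientDataError(HbcubeError, ValueError):
    """Too few data points to attempt a fit."""


class DegenerateDataError(HbcubeError, ValueError):
    """Data carry no usable signal (e.g. constant trace/curve)."""


class NoDataError(HbcubeError, ValueError):
    """An aggregation was requested over an empty collection."""


class MissingDataError(HbcubeError, KeyError):
    """A required genotype/taxon/trait row is absent from a table."""


class InvalidSitesError(HbcubeError, ValueError):
    """Site definitions are malformed (duplicates, bad states...)."""


class InvalidSiteStateError(HbcubeError, ValueError):
    """A genotype's state at a site is inconsistent with the request."""


class SizeLimitError(HbcubeError, ValueError):
    """Requested enumeration would be combinatorially explosive."""


class MissingTaxonError(MissingDataError):
    """A tree tip has no row in the site-state matrix."""


class UnresolvedStateError(HbcubeError, ValueError):
    """An ancestral state query hit an ambiguous (multi-state) node."""


class UndefinedCorrelationError(HbcubeError, ValueError):
    """Correlation undefined (zero variance in a coordinate)."""


class ConfigError(HbcubeError, ValueError):
    """Invalid or unknown configuration."""


class ParseError(HbcubeError, ValueError):
    """Malformed input file; message carries file/line context."""
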