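"""Exception hierarchy shared across the package."""


class PhyloconflictError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(PhyloconflictError):
    """Malformed newick / extended-newick input."""


class SpeciesMappingError(PhyloconflictError):
    """A tip could not be assigned to a species."""


class MissingSpeciesError(PhyloconflictError):
    """A query names species absent from the tree."""


class RootingError(PhyloconflictError):
    """Outgroup rooting is impossible (no outgroup tips, or nothing else)."""


class NetworkError(PhyloconflictError):
    """Invalid species network (bad inheritance probabilities, cycles, ...)."""


class InsufficientDataError(PhyloconflictError):
    """Too few observations for a fit or a resampling scheme."""


class DegenerateDataError(PhyloconflictError):
    """All observations identical (typically all zero) -- no fit possible."""


class UndefinedStatisticError(PhyloconflictError):
    """The requested statistic has an empty denominator (e.g. no informative sites)."""


class SaturationError(PhyloconflictError):
    """Synonymous divergence beyond the correctable range (pS >= 0.75)."""


class FamilySizeError(PhyloconflictError):
    """Gene family outside the low-copy filter (membership must satisfy 1 < n < 5)."""
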