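"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`VitivarError`, so callers can catch one type at pipeline
boundaries. Subclasses distinguish bad configuration from bad data
from degenerate analysis requests.
"""


class VitivarError(Exception):
    """Base class for all errors raised by vitivar."""


class ConfigurationError(VitivarError):
    """Invalid parameter values or inconsistent configuration."""


class DataError(VitivarError):
    """Malformed or physically impossible input data."""


class ClassificationError(VitivarError):
    """A site's declared variant class contradicts its alleles, or a
    classification input (e.g. an association result) is missing."""


class ComparisonError(VitivarError):
    """Two call sets cannot be compared (e.g. disjoint sample sets)."""


class ValidationError(VitivarError):
    """Truth-set validation is undefined (e.g. empty denominator)."""


class RegionError(VitivarError):
    """A genomic region query selects no usable sites."""


class PhenotypeError(VitivarError):
    """A phenotype cannot be determined from the supplied genotypes."""


class DesignError(VitivarError):
    """A statistical design is degenerate (e.g. single-class phenotype)."""
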