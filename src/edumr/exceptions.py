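"""Exception hierarchy: configuration, data, and estimation failures are distinct."""


class EdumrError(Exception):
    """Base class for package errors."""


class ConfigurationError(EdumrError):
    """Invalid or inconsistent configuration values."""


class DataError(EdumrError):
    """Input data violate a precondition (missing columns, empty cells...)."""


class DegenerateSampleError(DataError):
    """An operation removed or required rows that are not there."""


class HarmonizationError(EdumrError):
    """A GWAS record cannot be reconciled with the genotype panel."""


class EstimationError(EdumrError):
    """An estimator could not be computed."""


class DegenerateInstrumentError(EstimationError):
    """Instrument is constant / has no (within-family) variance."""


class RankDeficiencyError(EstimationError):
    """Design matrix is rank deficient (collinear columns)."""


class InsufficientInstrumentsError(EstimationError):
    """Too few SNPs/instruments for the requested estimator."""


class UndefinedStatisticError(EstimationError):
    """A statistic is undefined for the given inputs (e.g. < 2 points for a correlation)."""
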