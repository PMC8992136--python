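"""Exception hierarchy shared across the package."""


class MetspathError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MetspathError, ValueError):
    """Invalid generator or pipeline configuration."""


class SchemaError(MetspathError, ValueError):
    """Cohort table does not match the documented CSV schema."""


class EmptyCohortError(SchemaError):
    """Cohort file or table contains no subjects."""


class SpecificationError(MetspathError, ValueError):
    """Path-model specification is structurally invalid (cycles, undeclared variables...)."""


class CollinearityError(MetspathError, ValueError):
    """A parent set is rank-deficient / numerically collinear."""


class DegenerateDataError(MetspathError, ValueError):
    """Data degenerate for the requested statistic (constant input, zero variance)."""


class EstimabilityError(MetspathError, ValueError):
    """Factorial design cannot be estimated (empty cell)."""


class ClassificationError(MetspathError, ValueError):
    """Subject record cannot be classified (unknown sex code, invalid values)."""
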