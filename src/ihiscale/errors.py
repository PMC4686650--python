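"""Exception taxonomy shared across the package.

The hierarchy mirrors the CLI exit-code contract: configuration problems
(exit 1), data-validation problems (exit 2) and statistically degenerate
inputs (exit 3).
"""


class IhiScaleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IhiScaleError):
    """Invalid configuration value (bad bin edges, unnormalized probabilities...)."""


class DataValidationError(IhiScaleError):
    """Input data violates a schema or an invariant (off-grid grade, duplicate key...)."""


class SchemaError(DataValidationError):
    """A table is missing required columns or has an unusable header."""


class InvalidGeometryError(DataValidationError):
    """Geometric observation outside its physical domain (non-positive length...)."""


class NotApplicableError(DataValidationError):
    """Observation combination the grading tables declare impossible (flat + vertical)."""


class IncompleteAssessmentError(DataValidationError):
    """A composite quantity was requested from a record with missing grades."""


class DegenerateInputError(IhiScaleError):
    """Statistic undefined for this input (single-class labels, zero marginal...)."""


class UndefinedKappaError(DegenerateInputError):
    """Chance agreement equals 1 (both raters constant and identical)."""
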