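"""Exception hierarchy used across the package."""


class CoxDistError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CoxDistError):
    """A required column is missing from an input table."""


class ValidationError(CoxDistError):
    """Input values violate a precondition (shapes, signs, ranges)."""


class ConfigurationError(CoxDistError):
    """An unknown family tag or invalid distribution/network parameters."""


class FitError(CoxDistError):
    """A maximum-likelihood fit is degenerate or failed to converge."""


class TrainingError(CoxDistError):
    """Network training cannot proceed (no events, non-finite loss, ...)."""
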