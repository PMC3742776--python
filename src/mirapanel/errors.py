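"""Exception taxonomy shared across the package."""


class MirapanelError(Exception):
    """Base class for all package errors."""


class SchemaError(MirapanelError):
    """A required column is missing from an input table."""


class ValidationError(MirapanelError):
    """A cell-level validation failure (missing/non-numeric/out-of-range)."""


class CodingError(ValidationError):
    """A binary flag is outside {0, 1}."""


class ConfigError(MirapanelError):
    """Invalid configuration value."""


class InputError(MirapanelError):
    """Malformed input to a computation."""


class FitError(MirapanelError):
    """Base class for model-fitting failures."""


class DegenerateOutcomeError(FitError):
    """Outcome vector contains a single class."""


class CollinearityError(FitError):
    """Design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design matrix; dependent columns: {self.columns}")


class SeparationError(FitError):
    """Quasi-complete separation detected in logistic regression."""


class ConvergenceError(FitError):
    """Optimizer failed to converge."""


class NonIdentifiableError(FitError):
    """Likelihood cannot identify the parameters (e.g. all observations censored)."""


class SelectionError(MirapanelError):
    """No successful candidate model to select from."""
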