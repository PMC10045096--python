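"""Exception and warning types shared across the pipeline."""


class GaitdxError(Exception):
    """Base class for all gaitdx errors."""


class ConfigError(GaitdxError):
    """A configuration value is outside its admissible range."""


class SchemaError(GaitdxError):
    """Input data does not match the expected column/signal layout."""


class InvalidSubjectError(GaitdxError):
    """A subject record violates its invariants (e.g. non-positive mass)."""


class TooShortTrialError(GaitdxError):
    """A trial has fewer than two samples and cannot be resampled."""


class SingularDesignError(GaitdxError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, collinear_columns=None):
        super().__init__(message)
        self.collinear_columns = list(collinear_columns or [])


class InfeasibleProblemError(GaitdxError):
    """No muscle-force vector satisfies equilibrium within the strength bounds."""

    def __init__(self, message: str, violation: float | None = None):
        super().__init__(message)
        self.violation = violation


class GaitdxWarning(UserWarning):
    """Base class for gaitdx warnings."""


class DegenerateSignalWarning(GaitdxWarning):
    """A waveform is (numerically) all zero or has zero variance."""


class NegativeFlexionWarning(GaitdxWarning):
    """Knee flexion contains negative (hyperextension) values."""
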