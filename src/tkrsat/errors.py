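"""Exception hierarchy shared across the package."""


class TkrsatError(Exception):
    """Base class for all package-specific errors."""


class CodingError(TkrsatError, ValueError):
    """An input value does not belong to the variable's legal categories."""


class SchemaError(TkrsatError, KeyError):
    """A required column is absent from an input table."""


class InputValidationError(TkrsatError, ValueError):
    """A field value is outside its legal range."""


class DegenerateScaleError(TkrsatError, ValueError):
    """Score standardisation is impossible (constant or near-empty column)."""


class ParameterError(TkrsatError, ValueError):
    """An operation parameter (rate, count, threshold) is out of range."""


class ImputationError(TkrsatError):
    """Chained-equation imputation cannot proceed."""


class PoolingError(TkrsatError, ValueError):
    """Per-imputation fits are incompatible and cannot be pooled."""


class FitError(TkrsatError):
    """Logistic maximum-likelihood fitting failed."""


class SeparationError(FitError):
    """Complete or quasi-complete separation prevented convergence."""


class PredictionError(TkrsatError, ValueError):
    """A row lacks a predictor required by the model."""


class UndefinedAUCError(TkrsatError, ValueError):
    """Discrimination is undefined because only one outcome class is present."""


class ValidationRunError(TkrsatError):
    """Too many bootstrap validation replicates failed."""


class TransportError(TkrsatError, ValueError):
    """The external cohort is missing a predictor of the frozen model."""


class ReestimationError(TkrsatError):
    """Re-estimation failed on too many imputed datasets."""


class ConfigError(TkrsatError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class StageError(TkrsatError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed" + (f": {message}" if message else ""))
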