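"""Exception hierarchy shared across the package."""


class AblmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AblmError):
    """A configuration object is internally inconsistent or incomplete."""


class TokenizationError(AblmError):
    """An input sequence contains characters outside the vocabulary."""


class LengthError(AblmError):
    """A token stream exceeds the fixed model input length."""


class CalibrationError(AblmError):
    """A schedule target is unattainable for the given curve parameters."""


class SamplingError(AblmError):
    """A batch plan requested examples from an empty pool."""


class SplitError(AblmError):
    """A dataset is too small to split as requested."""


class EvaluationError(AblmError):
    """An evaluation was requested on a dataset without the required labels."""


class TaskError(AblmError):
    """A downstream-task dataset cannot be constructed as requested."""


class DivergenceError(AblmError):
    """Training produced a non-finite loss."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite loss at step {step}")
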