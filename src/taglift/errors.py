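"""Exception hierarchy shared across the pipeline stages."""


class TagliftError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TagliftError, ValueError):
    """Invalid configuration or degenerate generator parameters."""


class ImbalanceError(TagliftError):
    """Negative pool too small to balance positives without replacement."""


class TrainingError(TagliftError):
    """Classifier training received unusable input (e.g. a single class)."""


class ContractViolationError(TagliftError):
    """A classifier adapter returned a probability outside [0, 1]."""


class CoverageError(TagliftError):
    """Predictions do not cover every tweet exactly once."""


class DegenerateTableError(TagliftError):
    """A 2x2 table has a zero marginal; the chi-square p is undefined."""


class GeometryError(TagliftError):
    """An area polygon failed validation at load time."""


class DegenerateInputError(TagliftError):
    """A statistic is undefined on this input (e.g. a constant vector)."""


class CollinearityError(TagliftError):
    """Rank-deficient regression design."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; dependent columns: {self.columns}"
        )


class ConfigurationError(TagliftError):
    """Pipeline configuration is inconsistent or inputs are missing."""
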