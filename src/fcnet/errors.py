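"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`FcnetError` so callers can catch
pipeline failures without masking programming errors.
"""


class FcnetError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(FcnetError):
    """Invalid analysis configuration."""


class FormatError(FcnetError):
    """Malformed input file (ragged rows, bad delimiter, ...)."""


class ParseError(FormatError):
    """A cell could not be parsed as the expected type."""


class DimensionError(FcnetError):
    """Input has too few rows/columns for the requested operation."""


class ManifestError(FcnetError):
    """Invalid subject manifest (duplicate IDs, unknown group labels)."""


class SpecError(FcnetError):
    """Invalid synthetic ground-truth specification."""


class NumericError(FcnetError):
    """Numerically invalid input (e.g. non-PSD covariance)."""


class ParameterError(FcnetError):
    """Invalid parameter for a reference-graph construction."""


class DegenerateSignalError(FcnetError):
    """A region's time series has zero variance."""


class ThresholdError(FcnetError):
    """Sparsity threshold produces no edges."""


class InfeasibleSparsityError(ThresholdError):
    """Not enough positive correlations to reach the requested sparsity."""

    def __init__(self, message: str, max_sparsity: float):
        super().__init__(message)
        self.max_sparsity = max_sparsity


class UndefinedMetricError(FcnetError):
    """Metric undefined on this graph (e.g. path length with no finite pairs)."""


class UndefinedNormalizationError(FcnetError):
    """Null-ensemble mean is zero; normalized coefficient undefined."""


class LabelError(FcnetError):
    """A region label is unknown to the graph at hand."""


class InsufficientDataError(FcnetError):
    """Too few complete observations for the requested statistic."""


class DegenerateStatisticError(FcnetError):
    """Test statistic undefined (zero pooled variance)."""


class MissingInputError(FcnetError, LookupError):
    """A manifest subject has no readable time-series file."""


class StageError(FcnetError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage
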