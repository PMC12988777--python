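"""Exception hierarchy for alerteval.

All package errors derive from :class:`AlertEvalError` so callers can catch
one base class; subclasses mirror the failure modes of each pipeline stage.
"""


class AlertEvalError(Exception):
    """Base class for all alerteval errors."""


class SchemaError(AlertEvalError):
    """An input table is missing a required column or has the wrong layout."""


class DataValidationError(AlertEvalError):
    """An input table violates a data-model invariant (bad value, duplicate row...)."""


class ConfigError(AlertEvalError):
    """A configuration object is internally inconsistent or degenerate."""


class DegenerateAggregationError(AlertEvalError):
    """An area-weighted aggregation has no usable (weight > 0, non-missing) cells."""


class InsufficientDataError(AlertEvalError):
    """Too few usable rows to fit or evaluate a model."""


class ModelSelectionError(AlertEvalError):
    """Every candidate learner failed during baseline model selection."""


class FeatureSchemaError(AlertEvalError):
    """Prediction-time features do not match the schema the model was trained on."""


class DegenerateMetricError(AlertEvalError):
    """A skill metric is undefined (e.g. zero-variance denominator)."""


class InsufficientReferenceError(AlertEvalError):
    """Fewer reference days than the configured minimum for a correction factor."""


class DegeneratePredictionError(AlertEvalError):
    """Non-positive predictions where a ratio or percentage requires positivity."""


class MappingError(AlertEvalError):
    """A city cannot be resolved in the population/province table."""


class AlignmentError(AlertEvalError):
    """Two series that must share an index (city, day) do not align."""
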