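"""Exception hierarchy for the panel pipeline.

Every error raised by this package derives from :class:`PanelError`, so
callers can catch pipeline failures without masking programming errors.
"""


class PanelError(Exception):
    """Base class for all errors raised by mspanel."""


class SchemaError(PanelError):
    """A tabular input is missing required columns or has wrong dtypes."""


class ValidationError(PanelError):
    """Row-level invariants of an input table are violated."""


class ParameterError(PanelError):
    """A function argument is outside its documented domain."""


class ConfigError(PanelError):
    """A configuration object is internally inconsistent."""


class NormalizationError(PanelError):
    """Bridge normalization cannot be carried out (e.g. bridge-free batch)."""


class AlignmentError(PanelError):
    """Sample or protein identifiers of two objects do not match."""


class FitError(PanelError):
    """A model fit failed structurally (rank deficiency, no convergence)."""


class InsufficientDataError(PanelError):
    """Too few samples in a class or reference set for the requested fit."""


class EmptyLabelingError(PanelError):
    """No sample carries the annotation needed for the requested endpoint."""


class UndefinedStatisticError(PanelError):
    """The requested statistic is undefined on this input (constant vector,
    single-class labeling, ...)."""


class DegenerateImportanceError(PanelError):
    """An importance vector is identically zero and cannot be normalized."""


class PlanningError(PanelError):
    """A bootstrap plan cannot satisfy its class-presence invariant."""


class StageError(PanelError):
    """A pipeline stage failed or a required upstream artifact is missing."""
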