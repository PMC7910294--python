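"""Exception hierarchy for the screen pipeline."""


class ScreenError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(ScreenError):
    """A required column is missing or unparseable in an input table."""


class IntegrityError(ScreenError):
    """A dataset invariant is violated (duplicate wells, bad roles, ...)."""


class ControlCoverageError(ScreenError):
    """A plate lacks the control wells required for normalization / QC."""


class NormalizationError(ScreenError):
    """Plate normalization cannot be performed (no reference wells)."""


class DegenerateControlError(NormalizationError):
    """Reference wells exist but carry no usable signal."""


class DegenerateCurveError(ScreenError):
    """Dose-response data are too flat to define a logistic curve."""


class FitError(ScreenError):
    """Nonlinear least squares failed to converge."""


class InsufficientReplicatesError(ScreenError):
    """A compound or control group has too few replicate wells."""


class ConfigError(ScreenError):
    """Invalid simulator or pipeline configuration."""
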