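"""Exception hierarchy shared across the package."""


class MangoRipenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MangoRipenError):
    """Input data violates a documented precondition or schema."""


class SchemaError(ValidationError):
    """A tabular file or serialized document does not match its schema."""


class UndefinedHueError(ValidationError):
    """Hue angle requested for the colourless point a* = b* = 0."""


class BaselineError(ValidationError):
    """A harvest baseline X_p(0) is missing or non-positive."""


class CollinearityError(MangoRipenError):
    """Design matrix is rank deficient.

    ``columns`` names the predictors involved in the dependency.
    """

    def __init__(self, columns, message=None):
        self.columns = tuple(columns)
        super().__init__(
            message or f"collinear predictor column(s): {', '.join(self.columns)}"
        )


class LeakageError(MangoRipenError):
    """Calibration and validation sets share fruit identifiers."""


class DegenerateVarianceError(MangoRipenError):
    """All groups have zero within-group variance; Tukey HSD undefined."""


class IntegrityError(MangoRipenError):
    """A published-model fixture fails its internal consistency check."""
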