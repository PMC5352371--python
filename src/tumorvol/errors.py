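"""Exception hierarchy shared across the package."""


class TumorvolError(Exception):
    """Base class for all package-specific errors."""


class EmptyMaskError(TumorvolError):
    """A feature operation was attempted on a mask with no foreground voxels."""


class ParameterError(TumorvolError, ValueError):
    """An operation received a parameter outside its valid domain."""


class DegenerateShapeError(TumorvolError):
    """A phantom specification would digitize to a shape thinner than one voxel."""


class ConfigurationError(TumorvolError):
    """Required configuration (e.g. dose-response coefficients) is missing or invalid."""


class SchemaError(TumorvolError):
    """A cohort table is missing required columns or contains invalid rows."""


class SeparationError(TumorvolError):
    """Complete or quasi-complete separation in a logistic fit."""


class DegenerateStatisticError(TumorvolError):
    """A statistic is undefined on the given input (zero variance, constant ratings...)."""
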