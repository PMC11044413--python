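"""Exception hierarchy shared across the package."""


class CompartDWIError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CompartDWIError, ValueError):
    """An argument violates a documented precondition."""


class UnfittableVoxelError(CompartDWIError):
    """The voxel signal cannot support the requested fit (e.g. S0 <= 0)."""


class UnfittableROIError(CompartDWIError):
    """An ROI contains no usable voxels."""


class UndefinedMetricError(CompartDWIError):
    """A metric is undefined for the given inputs (e.g. two empty masks)."""


class ConfigurationError(CompartDWIError):
    """A pipeline / phantom configuration is internally inconsistent."""


class StratificationError(CompartDWIError):
    """Cross-validation folds cannot be stratified with the given labels."""
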