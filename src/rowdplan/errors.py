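"""Exception hierarchy shared across the toolkit."""


class RowdPlanError(Exception):
    """Base class for all toolkit errors."""


class DomainError(RowdPlanError, ValueError):
    """An input is outside the physical domain of a model (e.g. negative pO2)."""


class ConfigurationError(RowdPlanError, ValueError):
    """A parameter set, model spec or run configuration is invalid."""


class AlignmentError(RowdPlanError, ValueError):
    """Two voxel grids do not share dims/spacing/origin."""


class ValidationError(RowdPlanError, ValueError):
    """An on-disk artifact failed schema validation."""


class UnsupportedFormatError(RowdPlanError, ValueError):
    """A file is readable but not in a supported layout (e.g. 4-D NIfTI)."""
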