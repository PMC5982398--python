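"""Exception hierarchy shared across the package."""


class EmofusionError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EmofusionError):
    """A value violates a documented domain invariant (e.g. rating outside [1, 9])."""


class ConfigurationError(EmofusionError):
    """A configuration object is internally inconsistent or incompatible with the data."""


class InputError(EmofusionError):
    """An input array is degenerate or too small for the requested operation."""


class FormatError(EmofusionError):
    """An on-disk artifact does not have the expected layout."""


class DatasetIncompleteError(EmofusionError):
    """A multi-file dataset is missing one or more subject files."""


class ShapeError(EmofusionError):
    """A tensor shape mismatch inside the model; names the offending layer."""


class DivergenceError(EmofusionError):
    """Training produced non-finite gradients or losses."""


class LeakageError(EmofusionError):
    """Train and test partitions share (subject, video) trials."""


class MissingArtifactError(EmofusionError):
    """A pipeline stage was invoked before its upstream artifact exists."""
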