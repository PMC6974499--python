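"""Exception hierarchy for the SSM-PCA pipeline."""


class SSMPCAError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(SSMPCAError, ValueError):
    """Shapes, grids, affines or voxel orderings do not agree."""


class DegenerateMaskError(SSMPCAError, ValueError):
    """A brain mask selects no voxels."""


class DegenerateDataError(SSMPCAError, ValueError):
    """Data carry no usable signal (zero residuals, zero variance, <2 subjects)."""


class ConfigurationError(SSMPCAError, ValueError):
    """Invalid run configuration (bad threshold, missing reference controls, ...)."""
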