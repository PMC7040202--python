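"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError -> 2,
MissingArtifactError -> 3, everything else -> 1.
"""


class CTRadiomicsError(Exception):
    """Base class for all package errors."""


class ValidationError(CTRadiomicsError):
    """Invalid input data or configuration."""


class FormatError(ValidationError):
    """A file could not be read in the expected on-disk format."""


class GridMismatchError(ValidationError):
    """Image and mask are not on the same voxel grid."""


class EmptyVOIError(ValidationError):
    """A mask intended as a volume of interest has no foreground voxels."""


class ExtractionError(CTRadiomicsError):
    """A feature family failed to compute."""


class FittingError(CTRadiomicsError):
    """A statistical model could not be fitted."""


class MissingArtifactError(CTRadiomicsError):
    """A pipeline stage requires an output of an earlier stage."""
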