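"""Exception hierarchy.

Errors are grouped so the CLI can map them to distinct exit codes:
configuration problems (bad flags, inconsistent label maps), data problems
(unreadable files, empty structures), and computation failures (a method
produced no valid measurement).
"""


class CartithickError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CartithickError):
    """Inconsistent or invalid configuration (label maps, region references)."""


class DataError(CartithickError):
    """Problems with input data."""


class FormatError(DataError):
    """File not readable in the requested dialect."""


class MetadataError(DataError):
    """Required metadata (e.g. voxel spacing) missing from a file header."""


class EmptyStructureError(DataError):
    """A structure expected to be non-empty contains no voxels."""


class TooSmallError(DataError):
    """A cartilage plate is too small to parcellate."""


class ComputationError(CartithickError):
    """A measurement method failed to produce any output."""


class MeshError(ComputationError):
    """Surface mesh could not be constructed (degenerate point set)."""


class MethodFailureError(ComputationError):
    """A thickness method yielded zero valid samples."""


class PairingError(CartithickError):
    """Paired statistics called with mismatched series."""


class InsufficientDataError(CartithickError):
    """Cohort too small for the requested statistical analysis."""
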