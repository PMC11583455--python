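"""Exception hierarchy shared across the package."""


class BlisterflowError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(BlisterflowError):
    """Degenerate or self-intersecting geometry."""


class MaskError(BlisterflowError):
    """Invalid or empty projection mask."""


class ReconstructionError(BlisterflowError):
    """Reconstruction cannot proceed with the given inputs."""


class DegenerateViewsError(ReconstructionError):
    """The two views are parallel (theta = 0): depths are unobservable."""


class VoxelizationError(BlisterflowError):
    """Surface cannot be voxelized consistently (leaky / unlabeled caps)."""


class OscillatoryConvergenceError(BlisterflowError):
    """Mesh-refinement QoI sequence is non-monotone; the observed order of
    convergence is undefined."""


class PipelineError(BlisterflowError):
    """A pipeline stage failed; the stage name is included in the message."""
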