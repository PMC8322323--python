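"""Exception types shared across the simulator."""


class CtcsimError(Exception):
    """Base class for all ctcsim errors."""


class InvalidStateError(CtcsimError):
    """A physical field violates its invariants (e.g. non-positive density)."""


class StabilityError(CtcsimError):
    """Requested parameters would drive the lattice scheme unstable."""


class ConfigurationError(CtcsimError):
    """Inconsistent or incomplete scenario / solver configuration."""


class ParameterError(CtcsimError):
    """An operation received a parameter outside its supported range."""


class OutOfDomainError(CtcsimError):
    """A Lagrangian vertex left the fluid domain."""


class CFLViolationError(CtcsimError):
    """A vertex moved more than half a lattice spacing in one step."""


class DegenerateGeometryError(CtcsimError):
    """Mesh or point cloud is too degenerate for the requested computation."""


class ConvergenceError(CtcsimError):
    """An iterative solver failed to reach its residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class PlacementError(CtcsimError):
    """Cells could not be placed without overlap."""


class CheckpointError(CtcsimError):
    """Checkpoint file is missing, corrupt, or version-incompatible."""
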