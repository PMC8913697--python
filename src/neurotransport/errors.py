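"""Exception hierarchy shared across the package."""


class NeurotransportError(Exception):
    """Base class for all package errors."""


class SWCParseError(NeurotransportError, ValueError):
    """A malformed SWC record (carries the offending line number)."""


class SkeletonError(NeurotransportError, ValueError):
    """Structural problem with a skeleton (multiple roots, cycles, ...)."""


class GeometrySpecError(NeurotransportError, ValueError):
    """Inconsistent synthetic-geometry specification."""


class MeshingError(NeurotransportError, RuntimeError):
    """Sweeping failed (self-intersecting tube, degenerate junction, ...)."""


class ConfigurationError(NeurotransportError, ValueError):
    """Inconsistent run configuration (mode/field mismatch and friends)."""


class SolverError(NeurotransportError, RuntimeError):
    """A linear or nonlinear solve failed irrecoverably."""
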