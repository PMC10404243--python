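"""Exception hierarchy for stlgcp."""


class StlgcpError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(StlgcpError):
    """Window polygon is self-intersecting, empty or otherwise unusable."""


class MeshResourceError(StlgcpError):
    """A requested mesh would exceed the configured vertex cap."""


class AssemblyError(StlgcpError):
    """Finite-element assembly failed (e.g. degenerate triangle)."""


class PointLocationError(StlgcpError):
    """A point could not be located inside any mesh triangle."""

    def __init__(self, message: str, point_index: int | None = None):
        super().__init__(message)
        self.point_index = point_index


class DomainError(StlgcpError, ValueError):
    """A parameter lies outside its mathematically valid domain."""


class SizeError(StlgcpError, ValueError):
    """A dimension (number of periods, categories, ...) is too small."""


class NotPositiveDefiniteError(StlgcpError):
    """A matrix expected to be SPD failed to factorise."""


class SpecError(StlgcpError, ValueError):
    """Inconsistent or incomplete model specification."""


class SchemaError(StlgcpError, ValueError):
    """An input file does not match its documented schema."""


class ConvergenceError(StlgcpError):
    """An iterative procedure failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class FitError(StlgcpError):
    """Hyperparameter optimisation failed; carries the optimiser trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class ResourceError(StlgcpError):
    """A simulation or computation would exceed a configured resource cap."""


class EmptyPatternError(StlgcpError, ValueError):
    """An event set is empty where at least one event is required."""


class RangeError(StlgcpError, ValueError):
    """Dates or periods fall outside the declared study range."""
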