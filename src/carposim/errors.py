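"""Exception hierarchy shared across the package."""


class CarposimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CarposimError, ValueError):
    """A numeric parameter is outside its valid domain."""


class TopologyError(CarposimError, ValueError):
    """A mesh does not satisfy the topological preconditions (e.g. not closed)."""


class MeshFormatError(CarposimError, ValueError):
    """A mesh file could not be parsed.

    ``byte_offset`` is a best-effort position of the failure in the file
    (0 when unknown).
    """

    def __init__(self, message: str, byte_offset: int = 0):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset


class GeometryError(CarposimError, ValueError):
    """Degenerate geometric configuration (coincident points, self-intersection)."""


class AssemblyError(CarposimError, ValueError):
    """The multibody model cannot be assembled from the given components."""


class InputError(CarposimError, ValueError):
    """A signal or table input violates its contract."""


class DetectionError(CarposimError, RuntimeError):
    """An event-detection routine found no events."""


class IntegrationError(CarposimError, RuntimeError):
    """Numerical integration diverged (NaN in state)."""
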