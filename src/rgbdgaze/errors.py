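"""Error taxonomy shared across the package.

Geometric degeneracies (collapsed landmarks, collinear points) are
distinguished from plain invalid inputs and from recoverable per-frame
failures so that the pipeline can degrade gracefully instead of aborting
a whole stream.
"""


class RgbdGazeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RgbdGazeError, ValueError):
    """An argument is out of its documented domain (zero vector, depth <= 0, ...)."""


class DegenerateGeometryError(RgbdGazeError, ValueError):
    """A geometric construction is undefined (collinear points, collapsed chord, ...)."""


class RecoveryFailedError(RgbdGazeError, RuntimeError):
    """Rigid-body joint recovery is underdetermined (< 3 valid joints or collinear support)."""


class InvalidFrameError(RgbdGazeError, RuntimeError):
    """A frame has no usable head estimate (unrecovered invalid joints)."""


class InputOrderError(RgbdGazeError, ValueError):
    """A frame stream violates per-person timestamp monotonicity."""


class DataFormatError(RgbdGazeError, ValueError):
    """A file does not conform to the expected schema; carries a location hint."""

    def __init__(self, message: str, *, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += str(path)
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class EmptyInputError(RgbdGazeError, ValueError):
    """An operation that needs at least one element received none."""
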