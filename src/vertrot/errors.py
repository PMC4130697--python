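"""Exception hierarchy.

The CLI maps these onto distinct exit codes (parse / validation / geometry),
so library code should raise the most specific class that applies.
"""


class VertrotError(Exception):
    """Base class for all package errors."""


class ParseError(VertrotError):
    """A landmark or config file could not be parsed.

    Carries ``line`` (1-based) when the underlying parser reports one.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(VertrotError):
    """Parsed input violates a landmark-set invariant."""


class MissingLandmarkError(ValidationError):
    """A pedicle reference point is absent and no fallback flag explains it."""


class UnmeasurableError(ValidationError):
    """No measurement is possible (e.g. both pedicle shadows missing)."""


class GeometryError(VertrotError):
    """A geometric construction failed on otherwise-valid input."""


class DegenerateGeometryError(GeometryError):
    """Parallel diagonals, zero area, or an intersection far outside the
    configured extension range."""
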