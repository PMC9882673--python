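"""Exception hierarchy.

Every error raised by the library derives from :class:`NucarrayError` so that
callers (and the CLI) can catch the package's failures in one place.
"""


class NucarrayError(Exception):
    """Base class for all nucarray errors."""


class SchemaError(NucarrayError):
    """A serialized model violates the package schema; the message names the field."""


class InvalidArgumentError(NucarrayError, ValueError):
    """An argument is outside the operation's documented domain."""


class PlacementNotFoundError(NucarrayError):
    """No wrapped DNA could be detected for a designed positioning repeat."""


class ArmTooShortError(NucarrayError):
    """Fewer than 20 bp of free DNA beyond a wrap boundary."""


class FitError(NucarrayError):
    """A geometric fit (frame/axis) is degenerate."""


class SampleTooSmallError(NucarrayError, ValueError):
    """Too few observations for the requested statistical fit."""


class UndefinedCorrelationError(NucarrayError):
    """Correlation requested on a variable with zero variance."""


class AssemblyError(NucarrayError):
    """Fiber or condensate assembly exhausted its retry budget."""

    def __init__(self, message: str, reached: int = 0):
        super().__init__(message)
        self.reached = reached


class TooShortError(NucarrayError, ValueError):
    """A chain/centerline is too short for the requested analysis."""
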