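"""Exception hierarchy.

Validation problems (bad parameters, malformed files) and runtime/numeric
problems (degenerate motion, empty bins) are kept on separate branches so the
command-line layer can map them to distinct exit codes.
"""


class RoboGaitError(Exception):
    """Base class for all package errors."""


class ParameterError(RoboGaitError, ValueError):
    """A parameter failed validation; the message names the offending field."""


class ParseError(RoboGaitError, ValueError):
    """A file did not conform to the expected CSV/JSON dialect."""


class RuntimeFailure(RoboGaitError, RuntimeError):
    """A numerically or structurally degenerate situation at run time."""


class DegenerateMotionError(RuntimeFailure):
    """Rotation range too small (or motion pure translation) for a
    rotation-center estimate; carries the conditioning diagnostic."""

    def __init__(self, message: str, condition: float = float("inf")):
        super().__init__(message)
        self.condition = condition


class DegeneratePathError(RuntimeFailure):
    """A trajectory or loaded path contains a zero-length segment."""


class BinningError(RuntimeFailure):
    """A (gait-percent bin, cycle) cell received no samples."""


class RangeError(RoboGaitError, ValueError):
    """A commanded angle falls outside the recorded passive-path span."""
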