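"""Exception hierarchy.

The CLI maps these onto distinct exit codes (I/O and parsing: 2,
validation: 3, degenerate geometry / undefined objective: 4).
"""


class AortaViewError(Exception):
    """Base class for all package errors."""


class ParseError(AortaViewError):
    """A file could not be parsed; the message names the offending line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f"{path}: "
        if line is not None:
            where += f"line {line}: "
        super().__init__(where + message)


class ValidationError(AortaViewError):
    """An argument or configuration value violates a precondition."""


class DegenerateInputError(AortaViewError):
    """Geometry too degenerate for the requested computation (e.g. n < 2)."""


class UndefinedObjectiveError(AortaViewError):
    """The optimisation objective is undefined for this input.

    Raised e.g. when the enclosed-area criterion is requested for a
    straight centerline whose projection never closes a polygon.
    """
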