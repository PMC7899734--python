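"""Exception hierarchy for dnetgaze."""


class DnetGazeError(Exception):
    """Base class for all package errors."""


class FormatError(DnetGazeError):
    """An input file is structurally invalid (missing column, bad geometry)."""


class SequenceParseError(DnetGazeError):
    """Scanpath sequence text could not be parsed."""

    def __init__(self, message: str, position: int | None = None, line: int | None = None):
        self.position = position
        self.line = line
        where = []
        if line is not None:
            where.append(f"line {line}")
        if position is not None:
            where.append(f"position {position}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


class IntegrityError(DnetGazeError):
    """Data violates an internal consistency requirement (duplicates, bad keys)."""
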