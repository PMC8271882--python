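"""Shared exception and warning types."""


class DimensionMismatchError(ValueError):
    """Two sample sets (or a sample set and a basis) disagree in dimension."""

    def __init__(self, what: str, left: int, right: int):
        self.left = left
        self.right = right
        super().__init__(f"{what}: got {left} vs {right}")


class DegenerateDataWarning(UserWarning):
    """Input is degenerate (e.g. all points coincide) and a fallback was used."""


class ConsistencyError(RuntimeError):
    """An internal numerical invariant was violated (signals a broken kernel)."""


class BVHParseError(ValueError):
    """Malformed BVH input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
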