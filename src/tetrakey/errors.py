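"""Exception hierarchy shared across the toolkit."""


class TetrakeyError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(TetrakeyError):
    """Invalid input data (bad measurement, malformed CSV cell, ...)."""


class KeyStructureError(TetrakeyError):
    """A key file violates the structural contract (bad GOTO, bad schema)."""

    def __init__(self, message: str, couplet: int | None = None):
        super().__init__(message)
        self.couplet = couplet


class KeyConflict(TetrakeyError):
    """Both or neither lead of a couplet is satisfied by a fully known state."""

    def __init__(self, message: str, couplet: int):
        super().__init__(message)
        self.couplet = couplet


class AmbiguousState(TetrakeyError):
    """Strict traversal consulted a character whose state is unknown.

    Callers that can live with set-valued answers should use
    :func:`tetrakey.keys.traverse_partial` instead.
    """

    def __init__(self, message: str, character: str, couplet: int):
        super().__init__(message)
        self.character = character
        self.couplet = couplet
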