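"""Exception types shared across the package."""


class EpistrainError(Exception):
    """Base class for package errors."""


class GeometryError(EpistrainError):
    """A polygon or mesh violates a geometric precondition."""


class TopologyError(EpistrainError):
    """The mesh connectivity violates a structural invariant."""


class ConvergenceError(EpistrainError):
    """An iterative solver did not reach its tolerance.

    Carries the best-so-far state so callers can inspect it.
    """

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


class ValidationError(EpistrainError):
    """An input file or table failed schema/range validation."""
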