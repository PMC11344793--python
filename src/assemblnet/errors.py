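"""Exception hierarchy shared across the package."""


class AssemblnetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AssemblnetError):
    """Raised when an input table violates the expected dialect."""


class InvariantError(AssemblnetError):
    """Raised when a typed container would violate one of its invariants."""


class EmptyTableError(AssemblnetError):
    """Raised when filtering leaves no genera or samples."""


class ConvergenceError(AssemblnetError):
    """Raised when the null-model margin fit does not converge."""


class UnannotatableAssemblage(AssemblnetError):
    """Signal (not a crash) that an assemblage lacks functional or
    phylogenetic annotation for one of its members and must be skipped."""


class InfeasibleConstraint(AssemblnetError):
    """Raised when rejection sampling exhausts its attempt budget."""

    def __init__(self, message: str, attempts: int = 0):
        super().__init__(message)
        self.attempts = attempts
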