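"""Exception hierarchy shared across the package."""


class BBEReduceError(Exception):
    """Base class for all package errors."""


class ParseError(BBEReduceError):
    """Malformed .bnet or partition-specification input."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NetworkError(BBEReduceError):
    """Invalid network assembly (duplicate/undeclared variables, empty network)."""


class PartitionError(BBEReduceError):
    """Invalid partition (overlap, missing variables, wrong universe)."""


class NotBBEError(BBEReduceError):
    """A quotient was requested for a partition that is not a backward equivalence.

    Carries the falsifying witness so callers can inspect or split on it.
    """

    def __init__(self, witness):
        self.witness = witness
        super().__init__(
            "partition is not a backward equivalence; witness state "
            f"{witness.state_string()} has a non-constant successor"
        )


class NonConstantStateError(BBEReduceError):
    """A state projection was requested for a state not constant on the partition."""


class SizeGuardError(BBEReduceError):
    """Explicit state-space construction refused because the network is too large."""


class SolverTimeoutError(BBEReduceError):
    """The satisfiability budget was exhausted before the check completed."""
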