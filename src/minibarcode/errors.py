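"""Exception hierarchy.

ContractError and its subclasses signal bad inputs (CLI exit code 2);
InfeasibleDesignError signals a well-posed but unsatisfiable design request
(CLI exit code 3).
"""

from __future__ import annotations


class MiniBarcodeError(Exception):
    """Base class for all package errors."""


class ContractError(MiniBarcodeError, ValueError):
    """An operation was called outside its contract (bad input)."""


class FastaParseError(ContractError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class HeaderParseError(ContractError):
    def __init__(self, message: str, header: str):
        self.header = header
        super().__init__(f"{message}: {header!r}")


class AlignmentError(ContractError):
    """Ragged or otherwise invalid alignment."""


class DesignError(ContractError):
    """A primer/oligo design request violated a design precondition."""


class InfeasibleDesignError(MiniBarcodeError):
    """No oligo satisfies the design constraints.

    ``best_mismatches`` reports the best (largest) minimum-mismatch count
    against the targets achieved by any candidate window.
    """

    def __init__(self, message: str, best_mismatches: int | None = None):
        self.best_mismatches = best_mismatches
        if best_mismatches is not None:
            message = f"{message} (best achieved target mismatches: {best_mismatches})"
        super().__init__(message)


class IrreconcilableReplicatesError(ContractError):
    """Replicates of one query bundle diverge beyond the allowed tolerance."""
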