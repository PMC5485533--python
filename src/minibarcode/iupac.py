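"""IUPAC nucleotide-code tables: base sets, complements, degeneracy.

All sequences in this package are plain Python strings of uppercase IUPAC
codes, written 5'->3'.  The gap character is '-' and is only meaningful in
aligned contexts.
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Minimal IUPAC code for each non-empty subset of {A,C,G,T}.
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N", "-": "-",
}

VALID_CODES = frozenset(IUPAC_SETS)
BASES = frozenset("ACGT")


def bases(code: str) -> frozenset[str]:
    """Base set denoted by a single IUPAC code."""
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}") from None


def code_for(base_set: frozenset[str] | set[str]) -> str:
    """Minimal IUPAC code covering a non-empty set of A/C/G/T bases."""
    try:
        return CODE_FOR_SET[frozenset(base_set)]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(base_set)}") from None


def complement(code: str) -> str:
    try:
        return COMPLEMENT[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC string (code-aware, involutive)."""
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def degeneracy(seq: str) -> int:
    """Product of per-position code cardinalities (1 for a plain sequence)."""
    d = 1
    for c in seq:
        d *= len(bases(c))
    return d


def validate_sequence(seq: str, *, allow_gaps: bool = False, context: str = "sequence") -> None:
    """Raise ValueError naming the first offending character, if any."""
    allowed = VALID_CODES | ({"-"} if allow_gaps else set())
    for i, c in enumerate(seq):
        if c not in allowed:
            raise ValueError(f"{context}: invalid character {c!r} at position {i}")
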