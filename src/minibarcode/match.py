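"""IUPAC-aware approximate matching of oligos against templates.

The matching rule is asymmetric between primer and template: a degenerate
code in the *primer* matches any template base in its set, but an unknown
template base ('N') must never be credited as a match against an informative
primer position — an unknown base is evidence of nothing.  Two 'N's match
(the primer explicitly tolerates anything there).

Site coordinates are always reported as 0-based half-open intervals on the
forward strand of the template, with strand '+' when the oligo binds the
forward strand as written and '-' when it binds the reverse strand (i.e. its
reverse complement occurs in the forward strand).
"""

from __future__ import annotations

from dataclasses import dataclass

from .iupac import IUPAC_SETS, revcomp


def iupac_match(primer_symbol: str, template_symbol: str) -> bool:
    """True iff the primer code can pair the template code.

    Base sets must intersect; a template 'N' against a non-N primer symbol
    counts as a mismatch (unknown template base).
    """
    p = IUPAC_SETS.get(primer_symbol)
    t = IUPAC_SETS.get(template_symbol)
    if p is None:
        raise ValueError(f"invalid IUPAC nucleotide code: {primer_symbol!r}")
    if t is None:
        raise ValueError(f"invalid IUPAC nucleotide code: {template_symbol!r}")
    if template_symbol == "N" and primer_symbol != "N":
        return False
    return bool(p & t)


def window_mismatches(oligo: str, window: str, limit: int | None = None) -> int:
    """Number of mismatching positions between equal-length strings.

    Early-exits past ``limit`` when given (returns limit + 1).
    """
    if len(oligo) != len(window):
        raise ValueError("oligo and window must have equal length")
    mm = 0
    for p, t in zip(oligo, window):
        if not iupac_match(p, t):
            mm += 1
            if limit is not None and mm > limit:
                return mm
    return mm


@dataclass(frozen=True)
class SiteMatch:
    """Approximate binding site on a template's forward strand."""

    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int


def scan_sites(
    oligo: str,
    template: str,
    max_mismatch: int = 0,
    clamp_3prime: int = 0,
    strands: str = "+-",
) -> list[SiteMatch]:
    """All approximate occurrences of an oligo in a template.

    ``clamp_3prime`` positions at the oligo's 3' end must match exactly
    (polymerase extension is launched from the 3' terminus, so mismatches
    there are disqualifying even when the total is tolerated).  On the '-'
    strand the oligo's 3' end maps to the *start* of the forward-strand
    interval.  Sites are sorted by (start, strand).
    """
    if clamp_3prime > len(oligo):
        raise ValueError("clamp_3prime cannot exceed oligo length")
    k = len(oligo)
    hits: list[SiteMatch] = []
    if k == 0 or k > len(template):
        return hits
    for strand in strands:
        probe = oligo if strand == "+" else revcomp(oligo)
        # 3'-clamp positions in forward-strand window coordinates
        if clamp_3prime:
            clamp_idx = (
                range(k - clamp_3prime, k) if strand == "+" else range(clamp_3prime)
            )
        else:
            clamp_idx = ()
        for start in range(len(template) - k + 1):
            window = template[start : start + k]
            clamped = all(iupac_match(probe[i], window[i]) for i in clamp_idx)
            if not clamped:
                continue
            mm = window_mismatches(probe, window, limit=max_mismatch)
            if mm <= max_mismatch:
                hits.append(SiteMatch(start, start + k, strand, mm))
    hits.sort(key=lambda s: (s.start, s.strand))
    return hits


def best_site(
    oligo: str, template: str, strands: str = "+-"
) -> SiteMatch | None:
    """Site with the fewest mismatches (ties: leftmost, then '+').

    Returns None only for an empty template or oligo longer than template.
    """
    k = len(oligo)
    if k == 0 or k > len(template):
        return None
    best: SiteMatch | None = None
    for strand in strands:
        probe = oligo if strand == "+" else revcomp(oligo)
        for start in range(len(template) - k + 1):
            limit = None if best is None else best.mismatches
            mm = window_mismatches(probe, template[start : start + k], limit=limit)
            if best is None or mm < best.mismatches:
                best = SiteMatch(start, start + k, strand, mm)
    return best
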