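"""Degenerate consensus primer design, screening, and blocking oligos.

Primers are designed on conserved alignment blocks flanking a variable
loop.  Per column, the minimal IUPAC code covering every base above a
minor-allele floor is used; a degeneracy budget caps the combinatorial
explosion by collapsing the least-conserved positions back to their modal
base.  Screening covers primer-dimer potential (contiguous complementary
runs involving a 3' terminus) and alternative binding sites on the
reference library.

A blocking oligo suppresses amplification of a known contaminant (e.g.
human DNA in ancient-DNA extracts): it matches the contaminant exactly,
overlaps a primer's binding footprint, extends 3' of it into
contaminant-specific sequence, and carries a non-extendable 3' end
(modelling a C3 spacer) so the polymerase cannot elongate it.  Computation-
ally the spacer is exactly the boolean "cannot prime".

The package ships the published avian 16S mini-barcode primer set (two
pairs targeting the variable loops Aves-16S-1A and Aves-16S-2A, plus the
human blocker for fragment 1A) as built-in constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DesignError, InfeasibleDesignError
from .iupac import bases, code_for, complement, degeneracy as seq_degeneracy, revcomp
from .match import best_site, scan_sites
from .profile import LoopCandidate, column_conservation
from .refdb import ReferenceLibrary, ReferenceRecord

_BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class PrimerCandidate:
    """An oligo written 5'->3' with its design metadata.

    ``template_interval`` is the alignment column interval the primer was
    designed on (None for user-supplied or published primers).  A reverse
    primer's sequence is the reverse complement of its template interval's
    consensus.
    """

    name: str
    sequence: str
    orientation: str  # 'forward' | 'reverse'
    template_interval: tuple[int, int] | None = None
    degeneracy: int = 1
    blocked_3prime: bool = False

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise ContractError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if not self.sequence:
            raise ContractError("primer sequence must be non-empty")
        object.__setattr__(self, "degeneracy", seq_degeneracy(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with its expected product size.

    ``expected_amplicon_length`` is primer-inclusive, measured on a degapped
    consensus of the design alignment (or as published, for built-ins).
    """

    name: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    expected_amplicon_length: int | None = None

    def __post_init__(self):
        fi, ri = self.forward.template_interval, self.reverse.template_interval
        if fi is not None and ri is not None and fi[1] > ri[0]:
            raise ContractError(
                "forward primer interval must lie entirely left of the reverse interval"
            )


@dataclass(frozen=True)
class BlockingOligo:
    """Contaminant-specific oligo with a non-extendable 3' end."""

    name: str
    sequence: str
    contaminant_species: str = ""
    overlap_with_primer: int = 0
    blocked_3prime: bool = True

    def __post_init__(self):
        if not self.blocked_3prime:
            raise ContractError("a blocking oligo must carry a non-extendable 3' end")

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Published avian 16S mini-barcode set (two pairs + human blocker).
# Product sizes are primer-inclusive: c. 125 bp (1A) and c. 120 bp (2A).

AVES_16S_1AF = PrimerCandidate("Aves-16S-1AF", "CATAAGACGAGAAGACCCTGTGGA", "forward")
AVES_16S_1AR = PrimerCandidate("Aves-16S-1AR", "TCCAAGGTCGCCCCAACCGAA", "reverse")
AVES_16S_2AF = PrimerCandidate("Aves-16S-2AF", "CCTTGGAGAAAAACAAANCCTCCAAA", "forward")
AVES_16S_2AR = PrimerCandidate("Aves-16S-2AR", "TCCCTGGGGTAGCTTGGTCCAT", "reverse")

AVES_16S_1A = PrimerPair("Aves-16S-1A", AVES_16S_1AF, AVES_16S_1AR, 125)
AVES_16S_2A = PrimerPair("Aves-16S-2A", AVES_16S_2AF, AVES_16S_2AR, 120)

AVES_16S_1A_BLOCK = BlockingOligo(
    "Aves-16S-1A-Block",
    "AGACCCTATGGAGCTTTAATTTATTAATGCAAAC",
    contaminant_species="Homo sapiens",
)

BUILTIN_PRIMER_PAIRS: dict[str, PrimerPair] = {
    AVES_16S_1A.name: AVES_16S_1A,
    AVES_16S_2A.name: AVES_16S_2A,
}


# ---------------------------------------------------------------------------
# Consensus primer design


@dataclass(frozen=True)
class DesignConstraints:
    """Search-space bounds for primer-pair enumeration."""

    primer_len_range: tuple[int, int] = (18, 27)
    amplicon_len_range: tuple[int, int] = (100, 140)
    max_degeneracy: int = 8
    minor_allele_floor: float = 0.10


def _column_base_counts(library: ReferenceLibrary, interval: tuple[int, int]) -> list[dict]:
    """Per-column A/C/G/T counts (ambiguity codes and gaps tracked separately)."""
    start, end = interval
    if not library.is_alignment:
        raise ContractError("consensus design requires an aligned library")
    if not (0 <= start < end <= library.alignment_length):
        raise ContractError(f"interval {interval} outside alignment")
    cols = []
    for j in range(start, end):
        counts = {b: 0 for b in _BASE_ORDER}
        gaps = other = 0
        for rec in library:
            c = rec.sequence[j]
            if c == "-":
                gaps += 1
            elif c in counts:
                counts[c] += 1
            else:
                other += 1
        cols.append({"counts": counts, "gaps": gaps, "other": other})
    return cols


def consensus_primer(
    library: ReferenceLibrary,
    interval: tuple[int, int],
    orientation: str = "forward",
    max_degeneracy: int = 8,
    minor_allele_floor: float = 0.10,
    name: str | None = None,
) -> PrimerCandidate:
    """Minimal-degeneracy consensus primer over an alignment interval.

    Per column, the minimal IUPAC code covering all bases with frequency >=
    ``minor_allele_floor`` (among unambiguous characters); the modal base is
    always covered.  If total degeneracy would exceed ``max_degeneracy``,
    the least-conserved degenerate positions fall back to the modal base,
    leftmost first on ties.  Gap-containing columns are a design error.
    """
    cols = _column_base_counts(library, interval)
    codes: list[frozenset] = []
    modal: list[str] = []
    modal_freq: list[float] = []
    for j, col in enumerate(cols):
        if col["gaps"]:
            raise DesignError(
                f"column {interval[0] + j} contains gaps; primers cannot span indels"
            )
        total = sum(col["counts"].values())
        if total == 0:
            raise DesignError(f"column {interval[0] + j} has no unambiguous bases")
        freqs = {b: c / total for b, c in col["counts"].items()}
        m = max(_BASE_ORDER, key=lambda b: (freqs[b], -_BASE_ORDER.index(b)))
        keep = {b for b, f in freqs.items() if f >= minor_allele_floor} | {m}
        codes.append(frozenset(keep))
        modal.append(m)
        modal_freq.append(freqs[m])

    def total_degeneracy() -> int:
        d = 1
        for s in codes:
            d *= len(s)
        return d

    while total_degeneracy() > max_degeneracy:
        degenerate = [j for j, s in enumerate(codes) if len(s) > 1]
        if not degenerate:
            break
        worst = min(degenerate, key=lambda j: (modal_freq[j], j))
        codes[worst] = frozenset(modal[worst])

    seq = "".join(code_for(s) for s in codes)
    if orientation == "reverse":
        seq = revcomp(seq)
    if name is None:
        name = f"{orientation[0].upper()}{interval[0]}-{interval[1]}"
    return PrimerCandidate(name, seq, orientation, template_interval=interval)


def _degapped_length_lookup(library: ReferenceLibrary) -> np.ndarray:
    """Cumulative count of consensus-nongap columns (for amplicon length)."""
    mat = np.array([list(r.sequence) for r in library], dtype="U1")
    gap_major = (mat == "-").sum(axis=0) * 2 > mat.shape[0]
    return np.concatenate([[0], np.cumsum(~gap_major)])


def enumerate_primer_pairs(
    loops: Sequence[LoopCandidate],
    library: ReferenceLibrary,
    constraints: DesignConstraints = DesignConstraints(),
) -> list[PrimerPair]:
    """All primer placements around each variable loop, ranked.

    The forward primer ends at or inside the loop's left flanking block; the
    reverse primer starts at or inside the right block; the primer-inclusive
    amplicon length (on a degapped consensus) must fall in the constraint
    range.  Pairs are ranked by (loop variability ascending, total
    degeneracy, flank conservation descending), ties broken by leftmost
    start.  Placements whose consensus would span a gapped column are
    silently skipped.
    """
    lmin, lmax = constraints.primer_len_range
    amin, amax = constraints.amplicon_len_range
    profile = column_conservation(library)
    cum = _degapped_length_lookup(library)
    cache: dict[tuple[tuple[int, int], str], PrimerCandidate | None] = {}

    def primer_at(interval: tuple[int, int], orientation: str) -> PrimerCandidate | None:
        key = (interval, orientation)
        if key not in cache:
            try:
                cache[key] = consensus_primer(
                    library, interval, orientation,
                    max_degeneracy=constraints.max_degeneracy,
                    minor_allele_floor=constraints.minor_allele_floor,
                )
            except DesignError:
                cache[key] = None
        return cache[key]

    ranked: list[tuple] = []
    for li, loop in enumerate(loops):
        left, right = loop.left_block, loop.right_block
        fwd_intervals = [
            (e - plen, e)
            for e in range(left.start + lmin, left.end + 1)
            for plen in range(lmin, lmax + 1)
            if e - plen >= left.start
        ]
        rev_intervals = [
            (s, s + plen)
            for s in range(right.start, right.end - lmin + 1)
            for plen in range(lmin, lmax + 1)
            if s + plen <= right.end
        ]
        for fi in fwd_intervals:
            for ri in rev_intervals:
                amp_len = int(cum[ri[1]] - cum[fi[0]])
                if not amin <= amp_len <= amax:
                    continue
                fwd = primer_at(fi, "forward")
                rev = primer_at(ri, "reverse")
                if fwd is None or rev is None:
                    continue
                flank = float(
                    np.mean(
                        np.concatenate(
                            [profile.scores[fi[0]: fi[1]], profile.scores[ri[0]: ri[1]]]
                        )
                    )
                )
                pair = PrimerPair(
                    f"L{li}_F{fi[0]}-{fi[1]}_R{ri[0]}-{ri[1]}",
                    PrimerCandidate(f"L{li}F{fi[0]}", fwd.sequence, "forward", fi),
                    PrimerCandidate(f"L{li}R{ri[0]}", rev.sequence, "reverse", ri),
                    amp_len,
                )
                key = (
                    loop.loop_mean_score,
                    fwd.degeneracy * rev.degeneracy,
                    -flank,
                    fi[0],
                    ri[0],
                )
                ranked.append((key, pair))
    ranked.sort(key=lambda t: t[0])
    return [p for _, p in ranked]


# ---------------------------------------------------------------------------
# Screening


def _complementary(x: str, y: str) -> bool:
    """Antiparallel Watson-Crick complementarity of two IUPAC codes
    (true when the base sets intersect complementarily)."""
    return bool(bases(x) & bases(complement(y)))


def _seq(p: PrimerCandidate | str) -> str:
    return p.sequence if isinstance(p, PrimerCandidate) else p


def dimer_score(a: PrimerCandidate | str, b: PrimerCandidate | str,
                three_prime_window: int = 10) -> int:
    """Longest contiguous complementary run between a's 3'-terminal window
    and any region of b (antiparallel pairing)."""
    sa = _seq(a)[-three_prime_window:]
    sb = _seq(b)
    best = 0
    for i in range(len(sa)):
        for j in range(len(sb)):
            k = 0
            while i + k < len(sa) and j - k >= 0 and _complementary(sa[i + k], sb[j - k]):
                k += 1
            if k > best:
                best = k
    return best


def pair_dimer_score(a: PrimerCandidate | str, b: PrimerCandidate | str) -> int:
    """Symmetric wrapper: worst 3'-anchored run in either direction."""
    return max(dimer_score(a, b), dimer_score(b, a))


def self_dimer_score(a: PrimerCandidate | str) -> int:
    return dimer_score(a, a)


DIMER_FLAG_THRESHOLD = 5  # contiguous complementary run involving a 3' terminus


def is_dimer_flagged(a: PrimerCandidate | str, b: PrimerCandidate | str,
                     threshold: int = DIMER_FLAG_THRESHOLD) -> bool:
    return pair_dimer_score(a, b) >= threshold


def alternative_binding_scan(
    primer: PrimerCandidate | str,
    library: ReferenceLibrary,
    max_mismatch: int = 0,
) -> dict[str, int]:
    """Per-record count of approximate binding sites (both strands).

    The intended design site counts once; any record with more than one
    site indicates alternative binding.
    """
    seq = _seq(primer)
    counts: dict[str, int] = {}
    for rec in library:
        if "-" in rec.sequence:
            raise ContractError("alternative_binding_scan requires unaligned records")
        counts[rec.id] = len(scan_sites(seq, rec.sequence, max_mismatch=max_mismatch))
    return counts


def has_alternative_binding(
    pair: PrimerPair, library: ReferenceLibrary, max_mismatch: int = 0
) -> bool:
    """True when either primer of the pair has >1 site on any record."""
    for primer in (pair.forward, pair.reverse):
        if any(c > 1 for c in alternative_binding_scan(primer, library, max_mismatch).values()):
            return True
    return False


# ---------------------------------------------------------------------------
# Blocking oligo design


def design_blocking_oligo(
    contaminant: ReferenceRecord,
    targets: ReferenceLibrary,
    primer: PrimerCandidate,
    min_target_mismatches: int = 4,
    length_range: tuple[int, int] = (25, 40),
    primer_site_max_mismatch: int = 2,
    name: str = "blocker",
) -> BlockingOligo:
    """Design a contaminant-specific blocking oligo for one primer.

    The oligo (i) matches the contaminant exactly over its full length,
    (ii) overlaps the primer's binding footprint on the contaminant by >= 1
    nt and extends 3' of it into contaminant-specific sequence, and (iii)
    carries >= ``min_target_mismatches`` mismatches against every target
    record (best ungapped placement, both strands).  Among feasible windows
    the shortest, then leftmost, is returned.  Raises InfeasibleDesignError
    (reporting the best achieved target-mismatch count) when no window
    within ``length_range`` discriminates.
    """
    template = contaminant.sequence
    if "-" in template:
        raise ContractError("contaminant record must be unaligned (gap-free)")
    site = best_site(primer.sequence, template)
    if site is None or site.mismatches > primer_site_max_mismatch:
        raise DesignError(
            f"primer {primer.name} has no binding site on the contaminant "
            f"within {primer_site_max_mismatch} mismatches"
        )
    lmin, lmax = length_range
    best_achieved: int | None = None
    for L in range(lmin, lmax + 1):
        if site.strand == "+":
            starts = range(max(0, site.end - L + 1), min(site.end, len(template) - L + 1))
        else:
            # primer 3' end maps to site.start; extension runs leftward
            starts = range(max(0, site.start - L + 1), min(site.start, len(template) - L + 1))
        for s in starts:
            window = template[s : s + L]
            worst = min(
                (_min_mismatches(window, t.sequence) for t in targets),
                default=0,
            )
            if best_achieved is None or worst > best_achieved:
                best_achieved = worst
            if worst >= min_target_mismatches:
                overlap = min(site.end, s + L) - max(site.start, s)
                return BlockingOligo(
                    name,
                    window,
                    contaminant_species=contaminant.label.species,
                    overlap_with_primer=max(0, overlap),
                )
    raise InfeasibleDesignError(
        f"no {lmin}-{lmax} nt window overlapping the {primer.name} footprint has "
        f">= {min_target_mismatches} mismatches against every target",
        best_mismatches=best_achieved,
    )


def _min_mismatches(oligo: str, template: str) -> int:
    """Fewest mismatches of the oligo over any ungapped placement, both strands."""
    site = best_site(oligo, template)
    return len(oligo) if site is None else site.mismatches


# ---------------------------------------------------------------------------
# Primer set I/O


def primers_to_frame(items: Iterable[PrimerCandidate | BlockingOligo]) -> pd.DataFrame:
    rows = []
    for it in items:
        rows.append(
            {
                "name": it.name,
                "sequence": it.sequence,
                "orientation": getattr(it, "orientation", "blocker"),
                "blocked_3prime": it.blocked_3prime,
            }
        )
    return pd.DataFrame(rows, columns=["name", "sequence", "orientation", "blocked_3prime"])


def write_primer_tsv(items: Iterable[PrimerCandidate | BlockingOligo], path: str | Path) -> None:
    primers_to_frame(items).to_csv(path, sep="\t", index=False)


def read_primer_tsv(path: str | Path) -> list[PrimerCandidate | BlockingOligo]:
    df = pd.read_csv(path, sep="\t", dtype={"blocked_3prime": bool})
    out: list[PrimerCandidate | BlockingOligo] = []
    for row in df.itertuples(index=False):
        if row.orientation == "blocker":
            out.append(BlockingOligo(row.name, row.sequence))
        else:
            out.append(PrimerCandidate(row.name, row.sequence, row.orientation))
    return out


def write_primer_fasta(items: Iterable[PrimerCandidate | BlockingOligo], path: str | Path) -> None:
    with open(path, "w") as fh:
        for it in items:
            fh.write(f">{it.name}\n{it.sequence}\n")
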