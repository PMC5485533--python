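"""In-silico PCR: predict amplicons of a primer pair on template sequences.

A product is predicted wherever a forward-primer site on the plus strand is
followed by a reverse-primer site on the minus strand within the product
length cap.  Matching is IUPAC-aware and approximate, with a 3'-clamp: the
clamped number of 3'-terminal primer positions must match exactly, because
extension launches from the 3' end.  All overlapping products are reported
(downstream consumers filter); products suppressed by a blocking oligo are
reported with ``blocked=True`` rather than dropped.

Reverse primers are stored 5'->3' as published and matched against the
minus strand via reverse complement; all coordinates are 0-based half-open
on the template's forward strand, primer-inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ContractError
from .match import SiteMatch, iupac_match, scan_sites
from .primers import BlockingOligo, PrimerCandidate, PrimerPair
from .refdb import ReferenceLibrary, ReferenceRecord

__all__ = [
    "MatchParams",
    "AmpliconPrediction",
    "iupac_match",
    "find_primer_sites",
    "predict_amplicons",
    "amplicon_table",
    "amplification_rate",
    "amplicons_to_frame",
    "write_amplicon_fasta",
]


@dataclass(frozen=True)
class MatchParams:
    """Binding-site tolerance for the in-silico PCR surrogate.

    Defaults mimic permissive degraded-DNA PCR: up to 2 total mismatches
    per primer but a perfect 3-nt 3' clamp, products capped at 2 kb, and a
    blocking oligo only engages at a perfect (0-mismatch) match.
    """

    max_mismatch_total: int = 2
    clamp_3prime: int = 3
    max_product_length: int = 2000
    blocker_max_mismatch: int = 0

    def __post_init__(self):
        if min(self.max_mismatch_total, self.clamp_3prime,
               self.max_product_length, self.blocker_max_mismatch) < 0:
            raise ContractError("MatchParams fields must be non-negative")


@dataclass(frozen=True)
class AmpliconPrediction:
    """One predicted product, primer-inclusive, on the forward strand."""

    record_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int
    product_sequence: str
    blocked: bool = False

    def __post_init__(self):
        if self.end - self.start != len(self.product_sequence):
            raise ContractError("product_sequence length must equal end - start")

    @property
    def length(self) -> int:
        return self.end - self.start


def _template_seq(template: ReferenceRecord | str) -> tuple[str, str]:
    if isinstance(template, ReferenceRecord):
        seq, rid = template.sequence, template.id
    else:
        seq, rid = template, "template"
    if "-" in seq:
        raise ContractError("in-silico PCR requires unaligned (gap-free) templates")
    return seq, rid


def find_primer_sites(
    primer: PrimerCandidate | str,
    template: ReferenceRecord | str,
    params: MatchParams = MatchParams(),
) -> list[SiteMatch]:
    """All binding sites of a primer on either strand of a template.

    Sites are intervals on the forward strand; ``strand`` records which
    strand the primer (as written 5'->3') anneals to.
    """
    seq = primer.sequence if isinstance(primer, PrimerCandidate) else primer
    tseq, _ = _template_seq(template)
    clamp = min(params.clamp_3prime, len(seq))
    return scan_sites(seq, tseq, max_mismatch=params.max_mismatch_total,
                      clamp_3prime=clamp)


def predict_amplicons(
    pair: PrimerPair,
    template: ReferenceRecord | str,
    params: MatchParams = MatchParams(),
    blocker: BlockingOligo | None = None,
) -> list[AmpliconPrediction]:
    """Predicted products of a primer pair on one template.

    Every (forward site on '+', reverse site on '-') combination with the
    reverse site starting at or after the forward site's end and a product
    length within the cap yields one prediction.  When a blocking oligo is
    given and matches the template (within ``params.blocker_max_mismatch``)
    overlapping either primer footprint, the product is flagged blocked.
    """
    tseq, rid = _template_seq(template)
    fwd_all = find_primer_sites(pair.forward, tseq, params)
    rev_all = find_primer_sites(pair.reverse, tseq, params)

    blocked_ivals: list[tuple[int, int]] = []
    if blocker is not None:
        blocked_ivals = [
            (s.start, s.end)
            for s in scan_sites(blocker.sequence, tseq,
                                max_mismatch=params.blocker_max_mismatch)
        ]

    def _blocked(fwd: SiteMatch, rev: SiteMatch) -> bool:
        for bs, be in blocked_ivals:
            for ps, pe in ((fwd.start, fwd.end), (rev.start, rev.end)):
                if bs < pe and ps < be:
                    return True
        return False

    out: list[AmpliconPrediction] = []
    seen: set[tuple[int, int]] = set()
    # forward-orientation products: fwd on '+', rev on '-' downstream
    combos = [
        (f, r, f.start, r.end)
        for f in fwd_all if f.strand == "+"
        for r in rev_all if r.strand == "-" and r.start >= f.end
    ]
    # mirrored orientation (template supplied reverse-complemented):
    # rev on '+', fwd on '-' downstream
    combos += [
        (f, r, r.start, f.end)
        for r in rev_all if r.strand == "+"
        for f in fwd_all if f.strand == "-" and f.start >= r.end
    ]
    for f, r, start, end in combos:
        if end - start > params.max_product_length or (start, end) in seen:
            continue
        seen.add((start, end))
        out.append(
            AmpliconPrediction(
                record_id=rid,
                start=start,
                end=end,
                fwd_mismatches=f.mismatches,
                rev_mismatches=r.mismatches,
                product_sequence=tseq[start:end],
                blocked=_blocked(f, r),
            )
        )
    out.sort(key=lambda a: (a.start, a.end))
    return out


def amplicon_table(
    pair: PrimerPair,
    library: ReferenceLibrary,
    params: MatchParams = MatchParams(),
    blocker: BlockingOligo | None = None,
) -> dict[str, list[AmpliconPrediction]]:
    """predict_amplicons applied per record of an unaligned library."""
    if library.is_alignment:
        raise ContractError("amplicon_table requires an unaligned library "
                            "(use library.degapped())")
    return {rec.id: predict_amplicons(pair, rec, params, blocker) for rec in library}


def amplification_rate(table: dict[str, list[AmpliconPrediction]],
                       include_blocked: bool = False) -> float:
    """Fraction of records with at least one (unblocked) predicted product."""
    if not table:
        return 0.0
    ok = sum(
        1
        for preds in table.values()
        if any(include_blocked or not p.blocked for p in preds)
    )
    return ok / len(table)


def amplicons_to_frame(table: dict[str, list[AmpliconPrediction]]) -> pd.DataFrame:
    rows = [
        {
            "record_id": rid,
            "start": p.start,
            "end": p.end,
            "length": p.length,
            "fwd_mismatches": p.fwd_mismatches,
            "rev_mismatches": p.rev_mismatches,
            "blocked": p.blocked,
        }
        for rid, preds in table.items()
        for p in preds
    ]
    return pd.DataFrame(
        rows,
        columns=["record_id", "start", "end", "length",
                 "fwd_mismatches", "rev_mismatches", "blocked"],
    )


def write_amplicon_fasta(table: dict[str, list[AmpliconPrediction]],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, preds in table.items():
            for p in preds:
                fh.write(
                    f">{rid}:{p.start}-{p.end} mm={p.fwd_mismatches},"
                    f"{p.rev_mismatches} blocked={p.blocked}\n{p.product_sequence}\n"
                )
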