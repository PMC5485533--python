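"""Taxonomic assignment of (possibly degraded) query sequences.

The workflow mirrors barcoding practice for degraded material: independent
PCR replicates of one fragment are collapsed to a consensus with
disagreeing positions masked as 'N' (replication exposes bases miscalled
through template damage); each consensus is compared against every
reference amplicon by end-gap-free alignment identity; a call is made only
above a strict identity threshold (>97%), with near-ties collapsed to the
lowest common rank rather than arbitrarily picking a species; finally the
calls from a specimen's fragments (two independent marker loops) are
combined, noting when an identification rests on a single fragment.

At curated-library scale (thousands of <=150 nt amplicons) exhaustive exact
alignment of every query against every reference is tractable and fully
reproducible, so no heuristic seeding is used.  The original analysis this
replaces ran heuristic local alignment with default parameters (recorded in
``config.BLASTN_PROVENANCE``); here determinism wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError, IrreconcilableReplicatesError
from .iupac import revcomp
from .refdb import ReferenceLibrary, TaxonLabel
from .resolution import align_overlap, identity_stats, pairwise_identity

FRAGMENT_1A = "Aves-16S-1A"
FRAGMENT_2A = "Aves-16S-2A"

RANK_ORDER = ("species", "genus", "family", "unidentified")


@dataclass
class QueryBundle:
    """Replicated reads of one fragment of one specimen."""

    specimen_id: str
    fragment_id: str
    replicates: list[str]

    def __post_init__(self):
        if not self.replicates:
            raise ContractError("QueryBundle requires >= 1 replicate")
        for r in self.replicates:
            if "-" in r or not r:
                raise ContractError("replicates must be non-empty and gap-free")


@dataclass(frozen=True)
class HitReport:
    """One reference comparison for one query.

    ``covered`` records whether the aligned region spans enough of the
    shorter sequence to be taxonomically meaningful (see rank_hits).
    """

    reference: TaxonLabel
    identity: float
    mismatches: int
    aligned_length: int
    covered: bool = True

    def __post_init__(self):
        if not 0.0 <= self.identity <= 100.0:
            raise ContractError("identity must lie in [0, 100]")


@dataclass
class IdentificationResult:
    """Final call for one specimen, with per-fragment evidence."""

    specimen_id: str
    fragment_hits: dict[str, list[HitReport]]
    fragment_calls: dict[str, tuple[str, str]]  # fragment -> (rank, taxon)
    call_rank: str
    call_taxon: str
    single_fragment: bool
    threshold_used: float
    conflict: str = ""


def replicate_consensus(
    bundle: QueryBundle, min_replicate_identity: float = 80.0
) -> tuple[str, list[int]]:
    """Collapse replicates to a consensus, masking disagreements as 'N'.

    Each further replicate is aligned to the first; positions (indices on
    the first replicate, restricted to the region covered by all
    replicates) where any replicate disagrees become 'N' and are flagged.
    Replicates diverging below ``min_replicate_identity`` percent identity
    are irreconcilable — that is no longer sequencing error.
    """
    first = bundle.replicates[0]
    if len(bundle.replicates) == 1:
        return first, []
    consensus = list(first)
    covered = [False] * len(first)
    flagged: set[int] = set()
    lo_cov, hi_cov = 0, len(first)
    for rep in bundle.replicates[1:]:
        if pairwise_identity(first, rep) < min_replicate_identity:
            raise IrreconcilableReplicatesError(
                f"{bundle.specimen_id}/{bundle.fragment_id}: replicates diverge "
                f"below {min_replicate_identity}% identity"
            )
        ra, rb = align_overlap(first, rep)
        i = first.find(ra.replace("-", ""))
        # overlap region on the first replicate's coordinates
        pos = i
        lo_cov = max(lo_cov, i)
        hi_cov = min(hi_cov, i + len(ra.replace("-", "")))
        for ca, cb in zip(ra, rb):
            if ca == "-":
                continue
            if cb != "-" and cb != ca:
                flagged.add(pos)
                consensus[pos] = "N"
            elif cb == "-":
                flagged.add(pos)
                consensus[pos] = "N"
            pos += 1
    consensus_str = "".join(consensus[lo_cov:hi_cov])
    flags = sorted(p - lo_cov for p in flagged if lo_cov <= p < hi_cov)
    return consensus_str, flags


def rank_hits(
    query: str,
    references: Iterable[tuple[TaxonLabel, str]] | ReferenceLibrary,
    check_orientation: bool = True,
    min_overlap_fraction: float = 0.5,
) -> list[HitReport]:
    """Identity of a query against every reference amplicon, best first.

    Sorted by identity descending, ties by fewer mismatches, then by
    reference source id.  'N' positions in the query are excluded from
    both numerator and denominator.  With ``check_orientation`` the query
    is aligned on both strands and the better strand kept (Sanger reads
    arrive in either orientation).

    An overlap alignment between unrelated sequences can degenerate to a
    few perfectly matching terminal columns — 100% identity over a
    meaningless region.  Hits whose aligned length is below
    ``min_overlap_fraction`` of the shorter sequence are therefore ranked
    below every adequately covered hit (a deterministic stand-in for the
    significance filter of a heuristic local aligner).
    """
    if not query:
        raise ContractError("query must be non-empty")
    refs = _as_labelled_seqs(references)
    if not refs:
        raise ContractError("reference library is empty")
    hits: list[HitReport] = []
    rc = revcomp(query) if check_orientation else None
    for label, seq in refs:
        st = identity_stats(query, seq, exclude_n_in_a=True)
        if rc is not None:
            st_rc = identity_stats(rc, seq, exclude_n_in_a=True)
            if (st_rc.identity, -st_rc.mismatches) > (st.identity, -st.mismatches):
                st = st_rc
        ok = st.aligned_length >= min_overlap_fraction * min(len(query), len(seq))
        hits.append(
            HitReport(label, st.identity, st.mismatches, st.aligned_length, covered=ok)
        )
    hits.sort(
        key=lambda h: (not h.covered, -h.identity, h.mismatches, h.reference.source_id)
    )
    return hits


def classify(
    hits: Sequence[HitReport],
    threshold: float = 97.0,
    tie_margin: float = 0.5,
) -> tuple[str, str]:
    """Taxon call from ranked hits at a strict identity threshold.

    Identity must exceed the threshold strictly.  All hits within
    ``tie_margin`` percentage points of the top are considered jointly: a
    single species gives a species call; several species in one genus a
    genus call; several genera in one family a family call; anything
    broader is unidentified.
    """
    hits = [h for h in hits if h.covered]
    if not hits:
        return "unidentified", ""
    top = hits[0]
    if top.identity <= threshold:
        return "unidentified", ""
    tied = [h for h in hits if h.identity >= top.identity - tie_margin]
    species = {h.reference.species for h in tied}
    if len(species) == 1:
        return "species", next(iter(species))
    genera = {h.reference.genus for h in tied}
    if len(genera) == 1:
        return "genus", next(iter(genera))
    families = {h.reference.family for h in tied}
    if len(families) == 1 and "" not in families:
        return "family", next(iter(families))
    return "unidentified", ""


def combine_fragments(
    fragment_calls: dict[str, tuple[str, str]],
    taxonomy: dict[str, TaxonLabel] | None = None,
) -> tuple[str, str, bool, str]:
    """Combine per-fragment calls into one specimen call.

    Returns (rank, taxon, single_fragment, conflict_note).  Two agreeing
    species calls give a species call; calls agreeing only at genus give a
    genus call with a conflict note; broader disagreement is unidentified
    with a conflict note.  A call supported by only one identified
    fragment stands, flagged ``single_fragment``.
    """
    if not fragment_calls:
        raise ContractError("combine_fragments requires >= 1 fragment result")
    identified = {
        f: (r, t) for f, (r, t) in fragment_calls.items() if r != "unidentified"
    }
    if not identified:
        return "unidentified", "", False, ""
    if len(identified) == 1:
        (rank, taxon), = identified.values()
        single = len(fragment_calls) > 1 or True
        return rank, taxon, True, ""
    calls = list(identified.values())
    paths = [_rank_path(r, t, taxonomy) for r, t in calls]
    for level in ("species", "genus", "family"):
        values = {p.get(level) for p in paths}
        if None in values:
            continue
        if len(values) == 1:
            taxon = next(iter(values))
            conflict = ""
            if level != "species" and all(r == "species" for r, _ in calls):
                conflict = "fragments disagree at species; agree at " + level
            return level, taxon, False, conflict
    return "unidentified", "", False, "fragments disagree above genus"


def _rank_path(rank: str, taxon: str,
               taxonomy: dict[str, TaxonLabel] | None) -> dict[str, str | None]:
    """Expand a call to its (species, genus, family) path where known."""
    label = (taxonomy or {}).get(taxon)
    if rank == "species":
        genus = label.genus if label else taxon.split()[0]
        family = (label.family or None) if label else None
        return {"species": taxon, "genus": genus, "family": family}
    if rank == "genus":
        family = (label.family or None) if label else None
        return {"species": None, "genus": taxon, "family": family}
    return {"species": None, "genus": None, "family": taxon}


# ---------------------------------------------------------------------------
# End-to-end convenience


def read_query_fasta(path) -> list[QueryBundle]:
    """Read query FASTA (headers ``specimen|fragment|replicate``) into
    bundles, grouping replicates of one specimen/fragment together."""
    from Bio import SeqIO

    from .errors import HeaderParseError

    grouped: dict[tuple[str, str], list[str]] = {}
    for seqrec in SeqIO.parse(str(path), "fasta"):
        fields = seqrec.description.split("|")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise HeaderParseError(
                "query header needs 'specimen|fragment|replicate'", seqrec.description
            )
        grouped.setdefault((fields[0], fields[1]), []).append(str(seqrec.seq).upper())
    return [
        QueryBundle(specimen, fragment, reps)
        for (specimen, fragment), reps in grouped.items()
    ]


def identify_specimens(
    bundles: Iterable[QueryBundle],
    references: Iterable[tuple[TaxonLabel, str]] | ReferenceLibrary,
    threshold: float = 97.0,
    tie_margin: float = 0.5,
    min_replicate_identity: float = 80.0,
) -> list[IdentificationResult]:
    """Full pipeline: consensus -> rank -> classify -> combine, per specimen."""
    refs = _as_labelled_seqs(references)
    taxonomy = {lab.species: lab for lab, _ in refs}
    by_specimen: dict[str, list[QueryBundle]] = {}
    for b in bundles:
        by_specimen.setdefault(b.specimen_id, []).append(b)
    results: list[IdentificationResult] = []
    for specimen_id, frags in by_specimen.items():
        fragment_hits: dict[str, list[HitReport]] = {}
        fragment_calls: dict[str, tuple[str, str]] = {}
        for bundle in frags:
            consensus, _ = replicate_consensus(bundle, min_replicate_identity)
            hits = rank_hits(consensus, refs)
            fragment_hits[bundle.fragment_id] = hits
            fragment_calls[bundle.fragment_id] = classify(hits, threshold, tie_margin)
        rank, taxon, single, conflict = combine_fragments(fragment_calls, taxonomy)
        results.append(
            IdentificationResult(
                specimen_id=specimen_id,
                fragment_hits=fragment_hits,
                fragment_calls=fragment_calls,
                call_rank=rank,
                call_taxon=taxon,
                single_fragment=single,
                threshold_used=threshold,
                conflict=conflict,
            )
        )
    return results


def results_to_frame(results: Iterable[IdentificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        top = max(
            (h for hits in r.fragment_hits.values() for h in hits[:1]),
            key=lambda h: h.identity,
            default=None,
        )
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "call_rank": r.call_rank,
                "call_taxon": r.call_taxon,
                "top_identity": top.identity if top else float("nan"),
                "top_mismatches": top.mismatches if top else -1,
                "single_fragment": r.single_fragment,
                "fragment_calls": ";".join(
                    f"{f}:{rank}:{taxon}" for f, (rank, taxon) in sorted(r.fragment_calls.items())
                ),
                "conflict": r.conflict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["specimen_id", "call_rank", "call_taxon", "top_identity",
                 "top_mismatches", "single_fragment", "fragment_calls", "conflict"],
    )


def _as_labelled_seqs(
    references: Iterable[tuple[TaxonLabel, str]] | ReferenceLibrary,
) -> list[tuple[TaxonLabel, str]]:
    if isinstance(references, ReferenceLibrary):
        return [(rec.label, rec.sequence) for rec in references]
    return list(references)
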