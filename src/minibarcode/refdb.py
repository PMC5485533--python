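"""Reference libraries and queries: FASTA I/O, taxonomy-bearing headers.

A reference library is an ordered collection of taxonomically labelled
marker sequences, optionally a multiple alignment.  Coordinates everywhere
in this package are 0-based, half-open, on the forward strand of the stored
sequence.  The only gap character is ``'-'`` ('.' is rejected), and gaps are
permitted only in aligned libraries.

Two header schemes are supported:

``id_species``
    ``>ID Genus species [anything else]`` — e.g. ``>X1 Turdus pilaris voucher``.
``pipe``
    ``>ID|Genus_species|family`` — underscores in the species name become
    spaces; the family field may be empty.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import AlignmentError, ContractError, FastaParseError, HeaderParseError
from .iupac import VALID_CODES

HEADER_SCHEMES = ("id_species", "pipe")

_ALLOWED_UNALIGNED = VALID_CODES
_ALLOWED_ALIGNED = VALID_CODES | {"-"}


@dataclass(frozen=True)
class TaxonLabel:
    """Taxonomic label parsed from a record header.

    ``species`` is a binomial ("Genus species"); ``genus`` defaults to its
    first token.  ``family`` is optional (empty string when unknown).
    """

    species: str
    source_id: str
    genus: str = ""
    family: str = ""

    def __post_init__(self):
        if not self.species:
            raise ContractError("TaxonLabel.species must be non-empty")
        if not self.genus:
            object.__setattr__(self, "genus", self.species.split()[0])

    def header(self, scheme: str = "id_species") -> str:
        if scheme == "id_species":
            return f"{self.source_id} {self.species}"
        if scheme == "pipe":
            return f"{self.source_id}|{self.species.replace(' ', '_')}|{self.family}"
        raise ContractError(f"unknown header scheme: {scheme!r}")


@dataclass(frozen=True)
class ReferenceRecord:
    """One labelled nucleotide sequence, aligned (gaps allowed) or not."""

    label: TaxonLabel
    sequence: str
    aligned: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ContractError(f"record {self.label.source_id}: empty sequence")
        allowed = _ALLOWED_ALIGNED if self.aligned else _ALLOWED_UNALIGNED
        bad = set(self.sequence) - allowed
        if bad:
            raise ContractError(
                f"record {self.label.source_id}: invalid characters {sorted(bad)}"
                + ("" if self.aligned else " (gaps allowed only in aligned libraries)")
            )

    @property
    def id(self) -> str:
        return self.label.source_id

    def degapped(self) -> "ReferenceRecord":
        if not self.aligned:
            return self
        return ReferenceRecord(self.label, self.sequence.replace("-", ""), aligned=False)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceLibrary:
    """Ordered collection of ReferenceRecord; optionally a multiple alignment."""

    records: list[ReferenceRecord] = field(default_factory=list)
    is_alignment: bool = False

    def __post_init__(self):
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ContractError(f"duplicate source_id: {rec.id!r}")
            seen.add(rec.id)
        if self.is_alignment and self.records:
            length = len(self.records[0])
            for rec in self.records:
                if len(rec) != length:
                    raise AlignmentError(
                        f"ragged alignment: record {rec.id!r} has length "
                        f"{len(rec)}, expected {length}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ReferenceRecord:
        return self.records[i]

    @property
    def alignment_length(self) -> int:
        if not self.is_alignment:
            raise ContractError("library is not an alignment")
        return len(self.records[0]) if self.records else 0

    def degapped(self) -> "ReferenceLibrary":
        """Unaligned copy with all gaps stripped."""
        return ReferenceLibrary([r.degapped() for r in self.records], is_alignment=False)

    def species(self) -> list[str]:
        """Distinct species names, in order of first appearance."""
        out: list[str] = []
        for rec in self.records:
            if rec.label.species not in out:
                out.append(rec.label.species)
        return out


def parse_header(header: str, scheme: str = "id_species") -> TaxonLabel:
    """Parse a FASTA description line (without '>') into a TaxonLabel."""
    if scheme not in HEADER_SCHEMES:
        raise ContractError(f"unknown header scheme: {scheme!r}")
    header = header.strip()
    if scheme == "id_species":
        tokens = header.split()
        if len(tokens) < 3:
            raise HeaderParseError(
                "id_species header needs '>ID Genus species ...'", header
            )
        species = f"{tokens[1]} {tokens[2]}".replace("_", " ")
        return TaxonLabel(species=species, source_id=tokens[0])
    fields = header.split("|")
    if len(fields) < 2 or not fields[0] or not fields[1]:
        raise HeaderParseError("pipe header needs '>ID|Genus_species|family'", header)
    species = fields[1].replace("_", " ")
    family = fields[2] if len(fields) > 2 else ""
    return TaxonLabel(species=species, source_id=fields[0], family=family)


def read_fasta(
    path: str | Path,
    aligned: bool = False,
    scheme: str = "id_species",
    degap: bool = False,
) -> ReferenceLibrary:
    """Read a FASTA file into a ReferenceLibrary.

    Sequences are upper-cased.  With ``aligned=True`` all records must have
    equal length.  With ``aligned=False``, gap characters are an error unless
    ``degap=True``, in which case they are stripped (silent degapping hides
    user mistakes, so it is opt-in).
    """
    path = Path(path)
    text = path.read_text()
    _precheck_fasta(text)
    records: list[ReferenceRecord] = []
    for seqrec in SeqIO.parse(io.StringIO(text), "fasta"):
        label = parse_header(seqrec.description, scheme=scheme)
        seq = str(seqrec.seq).upper()
        if "." in seq:
            raise FastaParseError(
                f"record {label.source_id!r}: '.' gap dialect is not supported; use '-'"
            )
        if not aligned and "-" in seq:
            if degap:
                seq = seq.replace("-", "")
            else:
                raise ContractError(
                    f"record {label.source_id!r} contains gaps but aligned=False "
                    "(pass degap=True to strip them)"
                )
        records.append(ReferenceRecord(label, seq, aligned=aligned))
    return ReferenceLibrary(records, is_alignment=aligned)


def _precheck_fasta(text: str) -> None:
    """Light syntax check so malformed input fails with a line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError("expected FASTA header line starting with '>'", lineno)
        return


def write_fasta(
    library: ReferenceLibrary | Iterable[ReferenceRecord],
    path: str | Path,
    scheme: str = "id_species",
    width: int = 70,
) -> None:
    """Write a library to FASTA; ``read_fasta(write_fasta(L))`` round-trips."""
    records = list(library)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.label.header(scheme)}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
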