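"""Synthetic reference libraries and degraded queries with known truth.

The generator emulates the structure the marker-discovery method assumes:
long conserved blocks (low per-column substitution probability across
species) interrupted by short variable loops (high substitution
probability), with the published primer binding sites optionally implanted
verbatim at the block boundaries so that in-silico PCR recovers the
published product sizes (125 bp and 120 bp) by construction.

Queries are degraded copies of true amplicons: independent substitutions,
extra C->T transitions near the fragment ends (mimicking terminal cytosine
deamination in ancient DNA), and truncation from a random end.  Substitutions
are drawn independently per column with no phylogenetic correlation — enough
to exercise every identification contract, though real libraries have
tree-structured similarity.

Everything is deterministic under the seed, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .iupac import revcomp
from .primers import AVES_16S_1AF, AVES_16S_1AR, AVES_16S_2AF, AVES_16S_2AR
from .refdb import ReferenceLibrary, ReferenceRecord, TaxonLabel

_BASES = np.array(list("ACGT"))

#: Deamination window: terminal positions subject to extra C->T damage.
TERMINAL_DAMAGE_WINDOW = 5


@dataclass
class FixtureSpec:
    """Layout and rates of a synthetic reference alignment.

    ``conserved_block_layout`` and ``loop_layout`` alternate (blocks =
    loops + 1): each entry is (length, per-column substitution probability
    between species).  Loop probabilities must exceed block probabilities.
    ``within_species_rate`` adds small independent within-species variation
    to each reference individual.  With ``implant_primers`` the published
    forward/reverse primer sites are inserted verbatim (and never mutated)
    at the block edges flanking each loop: loop 1 is delimited by the
    Aves-16S-1A pair, loop 2 by the Aves-16S-2A pair.

    Defaults give two loops of 80 and 72 nt so the primer-inclusive
    products are 24+80+21 = 125 bp and 26+72+22 = 120 bp — the published
    amplicon sizes.  Between-species loop divergence at rate 0.15 is well
    above the 97% assignment threshold's gap; block rate 0.01 keeps primer
    flanks conserved.
    """

    n_species: int = 20
    refs_per_species: int = 3
    conserved_block_layout: list[tuple[int, float]] = field(
        default_factory=lambda: [(40, 0.01), (50, 0.01), (40, 0.01)]
    )
    loop_layout: list[tuple[int, float]] = field(
        default_factory=lambda: [(80, 0.15), (72, 0.15)]
    )
    implant_primers: bool = True
    within_species_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if len(self.conserved_block_layout) != len(self.loop_layout) + 1:
            raise ContractError("need exactly one more conserved block than loops")
        for length, p in self.conserved_block_layout + self.loop_layout:
            if length <= 0 or not 0.0 <= p <= 1.0:
                raise ContractError("segment lengths positive, probabilities in [0,1]")
        block_p = max(p for _, p in self.conserved_block_layout)
        loop_p = min(p for _, p in self.loop_layout)
        if self.loop_layout and loop_p <= block_p:
            raise ContractError(
                "loop substitution probability must exceed block substitution probability"
            )
        if not 0.0 <= self.within_species_rate <= 1.0:
            raise ContractError("within_species_rate must lie in [0, 1]")


@dataclass
class DamageSpec:
    """Degradation model for simulated query fragments."""

    substitution_rate: float = 0.01
    terminal_CtoT_rate: float = 0.2
    max_truncation: int = 15
    seed: int = 0

    def __post_init__(self):
        for r in (self.substitution_rate, self.terminal_CtoT_rate):
            if not 0.0 <= r <= 1.0:
                raise ContractError("damage rates must lie in [0, 1]")
        if self.max_truncation < 0:
            raise ContractError("max_truncation must be non-negative")


#: Primer sites implanted per loop: (left edge oligo, right edge oligo).
#: The right-edge site is the reverse primer's reverse complement — its
#: footprint on the forward strand.
_IMPLANTS = [
    (AVES_16S_1AF.sequence, revcomp(AVES_16S_1AR.sequence)),
    (AVES_16S_2AF.sequence, revcomp(AVES_16S_2AR.sequence)),
]


def _segment_bounds(spec: FixtureSpec) -> list[tuple[str, int, int, float]]:
    """(kind, start, end, substitution probability) per segment, in order."""
    out = []
    pos = 0
    for i, (blen, bp) in enumerate(spec.conserved_block_layout):
        out.append(("block", pos, pos + blen, bp))
        pos += blen
        if i < len(spec.loop_layout):
            llen, lp = spec.loop_layout[i]
            out.append(("loop", pos, pos + llen, lp))
            pos += llen
    return out


def generate_reference_alignment(
    spec: FixtureSpec,
) -> tuple[ReferenceLibrary, pd.DataFrame, dict[str, tuple[int, int]]]:
    """Generate an aligned reference library with a truth table.

    Returns (library, truth, primer_sites): ``truth`` has one row per
    record (record_id, species, genus, family); ``primer_sites`` maps
    implanted oligo names to their column intervals (empty when
    ``implant_primers=False``).  The alignment is gap-free (no indel model),
    so degapping is the identity.
    """
    rng = np.random.default_rng(spec.seed)
    segments = _segment_bounds(spec)
    L = segments[-1][2]
    root = rng.choice(_BASES, size=L)

    # per-column between-species substitution probability
    col_rate = np.empty(L)
    for _, s, e, p in segments:
        col_rate[s:e] = p

    immutable = np.zeros(L, dtype=bool)
    primer_sites: dict[str, tuple[int, int]] = {}
    if spec.implant_primers:
        blocks = [seg for seg in segments if seg[0] == "block"]
        names = [
            (AVES_16S_1AF.name, AVES_16S_1AR.name),
            (AVES_16S_2AF.name, AVES_16S_2AR.name),
        ]
        for li, (fwd_seq, rev_site) in enumerate(_IMPLANTS[: len(spec.loop_layout)]):
            left, right = blocks[li], blocks[li + 1]
            f_start = left[2] - len(fwd_seq)
            r_end = right[1] + len(rev_site)
            if f_start < left[1]:
                raise ContractError(
                    f"conserved block {li} too short for a {len(fwd_seq)} nt primer site"
                )
            if r_end > right[2]:
                raise ContractError(
                    f"conserved block {li + 1} too short for a {len(rev_site)} nt primer site"
                )
            # Implanted verbatim (IUPAC codes included) and spared from mutation.
            root[f_start : left[2]] = list(fwd_seq)
            root[right[1] : r_end] = list(rev_site)
            immutable[f_start : left[2]] = True
            immutable[right[1] : r_end] = True
            primer_sites[names[li][0]] = (f_start, left[2])
            primer_sites[names[li][1]] = (right[1], r_end)
        # The second pair's sites overlap neither: both must fit in the
        # shared middle block, checked above.

    records: list[ReferenceRecord] = []
    rows = []
    idx = 0
    for s in range(spec.n_species):
        genus = f"Genus{s // 2:02d}"
        family = f"Familia{s // 6:02d}"
        species = f"{genus} species{s:03d}"
        species_seq = _mutate(root, col_rate, immutable, rng)
        for _ in range(spec.refs_per_species):
            seq = _mutate(
                species_seq, np.full(L, spec.within_species_rate), immutable, rng
            )
            rid = f"ref{idx:04d}"
            label = TaxonLabel(species=species, source_id=rid, family=family)
            records.append(ReferenceRecord(label, "".join(seq), aligned=True))
            rows.append(
                {"record_id": rid, "species": species, "genus": genus, "family": family}
            )
            idx += 1
    truth = pd.DataFrame(rows, columns=["record_id", "species", "genus", "family"])
    library = ReferenceLibrary(records, is_alignment=True)
    return library, truth, primer_sites


def _mutate(
    seq: np.ndarray, col_rate: np.ndarray, immutable: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each mutable column with prob col_rate, to a different base."""
    out = seq.copy()
    hit = (rng.random(seq.size) < col_rate) & ~immutable
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def simulate_degraded_query(amplicon: str, spec: DamageSpec) -> str:
    """Degrade an amplicon: substitutions, terminal C->T, truncation.

    Substitutions are independent per position at ``substitution_rate``;
    additional C->T transitions hit the first/last TERMINAL_DAMAGE_WINDOW
    positions at ``terminal_CtoT_rate``; finally a uniform 0..max_truncation
    nt truncation is applied to one randomly chosen end.
    """
    if spec.max_truncation >= len(amplicon):
        raise ContractError("max_truncation must be smaller than the query length")
    rng = np.random.default_rng(spec.seed)
    seq = np.array(list(amplicon))
    hit = rng.random(seq.size) < spec.substitution_rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
    w = min(TERMINAL_DAMAGE_WINDOW, len(seq))
    terminal = list(range(w)) + list(range(len(seq) - w, len(seq)))
    for i in terminal:
        if seq[i] == "C" and rng.random() < spec.terminal_CtoT_rate:
            seq[i] = "T"
    cut = int(rng.integers(spec.max_truncation + 1))
    if cut:
        if rng.random() < 0.5:
            seq = seq[cut:]
        else:
            seq = seq[: len(seq) - cut]
    return "".join(seq)
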