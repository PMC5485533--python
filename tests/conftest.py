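"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from minibarcode.iupac import revcomp
from minibarcode.primers import AVES_16S_1A, AVES_16S_2A
from minibarcode.refdb import ReferenceLibrary, ReferenceRecord, TaxonLabel
from minibarcode.simulate import FixtureSpec, generate_reference_alignment


def make_library(seqs, aligned=True, species=None, family=None):
    """Small labelled library from raw sequences."""
    recs = []
    for i, s in enumerate(seqs):
        sp = species[i] if species else f"Testus sp{i:02d}"
        fam = (family[i] if isinstance(family, (list, tuple)) else family) or ""
        recs.append(
            ReferenceRecord(
                TaxonLabel(species=sp, source_id=f"r{i:02d}", family=fam),
                s,
                aligned=aligned,
            )
        )
    return ReferenceLibrary(recs, is_alignment=aligned)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170621)


@pytest.fixture(scope="session")
def synthetic_library():
    """Default synthetic reference alignment with truth (seeded)."""
    spec = FixtureSpec(seed=42)
    library, truth, sites = generate_reference_alignment(spec)
    return library, truth, sites


@pytest.fixture(scope="session")
def template_125():
    """Template built to yield exactly one 125 bp product of the first pair:
    24 nt forward primer + 80 nt insert + 21 nt reverse-primer site."""
    r = np.random.default_rng(125)
    insert = random_seq(r, 80)
    return (
        random_seq(r, 10)
        + AVES_16S_1A.forward.sequence
        + insert
        + revcomp(AVES_16S_1A.reverse.sequence)
        + random_seq(r, 10)
    )


@pytest.fixture(scope="session")
def template_120():
    """Analogue for the second pair: 26 + 72 + 22 = 120."""
    r = np.random.default_rng(120)
    insert = random_seq(r, 72)
    # the degenerate N in the forward primer is instantiated as 'A' on the
    # template (a real template carries a concrete base there)
    return (
        random_seq(r, 10)
        + AVES_16S_2A.forward.sequence.replace("N", "A")
        + insert
        + revcomp(AVES_16S_2A.reverse.sequence)
        + random_seq(r, 10)
    )
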