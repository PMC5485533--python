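"""Primer design: consensus degeneracy, pair enumeration, screening, blockers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minibarcode.errors import DesignError, InfeasibleDesignError
from minibarcode.iupac import degeneracy, revcomp
from minibarcode.primers import (
    AVES_16S_1A,
    AVES_16S_1A_BLOCK,
    AVES_16S_2A,
    DesignConstraints,
    alternative_binding_scan,
    consensus_primer,
    design_blocking_oligo,
    dimer_score,
    enumerate_primer_pairs,
    pair_dimer_score,
    read_primer_tsv,
    write_primer_tsv,
)
from minibarcode.profile import column_conservation, find_conserved_blocks, find_loop_candidates
from minibarcode.pcr import MatchParams, predict_amplicons
from minibarcode.refdb import ReferenceRecord, TaxonLabel

from conftest import make_library, random_seq
from oracles import bf_binding_counts, bf_dimer

DNA = st.text(alphabet="ACGT", min_size=10, max_size=25)


class TestBuiltinSet:
    def test_published_primer_lengths_and_product_sizes(self):
        assert AVES_16S_1A.forward.length == 24
        assert AVES_16S_1A.reverse.length == 21
        assert AVES_16S_2A.forward.length == 26
        assert AVES_16S_2A.reverse.length == 22
        assert AVES_16S_1A.expected_amplicon_length == 125
        assert AVES_16S_2A.expected_amplicon_length == 120
        assert AVES_16S_1A_BLOCK.length == 34
        assert AVES_16S_1A_BLOCK.blocked_3prime

    def test_degenerate_position_in_published_forward_primer(self):
        # the second pair's forward primer carries one N
        assert AVES_16S_2A.forward.sequence.count("N") == 1
        assert AVES_16S_2A.forward.degeneracy == 4


class TestConsensusPrimer:
    def test_monomorphic_interval_gives_plain_consensus(self):
        lib = make_library(["ACGTACGT"] * 5)
        p = consensus_primer(lib, (0, 8))
        assert p.sequence == "ACGTACGT" and p.degeneracy == 1

    def test_fifty_fifty_column_becomes_r(self):
        lib = make_library(["AAAA", "AGAA"] * 2)
        p = consensus_primer(lib, (0, 4), minor_allele_floor=0.1)
        assert p.sequence == "ARAA" and p.degeneracy == 2

    def test_four_way_column_becomes_n(self):
        lib = make_library(["AAAA", "ACAA", "AGAA", "ATAA"])
        p = consensus_primer(lib, (0, 4), minor_allele_floor=0.1)
        assert p.sequence[1] == "N" and p.degeneracy == 4

    def test_max_degeneracy_one_equals_modal_consensus(self):
        lib = make_library(["AAAA", "ACAA", "AGAA", "ATAA", "ACAA"])
        p = consensus_primer(lib, (0, 4), max_degeneracy=1)
        assert p.sequence == "ACAA" and p.degeneracy == 1

    def test_degeneracy_budget_collapses_least_conserved_first(self):
        # column 1 is 3:2, column 2 is 4:1 -> with budget 2 only column 2's
        # code survives? no: least-conserved (col 1, modal 0.6) collapses first
        lib = make_library(["AAGA", "ACGA", "ACGA", "AATA", "AAGA"])
        p = consensus_primer(lib, (0, 4), max_degeneracy=2, minor_allele_floor=0.1)
        assert degeneracy(p.sequence) <= 2
        assert p.sequence[1] == "A"  # modal of {A:3, C:2}

    def test_reverse_orientation_is_reverse_complement(self):
        lib = make_library(["ACGTACGT"] * 4)
        fwd = consensus_primer(lib, (0, 8), "forward")
        rev = consensus_primer(lib, (0, 8), "reverse")
        assert rev.sequence == revcomp(fwd.sequence)

    def test_gap_column_is_design_error(self):
        lib = make_library(["AC-T", "ACGT", "ACGT"])
        with pytest.raises(DesignError, match="gap"):
            consensus_primer(lib, (0, 4))


@pytest.fixture(scope="module")
def flank_loop_flank():
    """30-col conserved flank + 80-col variable loop + 30-col flank."""
    rng = np.random.default_rng(3)
    left = random_seq(rng, 30)
    right = random_seq(rng, 30)
    seqs = []
    for _ in range(6):
        loop = random_seq(rng, 80)
        seqs.append(left + loop + right)
    lib = make_library(seqs)
    prof = column_conservation(lib)
    blocks = find_conserved_blocks(prof, min_len=20)
    loops = find_loop_candidates(blocks, prof, min_loop=40, max_loop=120)
    return lib, loops


@pytest.fixture(scope="module")
def contaminant_fixture():
    """Targets share a primer site; the contaminant differs at 4 clustered
    positions 3' of the primer footprint."""
    rng = np.random.default_rng(17)
    pad = random_seq(rng, 40)
    tail = random_seq(rng, 60)
    primer = AVES_16S_1A.forward
    target_seq = pad + primer.sequence + tail
    swapped = {"A": "C", "C": "A", "G": "T", "T": "G"}
    cont_tail = list(tail)
    for i in range(4, 8):
        cont_tail[i] = swapped[cont_tail[i]]
    cont_seq = pad + primer.sequence + "".join(cont_tail)
    targets = make_library([target_seq] * 3, aligned=False)
    contaminant = ReferenceRecord(
        TaxonLabel(species="Homo sapiens", source_id="hum"), cont_seq
    )
    return targets, contaminant, primer, cont_seq


class TestEnumeratePairs:
    def test_pair_with_amplicon_120_exists(self, flank_loop_flank):
        lib, loops = flank_loop_flank
        constraints = DesignConstraints(
            primer_len_range=(20, 20), amplicon_len_range=(100, 140)
        )
        pairs = enumerate_primer_pairs(loops, lib, constraints)
        assert any(p.expected_amplicon_length == 120 for p in pairs)
        # 20 nt primers at the loop edges: 20 + 80 + 20
        exact = [
            p
            for p in pairs
            if p.forward.template_interval == (10, 30)
            and p.reverse.template_interval == (110, 130)
        ]
        assert exact and exact[0].expected_amplicon_length == 120

    def test_unsatisfiable_amplicon_range_gives_empty(self, flank_loop_flank):
        lib, loops = flank_loop_flank
        constraints = DesignConstraints(
            primer_len_range=(20, 20), amplicon_len_range=(50, 60)
        )
        assert enumerate_primer_pairs(loops, lib, constraints) == []

    def test_two_loops_both_reported(self):
        rng = np.random.default_rng(8)
        blocks = [random_seq(rng, 30) for _ in range(3)]
        seqs = []
        for _ in range(6):
            loops_seq = [random_seq(rng, 60), random_seq(rng, 70)]
            seqs.append(blocks[0] + loops_seq[0] + blocks[1] + loops_seq[1] + blocks[2])
        lib = make_library(seqs)
        prof = column_conservation(lib)
        cblocks = find_conserved_blocks(prof, min_len=20)
        loops = find_loop_candidates(cblocks, prof, min_loop=40, max_loop=120)
        assert len(loops) == 2
        pairs = enumerate_primer_pairs(
            loops, lib, DesignConstraints(primer_len_range=(20, 20))
        )
        names = {p.name.split("_")[0] for p in pairs}
        assert names == {"L0", "L1"}

    def test_every_emitted_pair_amplifies_the_library(self, flank_loop_flank):
        """Zero-mismatch in-silico PCR succeeds on every member for any pair."""
        lib, loops = flank_loop_flank
        constraints = DesignConstraints(
            primer_len_range=(20, 22), amplicon_len_range=(115, 125)
        )
        pairs = enumerate_primer_pairs(loops, lib, constraints)
        assert pairs
        params = MatchParams(max_mismatch_total=0, clamp_3prime=0)
        for pair in pairs[:5]:
            for rec in lib.degapped():
                assert predict_amplicons(pair, rec, params)


class TestDimerScore:
    def test_perfect_complement_scores_window_length(self):
        assert dimer_score("AAAAAAAAAA", "TTTTTTTTTT") == 10

    def test_self_identity_of_a_homopolymer_is_zero(self):
        # A is not complementary to A
        assert dimer_score("AAAAAAAAAA", "AAAAAAAAAA") == 0

    def test_three_prime_run_detected(self):
        a = "GGGGGGGGGGGGGGGCTAGC"  # 3' end ...CTAGC
        b = "GCTAGGGGGGGGGGGGGGGG"  # 5' GCTAG pairs CTAGC antiparallel
        assert dimer_score(a, b) >= 5

    def test_symmetric_wrapper(self):
        a, b = "ACGTACGTACGTACGTACGT", "TTTTACGTACGTACGTACGT"
        assert pair_dimer_score(a, b) == max(dimer_score(a, b), dimer_score(b, a))

    @settings(derandomize=True, max_examples=60)
    @given(DNA, DNA)
    def test_agrees_with_exhaustive_offset_scan(self, a, b):
        assert dimer_score(a, b) == bf_dimer(a, b)


class TestAlternativeBinding:
    def test_single_implanted_site_counts_once(self, rng):
        primer = "CATAAGACGAGAAGACCCTGTGGA"
        recs = [random_seq(rng, 50) + primer + random_seq(rng, 50) for _ in range(4)]
        lib = make_library(recs, aligned=False)
        counts = alternative_binding_scan(primer, lib, max_mismatch=0)
        assert all(c == 1 for c in counts.values())

    def test_duplicated_site_flags_record(self, rng):
        primer = "CATAAGACGAGAAGACCCTGTGGA"
        seq = primer + random_seq(rng, 40) + primer
        lib = make_library([seq], aligned=False)
        counts = alternative_binding_scan(primer, lib, max_mismatch=0)
        assert counts["r00"] == 2

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 2))
    def test_counts_match_brute_force(self, seed, max_mm):
        rng = np.random.default_rng(seed)
        primer = random_seq(rng, 12)
        lib = make_library(
            [random_seq(rng, int(rng.integers(50, 400))) for _ in range(3)],
            aligned=False,
        )
        got = alternative_binding_scan(primer, lib, max_mismatch=max_mm)
        assert got == bf_binding_counts(primer, lib, max_mm)


class TestBlockingOligo:
    def test_designed_blocker_contract(self, contaminant_fixture):
        targets, contaminant, primer, cont_seq = contaminant_fixture
        oligo = design_blocking_oligo(
            contaminant, targets, primer, min_target_mismatches=4, length_range=(20, 40)
        )
        assert oligo.blocked_3prime
        assert oligo.sequence in cont_seq  # exact contaminant match
        assert oligo.overlap_with_primer >= 1
        # covers the 4 discriminating positions: >= 4 mismatches vs every target
        from minibarcode.match import best_site

        for rec in targets:
            site = best_site(oligo.sequence, rec.sequence)
            assert site.mismatches >= 4

    def test_blocker_extends_three_prime_of_primer(self, contaminant_fixture):
        targets, contaminant, primer, cont_seq = contaminant_fixture
        oligo = design_blocking_oligo(
            contaminant, targets, primer, min_target_mismatches=4, length_range=(20, 40)
        )
        footprint_end = 40 + primer.length
        assert cont_seq.index(oligo.sequence) + oligo.length > footprint_end

    def test_indistinguishable_contaminant_is_infeasible(self, contaminant_fixture):
        targets, _, primer, _ = contaminant_fixture
        twin = ReferenceRecord(
            TaxonLabel(species="X y", source_id="twin"), targets[0].sequence
        )
        with pytest.raises(InfeasibleDesignError) as exc:
            design_blocking_oligo(twin, targets, primer, min_target_mismatches=4)
        assert exc.value.best_mismatches == 0

    def test_no_primer_site_is_design_error(self, contaminant_fixture):
        targets, _, primer, _ = contaminant_fixture
        rng = np.random.default_rng(5)
        stranger = ReferenceRecord(
            TaxonLabel(species="X y", source_id="s"), random_seq(rng, 120)
        )
        with pytest.raises(DesignError):
            design_blocking_oligo(stranger, targets, primer)


class TestRevcompAndIO:
    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=40))
    def test_reverse_complement_is_involutive(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_primer_tsv_round_trip(self, tmp_path):
        items = [AVES_16S_1A.forward, AVES_16S_1A.reverse, AVES_16S_1A_BLOCK]
        p = tmp_path / "primers.tsv"
        write_primer_tsv(items, p)
        back = read_primer_tsv(p)
        assert [(i.name, i.sequence) for i in back] == [
            (i.name, i.sequence) for i in items
        ]
        assert back[2].blocked_3prime
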