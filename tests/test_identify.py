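"""Identification decision procedure: local alignment hits, e-value
ordering, tie-breaks with rank escalation, the 95% threshold, the
reading-frame screen, and novel-candidate screening."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sangerbarcode.consensus import ConsensusBarcode
from sangerbarcode.identify import (
    STATUS_EXCLUDED,
    STATUS_IDENTIFIED,
    STATUS_POTENTIAL_NOVEL,
    AlignmentHit,
    align_to_references,
    classify_identity,
    evalue,
    identify_sample,
    novelty_screen,
    select_best_hit,
    translate_and_check,
)
from sangerbarcode.qc import SangerRead
from sangerbarcode.taxonomy import Rank

from conftest import make_library, make_lineage

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


def local_affine_oracle(a, b, match=1, mismatch=-2, open_=-5, extend=-2):
    """Gotoh local alignment; a length-k gap scores open + (k-1)*extend."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend, X[i, j - 1] + open_)
            best = max(best, M[i, j])
    return best


def consensus_of(seq, marker="COI", sample_id="S1"):
    return ConsensusBarcode(
        sample_id=sample_id,
        marker=marker,
        sequence=seq,
        overlap_length=len(seq),
        per_base_support=tuple(["both_agree"] * len(seq)),
    )


@pytest.fixture
def small_library(rng):
    bases = np.array(list("ACGT"))
    seqs = ["".join(rng.choice(bases, 120)) for _ in range(3)]
    return make_library(
        [
            ("R0", "COI", seqs[0], make_lineage("Tetramorium", "Tetramorium caespitum")),
            ("R1", "COI", seqs[1], make_lineage("Monomorium", "Monomorium viride")),
            ("R2", "COI", seqs[2], make_lineage("Monomorium", "Monomorium minimum")),
        ]
    )


class TestAlignToReferences:
    def test_exact_match_has_identity_100(self, small_library):
        ref = small_library.get("R0")
        hits = align_to_references(consensus_of(ref.sequence), small_library)
        assert hits[0].ref_id == "R0"
        assert hits[0].percent_identity == 100.0

    def test_single_substitution_over_100_columns(self, small_library, rng):
        ref = small_library.get("R0")
        seq = ref.sequence[:100]
        mutated = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
        hits = align_to_references(consensus_of(mutated), small_library)
        top = hits[0]
        assert top.ref_id == "R0"
        assert top.n_identical == 99
        assert top.percent_identity == pytest.approx(99.0)

    def test_n_columns_excluded_symmetrically(self, small_library):
        ref = small_library.get("R0")
        seq = ref.sequence[:20] + "NNNNN" + ref.sequence[25:]
        hits = align_to_references(consensus_of(seq), small_library)
        assert hits[0].ref_id == "R0"
        assert hits[0].percent_identity == 100.0

    def test_no_same_marker_reference_is_an_error(self, small_library):
        with pytest.raises(ValueError, match="rbcL"):
            align_to_references(
                consensus_of("ACGT" * 30, marker="rbcL"), small_library
            )

    @given(dna, dna)
    def test_local_score_matches_gotoh_oracle(self, a, b):
        from Bio import Align

        from sangerbarcode.identify import _local_aligner

        got = float(_local_aligner().score(a, b))
        assert got == local_affine_oracle(a, b)


class TestEvalue:
    def test_monotone_decreasing_in_score(self):
        assert evalue(60, 600, 10000) < evalue(50, 600, 10000)

    def test_linear_in_database_length(self):
        assert evalue(50, 600, 20000) == pytest.approx(2 * evalue(50, 600, 10000))

    def test_direct_evaluation(self):
        expected = 0.621 * 600 * 10000 * math.exp(-1.33 * 50)
        assert evalue(50, 600, 10000) == pytest.approx(expected)

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            evalue(50, 0, 10000)


def hit(ref_id, lineage, pid, e):
    return AlignmentHit(
        ref_id=ref_id,
        lineage=lineage,
        percent_identity=pid,
        alignment_length=100,
        n_identical=int(pid),
        n_mismatch=100 - int(pid),
        n_gap_columns=0,
        raw_score=50,
        bit_score=96.0,
        e_value=e,
    )


class TestSelectBestHit:
    tetra = make_lineage("Tetramorium", "Tetramorium caespitum")
    mono_v = make_lineage("Monomorium", "Monomorium viride")
    mono_m = make_lineage("Monomorium", "Monomorium minimum")

    def test_single_hit_assigns_species(self):
        assert select_best_hit([hit("R0", self.tetra, 97.0, 1e-50)]) == (
            "Tetramorium caespitum",
            Rank.species,
            False,
        )

    def test_identity_tie_broken_by_evalue(self):
        hits = [
            hit("R0", self.tetra, 96.0, 1e-48),
            hit("R1", self.mono_v, 96.0, 1e-50),
        ]
        name, rank, escalated = select_best_hit(hits)
        assert (name, rank, escalated) == ("Monomorium viride", Rank.species, False)

    def test_full_tie_escalates_to_genus(self):
        hits = [
            hit("R1", self.mono_v, 96.0, 1e-50),
            hit("R2", self.mono_m, 96.0, 1e-50),
        ]
        assert select_best_hit(hits) == ("Monomorium", Rank.genus, True)

    def test_tie_across_genera_escalates_to_family(self):
        hits = [
            hit("R0", self.tetra, 96.0, 1e-50),
            hit("R1", self.mono_v, 96.0, 1e-50),
        ]
        assert select_best_hit(hits) == ("Formicidae", Rank.family, True)

    def test_same_species_twice_is_not_an_escalation(self):
        hits = [
            hit("R1a", self.mono_v, 96.0, 1e-50),
            hit("R1b", self.mono_v, 96.0, 1e-50),
        ]
        assert select_best_hit(hits) == ("Monomorium viride", Rank.species, False)

    def test_identity_rounding_to_two_decimals(self):
        # 96.004 and 96.0009 both round to 96.0: a tie
        hits = [
            hit("R1", self.mono_v, 96.004, 1e-50),
            hit("R2", self.mono_m, 96.0009, 1e-50),
        ]
        assert select_best_hit(hits)[2] is True

    def test_evalue_rounding_to_two_significant_figures(self):
        # 1.04e-50 and 1.0e-50 round to the same printed value: a tie
        hits = [
            hit("R1", self.mono_v, 96.0, 1.04e-50),
            hit("R2", self.mono_m, 96.0, 1.0e-50),
        ]
        assert select_best_hit(hits)[2] is True

    def test_permutation_invariant(self):
        hits = [
            hit("R0", self.tetra, 95.0, 1e-40),
            hit("R1", self.mono_v, 96.0, 1e-50),
            hit("R2", self.mono_m, 96.0, 1e-49),
        ]
        assert select_best_hit(hits) == select_best_hit(hits[::-1])

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            select_best_hit([])


class TestClassifyIdentity:
    @pytest.mark.parametrize(
        "pid,expected",
        [
            (95.0, STATUS_IDENTIFIED),
            (94.99, STATUS_POTENTIAL_NOVEL),
            (100.0, STATUS_IDENTIFIED),
            (None, STATUS_POTENTIAL_NOVEL),
        ],
    )
    def test_threshold_boundary(self, pid, expected):
        assert classify_identity(pid) == expected


class TestTranslateAndCheck:
    def test_stop_free_sequence_passes_in_frame_zero(self):
        frame, ok = translate_and_check("ATGGCT" * 20, "COI")
        assert ok and frame == 0

    def test_stops_in_all_three_frames_fail(self):
        # TAAA repeated drifts the phase, placing a TAA stop at offsets
        # 0, 4, 8 and hence in every reading frame
        core = "ATGGCA" * 10
        seq = core + "TAAATAAATAAA" + core
        _, ok = translate_and_check(seq, "rbcL")
        assert not ok
        _, ok_coi = translate_and_check(seq, "COI")
        assert not ok_coi

    def test_tga_is_tryptophan_in_invertebrate_mito_but_stop_in_standard(self):
        # TGA at every phase (offsets 0, 4, 8) while avoiding TAA/TAG
        core = "ATGGCA" * 10
        seq = core + "TGAATGAATGAA" + core
        _, ok_coi = translate_and_check(seq, "COI")
        assert ok_coi
        _, ok_rbcl = translate_and_check(seq, "rbcL")
        assert not ok_rbcl

    def test_its_is_never_translated(self):
        seq = "TAA" * 40  # stops everywhere
        frame, ok = translate_and_check(seq, "ITS")
        assert ok and frame is None

    def test_alphabet_violation(self):
        with pytest.raises(ValueError):
            translate_and_check("ACGU" * 20, "COI")


class TestNoveltyScreen:
    def good_read(self, direction="forward"):
        return SangerRead("S1", direction, "ACGT" * 30, tuple([40] * 120))

    def bad_read(self, direction="reverse"):
        return SangerRead("S1", direction, "ACGT" * 30, tuple([10] * 120))

    def novel_result(self):
        lin = make_lineage("Monomorium", "Monomorium viride")
        return_hits = [hit("R1", lin, 90.0, 1e-30)]
        from sangerbarcode.identify import IdentificationResult

        return IdentificationResult(
            sample_id="S1",
            marker="COI",
            assigned_name="Monomorium viride",
            assigned_rank=Rank.species,
            status=STATUS_POTENTIAL_NOVEL,
            top_hits=return_hits,
        )

    def test_clean_candidate_is_publishable(self):
        cons = consensus_of("ATGGCT" * 20)
        report = novelty_screen(
            self.novel_result(), self.good_read(), self.good_read("reverse"), cons
        )
        assert report.publishable

    def test_low_quality_reverse_read_blocks_publication(self):
        cons = consensus_of("ATGGCT" * 20)
        report = novelty_screen(
            self.novel_result(), self.good_read(), self.bad_read(), cons
        )
        assert not report.reads_high_quality
        assert not report.publishable

    def test_short_overlap_blocks_publication(self):
        seq = "ATGGCT" * 20
        cons = ConsensusBarcode(
            sample_id="S1",
            marker="COI",
            sequence=seq,
            overlap_length=10,
            per_base_support=tuple(
                ["both_agree"] * 10 + ["single_read"] * (len(seq) - 10)
            ),
        )
        report = novelty_screen(
            self.novel_result(), self.good_read(), self.good_read("reverse"), cons
        )
        assert not report.overlap_sufficient

    def test_frameshifted_candidate_fails_translation(self):
        core = "ATGGCA" * 10
        seq = core + "TAAATAAATAAA" + core
        report = novelty_screen(
            self.novel_result(),
            self.good_read(),
            self.good_read("reverse"),
            consensus_of(seq),
        )
        assert not report.translation_ok

    def test_rejects_identified_samples(self):
        result = self.novel_result()
        result.status = STATUS_IDENTIFIED
        with pytest.raises(ValueError):
            novelty_screen(
                result,
                self.good_read(),
                self.good_read("reverse"),
                consensus_of("ATGGCT" * 20),
            )


def test_identify_sample_end_to_end(small_library):
    ref = small_library.get("R1")
    result = identify_sample(consensus_of(ref.sequence), small_library)
    assert result.status == STATUS_IDENTIFIED
    assert result.assigned_name == "Monomorium viride"
    assert result.assigned_rank == Rank.species
    assert result.lineage.terminal_name == "Monomorium viride"
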