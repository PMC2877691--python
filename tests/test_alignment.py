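"""Reference conversion, pairwise alignment, orientation, frame merging."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bisclone.alignment import (
    AlignParams,
    OrientedRead,
    build_alignment,
    convert_reference,
    needs_msa_fallback,
    orient_and_trim,
    pairwise_align,
)
from bisclone.errors import UnalignableReadError
from bisclone.simulate import SimConfig, simulate_reads, simulate_reference

from conftest import best_alignments_bruteforce

REVCOMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(REVCOMP)[::-1]


class TestConvertReference:
    @pytest.mark.parametrize(
        "seq, converted, cpg, noncpg",
        [
            ("ACGT", "ACGT", (1,), ()),
            ("ACCA", "ATTA", (), (1, 2)),
            ("TTCGCCG", "TTCGTCG", (2, 5), (4,)),
            ("CGCG", "CGCG", (0, 2), ()),
            ("CCCC", "TTTT", (), (0, 1, 2, 3)),  # terminal C converts too
        ],
    )
    def test_conversion_rule(self, seq, converted, cpg, noncpg):
        ref = convert_reference("r", seq)
        assert ref.converted == converted
        assert ref.cpg_positions == cpg
        assert ref.noncpg_c_positions == noncpg

    def test_partition_of_cytosines(self):
        ref = convert_reference("r", "CTCGACCGTCAC")
        all_c = {i for i, b in enumerate(ref.original) if b == "C"}
        assert set(ref.cpg_positions) | set(ref.noncpg_c_positions) == all_c
        assert set(ref.cpg_positions) & set(ref.noncpg_c_positions) == set()

    def test_converted_differs_only_at_noncpg(self):
        ref = convert_reference("r", "CTCGACCGTCAC")
        diff = {i for i, (a, b) in enumerate(zip(ref.original, ref.converted)) if a != b}
        assert diff == set(ref.noncpg_c_positions)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            convert_reference("r", "A")


class TestPairwiseAlign:
    def test_identity(self):
        aln = pairwise_align("ACGT", "ACGT")
        assert "-" not in aln.ref_gapped + aln.read_gapped
        assert aln.ref_gapped == aln.read_gapped == "ACGT"

    def test_single_deletion_against_bruteforce(self):
        # unit costs: linear gaps, one deletion column is optimal
        params = AlignParams(match=1, mismatch=-1, gap_open=0, gap_extend=-1)
        ours = pairwise_align("ACGT", "AGT", params)
        best, optima = best_alignments_bruteforce("ACGT", "AGT")
        assert ours.score == best
        assert (ours.ref_gapped, ours.read_gapped) in optima
        assert ours.read_gapped == "A-GT"

    def test_tie_broken_leftmost(self):
        # leading and trailing end gaps tie; the leftmost placement wins
        params = AlignParams(match=1, mismatch=-1, gap_open=0, gap_extend=-1)
        ours = pairwise_align("AAA", "AA", params)
        best, optima = best_alignments_bruteforce("AAA", "AA")
        assert ours.score == best
        assert ours.read_gapped == "-AA"

    def test_read_t_matches_reference_cpg_c(self):
        # converted reference keeps C only at CpGs; a read T there is no mismatch
        aln_t = pairwise_align("ACGT", "ATGT")
        aln_c = pairwise_align("ACGT", "ACGT")
        assert aln_t.score == aln_c.score

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("A", "")

    def test_row_invariants(self):
        aln = pairwise_align("ACGTACGT", "ACGACG")
        assert aln.ref_ungapped == "ACGTACGT"
        assert aln.read_ungapped == "ACGACG"
        assert not any(
            a == b == "-" for a, b in zip(aln.ref_gapped, aln.read_gapped)
        )


class TestOrientAndTrim:
    def test_forward_identity(self, small_ref):
        read, orientation, aln = orient_and_trim("r1", small_ref.converted, small_ref)
        assert orientation == "forward"
        assert read == small_ref.converted

    def test_reverse_with_vector_prefix_trimmed(self, small_ref):
        insert = rc(small_ref.converted)
        read = "GTGTGTGTGTGTGTGTGTGT" + insert  # 20 nt vector prefix
        oriented, orientation, aln = orient_and_trim("r1", read, small_ref)
        assert orientation == "reverse"
        assert oriented == small_ref.converted

    def test_unrelated_sequence_flagged(self, small_ref):
        with pytest.raises(UnalignableReadError):
            orient_and_trim("junk", "GGGGGGGGGGGGGGGGGGGGGG", small_ref)

    def test_orientation_involutive(self):
        ref = convert_reference("r", "ACGTTACGGATCCGATTACGCATG")
        read = ref.converted
        fwd, _, _ = orient_and_trim("a", read, ref)
        rev, _, _ = orient_and_trim("b", rc(read), ref)
        assert fwd == rev


class TestBuildAlignment:
    def _orient(self, ref, seqs):
        out = []
        for i, s in enumerate(seqs):
            _, orientation, aln = orient_and_trim(f"r{i}", s, ref)
            out.append(OrientedRead(f"r{i}", orientation, aln))
        return out

    def test_rows_ungap_to_trimmed_reads(self):
        ref = convert_reference("r", "ACGTTACGGATCCGATTACG")
        seqs = [ref.converted, ref.converted[3:15], ref.converted[:10] + "T" + ref.converted[10:]]
        oriented = self._orient(ref, seqs)
        aln = build_alignment(oriented, ref, mode="stitched")
        for o, row in zip(oriented, aln.rows):
            assert row.ungapped == o.alignment.read_ungapped
        assert aln.reference_row.replace("-", "") == ref.converted

    def test_insertion_opens_shared_gap_column(self):
        ref = convert_reference("r", "ACGTTACGGATCCGATTACG")
        with_ins = ref.converted[:10] + "A" + ref.converted[10:]
        oriented = self._orient(ref, [ref.converted, with_ins])
        aln = build_alignment(oriented, ref, mode="stitched")
        assert len(aln.reference_row) == ref.length + 1
        assert aln.reference_row.count("-") == 1

    def test_auto_selects_stitched_without_tstretch(self):
        ref = convert_reference("r", "ACGAGAGACGAGAGAGACGA")
        assert not needs_msa_fallback(ref)
        oriented = self._orient(ref, [ref.converted])
        assert build_alignment(oriented, ref, mode="auto").mode == "stitched"

    def test_auto_selects_msa_for_terminal_tstretch_cpg(self):
        # CpG 2 bp from the 3' end immediately behind a 5-T stretch
        ref = convert_reference("r", "AGAGAGAGAGAGATTTTTCG")
        assert needs_msa_fallback(ref)
        oriented = self._orient(ref, [ref.converted])
        assert build_alignment(oriented, ref, mode="auto").mode == "msa"

    def test_conversion_creates_tstretch_triggering_fallback(self):
        # CCTTC near the end converts to TTTTT in front of the terminal CpG
        ref = convert_reference("r", "AGAGAGAGAGAGACCTTCCGA")
        assert ref.converted.endswith("TTTTTCGA")
        assert needs_msa_fallback(ref)

    def test_forced_mode_overrides_rule(self):
        ref = convert_reference("r", "ACGAGAGACGAGAGAGACGA")
        oriented = self._orient(ref, [ref.converted])
        assert build_alignment(oriented, ref, mode="msa").mode == "msa"


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_rows_ungap_to_trimmed_reads_on_simulated_data(seed):
    """Every frame row recovers its oriented trimmed read exactly."""
    cfg = SimConfig(seed=seed, ref_length=120, n_cpg=6, n_clones=3)
    _, seq = simulate_reference(cfg)
    reads, _ = simulate_reads(seq, cfg)
    ref = convert_reference("r", seq)
    oriented = []
    for r in reads:
        trimmed, orientation, aln = orient_and_trim(r.read_id, r.sequence, ref)
        assert aln.read_ungapped == trimmed
        oriented.append(OrientedRead(r.read_id, orientation, aln))
    frame = build_alignment(oriented, ref, mode="stitched")
    for o, row in zip(oriented, frame.rows):
        assert row.ungapped == o.alignment.read_ungapped
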