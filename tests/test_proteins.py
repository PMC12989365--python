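import random

import pytest
from hypothesis import given, settings, strategies as st

from micapop.proteins import (
    build_alignment,
    classify_aa129,
    detect_null,
    group_by_nearest_frequent,
    variant_matrix,
)

from conftest import a  # noqa: F401  (kept for symmetry with other modules)

# varied 20-residue toy reference (no repeats that could shift gap placement)
TOY_REF = "MKVLATCEWGQDNHRFYPSI"


def mutate(seq, pos, new):
    return seq[:pos] + new + seq[pos + 1 :]


class TestBuildAlignment:
    def test_identical_sequences(self):
        aln = build_alignment({"R": TOY_REF, "S": TOY_REF}, "R")
        assert aln.rows["R"] == aln.rows["S"] == TOY_REF
        assert all(not c.is_insertion for c in aln.columns)

    def test_single_substitution(self):
        aln = build_alignment({"R": TOY_REF, "S": mutate(TOY_REF, 7, "A")}, "R")
        diffs = [i for i, (x, y) in enumerate(zip(aln.rows["R"], aln.rows["S"])) if x != y]
        assert diffs == [7]

    def test_internal_three_residue_deletion(self):
        # hand-scored oracle: ungapped flanks + one 3-column gap is optimal
        deleted = TOY_REF[:8] + TOY_REF[11:]
        aln = build_alignment({"R": TOY_REF, "S": deleted}, "R")
        assert aln.rows["R"] == TOY_REF
        assert aln.rows["S"] == TOY_REF[:8] + "---" + TOY_REF[11:]

    def test_insertion_tagged_not_renumbered(self):
        inserted = TOY_REF[:10] + "WW" + TOY_REF[10:]
        aln = build_alignment({"R": TOY_REF, "S": inserted}, "R")
        ins_cols = [c for c in aln.columns if c.is_insertion]
        assert len(ins_cols) == 2
        # mature numbering of reference columns is untouched
        ref_positions = [c.position for c in aln.columns if not c.is_insertion]
        assert ref_positions == list(range(1, len(TOY_REF) + 1))
        idx = aln.columns.index(ins_cols[0])
        assert aln.rows["R"][idx] == "-"
        assert aln.rows["S"][idx] == "W"

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            build_alignment({"S": TOY_REF}, "R")

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            build_alignment({"R": TOY_REF, "S": "MKV1"}, "R")

    def test_idempotence_on_identical_inputs(self):
        aln1 = build_alignment({"R": TOY_REF, "S": TOY_REF, "T": TOY_REF}, "R")
        aln2 = build_alignment(dict(aln1.rows), "R")
        assert aln2.rows == aln1.rows


class TestVariantMatrix:
    def test_reference_has_no_variants(self):
        aln = build_alignment({"R": TOY_REF, "S": mutate(TOY_REF, 3, "W")}, "R")
        vm = variant_matrix(aln)
        assert vm.variants["R"] == []

    def test_planted_substitutions_counted(self):
        mutated = TOY_REF
        for pos, new in [(2, "A"), (5, "H"), (9, "D"), (13, "W"), (17, "C")]:
            mutated = mutate(mutated, pos, new)
        aln = build_alignment({"R": TOY_REF, "S": mutated}, "R")
        vm = variant_matrix(aln)
        assert len(vm.variants["S"]) == 5
        assert [v.position for v in vm.variants["S"]] == [3, 6, 10, 14, 18]

    def test_deletion_reported_with_gap_symbol(self):
        deleted = TOY_REF[:8] + TOY_REF[11:]
        aln = build_alignment({"R": TOY_REF, "S": deleted}, "R")
        vm = variant_matrix(aln)
        gaps = [v for v in vm.variants["S"] if v.alt_symbol == "-"]
        assert [v.position for v in gaps] == [9, 10, 11]

    def test_variant_count_equals_hamming(self):
        rng = random.Random(23)
        residues = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            mutated = "".join(
                rng.choice(residues) if rng.random() < 0.2 else ch for ch in TOY_REF
            )
            aln = build_alignment({"R": TOY_REF, "S": mutated}, "R")
            vm = variant_matrix(aln)
            expected = sum(1 for x, y in zip(aln.rows["R"], aln.rows["S"]) if x != y)
            assert len(vm.variants["S"]) == expected


def with_position_129(symbol):
    """A 140-residue toy whose mature position 129 carries `symbol`."""
    base = (TOY_REF * 7)[:140]
    return base[:128] + symbol + base[129:]


class TestAA129:
    def test_met(self):
        aln = build_alignment(
            {"R": with_position_129("M"), "S": with_position_129("M")}, "R"
        )
        assert classify_aa129(aln)["S"] == "Met"

    def test_val_backbone(self):
        ref = with_position_129("M")
        aln = build_alignment({"R": ref, "S": with_position_129("V")}, "R")
        out = classify_aa129(aln)
        assert out == {"R": "Met", "S": "Val"}

    def test_met_exception_on_val_backbone(self):
        # an allele nearly identical to a Val-129 backbone but carrying Met
        val_allele = with_position_129("V")
        met_variant = mutate(val_allele, 128, "M")
        aln = build_alignment({"R": val_allele, "S": met_variant}, "R")
        assert classify_aa129(aln) == {"R": "Val", "S": "Met"}

    def test_other_for_gap(self):
        ref = with_position_129("M")
        deleted = ref[:126] + ref[132:]  # 6-residue deletion spanning 129
        aln = build_alignment({"R": ref, "S": deleted}, "R")
        assert classify_aa129(aln)["S"] == "other"

    def test_missing_column_rejected(self):
        aln = build_alignment({"R": TOY_REF, "S": TOY_REF}, "R")
        with pytest.raises(KeyError):
            classify_aa129(aln)


# toy CDS: ATG + distinct codons, stop at the end; exons on the reference
TOY_CDS = "ATGGAATGCCTGAAACGTGATTTCGGTCATCCAGTTTGGTAA"
TOY_EXONS = [(0, 9), (9, 21), (21, 33), (33, 42)]


class TestDetectNull:
    def test_single_base_deletion_exon2(self):
        q = TOY_CDS[:10] + TOY_CDS[11:]
        result = detect_null(q, TOY_CDS, TOY_EXONS)
        assert result == (True, "frameshift", 2)

    def test_two_base_deletion_frameshift(self):
        q = TOY_CDS[:22] + TOY_CDS[24:]
        result = detect_null(q, TOY_CDS, TOY_EXONS)
        assert result.mechanism == "frameshift"
        assert result.exon == 3

    def test_single_base_insertion_frameshift(self):
        q = TOY_CDS[:12] + "A" + TOY_CDS[12:]
        result = detect_null(q, TOY_CDS, TOY_EXONS)
        assert result.mechanism == "frameshift"
        assert result.exon == 2

    def test_in_frame_deletion_not_null(self):
        q = TOY_CDS[:12] + TOY_CDS[15:]
        assert detect_null(q, TOY_CDS, TOY_EXONS) == (False, "none", None)

    def test_premature_stop_exon3(self):
        # translate-by-hand oracle: codon 8 (nt 24-26) -> TAA, inside exon 3
        q = TOY_CDS[:24] + "TAA" + TOY_CDS[27:]
        result = detect_null(q, TOY_CDS, TOY_EXONS)
        assert result == (True, "premature_stop", 3)

    def test_reference_itself_clean(self):
        assert detect_null(TOY_CDS, TOY_CDS, TOY_EXONS).mechanism == "none"

    def test_empty_cds_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_null("", TOY_CDS, TOY_EXONS)

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            detect_null("ATGXYZ", TOY_CDS, TOY_EXONS)

    @given(
        pos=st.integers(3, len(TOY_CDS) - 4),
        width=st.integers(1, 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_short_indels_always_frameshift(self, pos, width):
        deletion = TOY_CDS[:pos] + TOY_CDS[pos + width :]
        assert detect_null(deletion, TOY_CDS, TOY_EXONS).mechanism == "frameshift"

    @given(codons=st.integers(1, 3), pos=st.sampled_from([3, 9, 15, 21, 27]))
    @settings(max_examples=30, deadline=None)
    def test_in_frame_stop_free_insertions_never_null(self, codons, pos):
        insert = "GCT" * codons  # alanines: cannot create a stop at codon joints
        q = TOY_CDS[:pos] + insert + TOY_CDS[pos:]
        assert not detect_null(q, TOY_CDS, TOY_EXONS).is_null


class TestGrouping:
    def build(self):
        frequent_a = TOY_REF
        frequent_b = mutate(mutate(mutate(TOY_REF, 2, "W"), 8, "H"), 14, "D")
        near_a = mutate(TOY_REF, 5, "N")
        return build_alignment(
            {"FA": frequent_a, "FB": frequent_b, "X": near_a}, "FA"
        )

    def test_frequent_allele_groups_to_itself(self):
        out = group_by_nearest_frequent(self.build(), ["FA", "FB"])
        assert out["FA"].label == "FA"
        assert out["FA"].distance == 0
        assert out["FB"].label == "FB"

    def test_single_substitution_groups_to_nearest(self):
        out = group_by_nearest_frequent(self.build(), ["FA", "FB"])
        assert out["X"].label == "FA"
        assert out["X"].distance == 1
        assert not out["X"].tie

    def test_equidistant_tie_flagged(self):
        frequent_a = TOY_REF
        frequent_b = mutate(mutate(TOY_REF, 2, "W"), 8, "H")
        midpoint = mutate(TOY_REF, 2, "W")  # distance 1 from both
        aln = build_alignment({"FA": frequent_a, "FB": frequent_b, "X": midpoint}, "FA")
        out = group_by_nearest_frequent(aln, ["FA", "FB"])
        assert out["X"].tie
        assert out["X"].label == "FA"  # lexicographically smallest

    def test_row_order_invariant(self):
        aln = self.build()
        out1 = group_by_nearest_frequent(aln, ["FA", "FB"])
        reordered = type(aln)(
            reference_id=aln.reference_id,
            columns=aln.columns,
            rows=dict(reversed(list(aln.rows.items()))),
        )
        out2 = group_by_nearest_frequent(reordered, ["FB", "FA"])
        assert out1 == out2

    def test_empty_frequent_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_by_nearest_frequent(self.build(), [])

    def test_unknown_frequent_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            group_by_nearest_frequent(self.build(), ["NOPE"])
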