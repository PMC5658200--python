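"""Helix maps, canonical folding with the closure rule, variability."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrnhet import (
    HelixMap,
    default_16s_helix_map,
    find_signature,
    fold_helix,
    helix_variability,
    map_columns_to_model,
)
from rrnhet.rrna_structure import Helix, dot_bracket
from conftest import make_alignment

STRAND = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestFoldHelix:
    def test_fully_canonical_rna_strands(self):
        # G:C, G:C, C:G, A:U, U:A reading antiparallel
        assert fold_helix("GGCAU", "AUGCC") == [True] * 5

    def test_non_canonical_positions_unpaired(self):
        mask = fold_helix("GGCAA", "AUGCC")
        assert mask == [True, True, True, True, False]

    def test_wobble_counts_as_canonical_by_default(self):
        assert fold_helix("G", "T") == [True]
        assert fold_helix("G", "T", wobble=False) == [False]

    def test_reference_mismatch_closed_when_canonical(self):
        # position 3 is a model mismatch; target holds G opposite C
        mask = fold_helix("AAGAA", "TTCTT", reference_mismatch_positions={3})
        assert mask[2] is True

    def test_reference_mismatch_not_closed_when_non_canonical(self):
        mask = fold_helix("AAAAA", "TTATT", reference_mismatch_positions={3})
        assert mask[2] is False

    def test_too_many_closures_leaves_all_open(self):
        # three closable model mismatches exceed the default budget of 2
        mask = fold_helix("GGG", "CCC", reference_mismatch_positions={1, 2, 3})
        assert mask == [False, False, False]
        assert fold_helix("GGG", "CCC", reference_mismatch_positions={1, 2}) == [
            True,
            True,
            True,
        ]

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            fold_helix("AAA", "TT")

    @settings(max_examples=60, deadline=None)
    @given(STRAND, STRAND, st.sets(st.integers(1, 8), max_size=3))
    def test_zero_budget_reduces_to_plain_canonical_mask(self, s5, s3, ref):
        n = min(len(s5), len(s3))
        s5, s3 = s5[:n], s3[:n]
        ref = {p for p in ref if p <= n}
        plain = fold_helix(s5, s3)
        with_rule = fold_helix(s5, s3, reference_mismatch_positions=ref, max_closable=0)
        assert [m for i, m in enumerate(with_rule, 1) if i not in ref] == [
            m for i, m in enumerate(plain, 1) if i not in ref
        ]
        assert all(not with_rule[p - 1] for p in ref)

    def test_dot_bracket_export(self):
        assert dot_bracket("GGC", "GCC", [True, True, False]) == "((.....))"


class TestHelixMap:
    def test_tsv_round_trip(self, tmp_path):
        hmap = default_16s_helix_map()
        p = tmp_path / "map.tsv"
        hmap.to_tsv(p)
        back = HelixMap.from_tsv(p)
        assert back.length == hmap.length
        assert back.helices == hmap.helices

    def test_overlapping_helices_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            HelixMap(
                molecule="16S",
                length=100,
                helices=[
                    Helix("H1", (1, 5), (20, 24)),
                    Helix("H2", (4, 8), (30, 34)),
                ],
            )

    def test_helix_of_lookup(self):
        hmap = HelixMap("16S", 50, [Helix("H1", (5, 8), (15, 18))])
        assert hmap.helix_of(6) == "H1"
        assert hmap.helix_of(16) == "H1"
        assert hmap.helix_of(10) is None


class TestColumnMapping:
    def test_gapless_model_row_is_identity(self):
        hmap = HelixMap("16S", 4, [Helix("H1", (1, 1), (4, 4))])
        aln = make_alignment({"m": "ACGT", "x": "ACGA"})
        colmap = map_columns_to_model(aln, "m", hmap)
        assert colmap.model_position == {1: 1, 2: 2, 3: 3, 4: 4}
        assert colmap.insertion_after == {}

    def test_model_gap_becomes_insertion_column(self):
        hmap = HelixMap("16S", 4, [Helix("H1", (1, 1), (4, 4))])
        aln = make_alignment({"m": "AC-GT", "x": "ACAGT"})
        colmap = map_columns_to_model(aln, "m", hmap)
        assert colmap.insertion_after == {3: 2}
        assert colmap.model_position == {1: 1, 2: 2, 4: 3, 5: 4}

    def test_wrong_model_length_errors(self):
        hmap = HelixMap("16S", 10, [Helix("H1", (1, 2), (9, 10))])
        aln = make_alignment({"m": "ACGT", "x": "ACGT"})
        with pytest.raises(ValueError, match="expects 10"):
            map_columns_to_model(aln, "m", hmap)


def two_type_alignment(t1_row: str, t2_row: str):
    return make_alignment(
        {"t1_a": t1_row, "t1_b": t1_row, "t2_a": t2_row, "t2_b": t2_row}
    ), {"t1_a": "Type1", "t1_b": "Type1", "t2_a": "Type2", "t2_b": "Type2"}


class TestHelixVariability:
    # model: positions 1-20; H9 pairs 3-6 with 13-16
    HMAP = HelixMap("16S", 20, [Helix("H9", (3, 6), (13, 16))])

    def test_identical_consensuses_all_zero(self):
        row = "ATGCATTAGCATGCATTAGC"
        aln, labels = two_type_alignment(row, row)
        sig = find_signature(aln, labels)
        colmap = map_columns_to_model(aln, "t2_a", self.HMAP)
        comp = helix_variability(aln, labels, sig, self.HMAP, colmap)
        h = comp.per_helix["H9"]
        assert (h.substitutions, h.insertions, h.deletions) == (0, 0, 0)
        assert comp.unpaired_region_changes == 0

    def test_substitution_inside_strand5_attributed_to_helix(self):
        t2 = "ATGCATTAGCATGCATTAGC"
        t1 = t2[:3] + "G" + t2[4:]  # column 4 sits in H9's 5' strand
        aln, labels = two_type_alignment(t1, t2)
        sig = find_signature(aln, labels)
        assert sig.columns == [4]
        colmap = map_columns_to_model(aln, "t2_a", self.HMAP)
        comp = helix_variability(aln, labels, sig, self.HMAP, colmap)
        assert comp.per_helix["H9"].substitutions == 1
        assert comp.unpaired_region_changes == 0

    def test_unpaired_substitution_counted_separately(self):
        t2 = "ATGCATTAGCATGCATTAGC"
        t1 = t2[:9] + "A" + t2[10:]  # column 10 is between the strands
        aln, labels = two_type_alignment(t1, t2)
        sig = find_signature(aln, labels)
        colmap = map_columns_to_model(aln, "t2_a", self.HMAP)
        comp = helix_variability(aln, labels, sig, self.HMAP, colmap)
        assert comp.per_helix["H9"].substitutions == 0
        assert comp.unpaired_region_changes == 1

    def test_insertion_in_helix_flags_structure_change(self):
        # Type1 carries a 4-base insertion inside H9's 5' strand
        t2 = "AT" + "GGCA" + "TTAGCA" + "TGCC" + "ATTA"
        t2_aln = t2[:4] + "----" + t2[4:]
        t1_aln = t2[:4] + "AAAA" + t2[4:]
        aln, labels = two_type_alignment(t1_aln, t2_aln)
        sig = find_signature(aln, labels)
        colmap = map_columns_to_model(aln, "t2_a", self.HMAP)
        comp = helix_variability(aln, labels, sig, self.HMAP, colmap)
        assert comp.per_helix["H9"].insertions == 4
        assert comp.per_helix["H9"].structure_altering is True

    def test_assignment_conservation(self, clean_dataset):
        ds = clean_dataset
        aln = ds.alignment_16s
        labels = ds.labels
        sig = find_signature(aln, labels)
        model_row = next(r.id for r in aln if labels[r.id] == "Type2")
        colmap = map_columns_to_model(aln, model_row, ds.helix_map)
        comp = helix_variability(aln, labels, sig, ds.helix_map, colmap)
        # gapless synthetic alignment: no indel columns, so assignments
        # must sum to the number of signature positions
        assert comp.total_assigned == len(sig)

    def test_recovers_planted_helix_counts(self, clean_dataset):
        ds = clean_dataset
        aln = ds.alignment_16s
        sig = find_signature(aln, ds.labels)
        model_row = next(r.id for r in aln if ds.labels[r.id] == "Type2")
        colmap = map_columns_to_model(aln, model_row, ds.helix_map)
        comp = helix_variability(aln, ds.labels, sig, ds.helix_map, colmap)
        planted = {}
        for entry in ds.truth.signature_16s:
            planted[entry["helix"]] = planted.get(entry["helix"], 0) + 1
        observed = {
            h.helix: h.substitutions
            for h in comp.per_helix.values()
            if h.substitutions
        }
        assert observed == planted
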