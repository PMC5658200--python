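"""Signature derivation, typing, reversions and primer windows."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrnhet import (
    best_primer,
    classify_sequence,
    design_type_primers,
    detect_reversions,
    find_signature,
)
from conftest import make_alignment


def labels_for(aln, type1_prefix="t1"):
    return {
        r.id: ("Type1" if r.id.startswith(type1_prefix) else "Type2") for r in aln
    }


def brute_force_signature(rows1, rows2, threshold):
    """Independent column-by-column re-derivation."""
    width = len(rows1[0])
    out = []
    for col in range(width):
        sig = []
        for rows in (rows1, rows2):
            bases = [r[col] for r in rows if r[col] in "ACGT"]
            if not bases:
                sig = None
                break
            counts = Counter(bases)
            top = max(counts.values())
            base = min(b for b, c in counts.items() if c == top)
            if top / len(bases) < threshold:
                sig = None
                break
            sig.append(base)
        if sig and sig[0] != sig[1]:
            out.append((col + 1, sig[0], sig[1]))
    return out


class TestFindSignature:
    def test_single_diagnostic_column(self):
        aln = make_alignment(
            {"t1_a": "AAGT", "t1_b": "AAGT", "t1_c": "AAGT",
             "t2_a": "AAAT", "t2_b": "AAAT", "t2_c": "AAAT"}
        )
        sig = find_signature(aln, labels_for(aln))
        assert len(sig) == 1
        p = sig.positions[0]
        assert (p.position, p.consensus_type1, p.consensus_type2) == (3, "G", "A")
        assert p.saturation_type1 == p.saturation_type2 == 1.0

    def test_identical_groups_give_empty_signature(self):
        aln = make_alignment(
            {"t1_a": "ACGT", "t1_b": "ACGT", "t2_a": "ACGT", "t2_b": "ACGT"}
        )
        assert len(find_signature(aln, labels_for(aln))) == 0

    def test_low_saturation_column_excluded(self):
        aln = make_alignment(
            {"t1_a": "AAGT", "t1_b": "AAAT", "t1_c": "AAGT",
             "t2_a": "AAAT", "t2_b": "AAAT", "t2_c": "AAAT"}
        )
        # Type1 saturation at column 3 is 2/3 < 0.85
        assert len(find_signature(aln, labels_for(aln), 0.85)) == 0

    def test_missing_residues_excluded_from_denominator(self):
        aln = make_alignment(
            {"t1_a": "AAGT", "t1_b": "AA-T", "t1_c": "AANT",
             "t2_a": "AAAT", "t2_b": "AAAT", "t2_c": "AAAT"}
        )
        sig = find_signature(aln, labels_for(aln))
        assert sig.columns == [3]
        assert sig.positions[0].saturation_type1 == 1.0  # 1/1 scorable

    def test_missing_type_errors(self):
        aln = make_alignment({"t2_a": "ACGT", "t2_b": "ACGT"})
        with pytest.raises(ValueError, match="Type1"):
            find_signature(aln, labels_for(aln))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6, size=2)
        width = int(rng.integers(5, 50))
        alpha = list("ACGT-N")
        rows = {
            f"t1_{i}": "".join(rng.choice(alpha, size=width)) for i in range(n1)
        } | {f"t2_{i}": "".join(rng.choice(alpha, size=width)) for i in range(n2)}
        aln = make_alignment(rows)
        sig = find_signature(aln, labels_for(aln), 0.85)
        expected = brute_force_signature(
            [rows[f"t1_{i}"] for i in range(n1)],
            [rows[f"t2_{i}"] for i in range(n2)],
            0.85,
        )
        assert [
            (p.position, p.consensus_type1, p.consensus_type2) for p in sig.positions
        ] == expected


@pytest.fixture()
def toy_signature():
    aln = make_alignment(
        {"t1_a": "AAGTC", "t1_b": "AAGTC", "t2_a": "AAATG", "t2_b": "AAATG"}
    )
    return aln, find_signature(aln, labels_for(aln))


class TestClassify:
    def test_perfect_type1_match(self, toy_signature):
        _, sig = toy_signature
        score = classify_sequence("AAGTC", sig)
        assert (score.frac_type1, score.frac_type2, score.frac_other) == (100, 0, 0)
        assert score.call == "Type1"

    def test_half_match_half_other(self, toy_signature):
        _, sig = toy_signature
        # signature columns are 3 and 5; G matches Type1, T matches neither
        score = classify_sequence("AAGTT", sig)
        assert (score.frac_type1, score.frac_type2, score.frac_other) == (50, 0, 50)

    def test_missing_positions_dropped_from_denominator(self, toy_signature):
        _, sig = toy_signature
        score = classify_sequence("AAGT-", sig)
        assert score.n_scored == 1
        assert (score.frac_type1, score.frac_type2, score.frac_other) == (100, 0, 0)

    def test_all_missing_errors(self, toy_signature):
        _, sig = toy_signature
        with pytest.raises(ValueError, match="missing"):
            classify_sequence("AA-T-", sig)

    def test_length_mismatch_errors(self, toy_signature):
        _, sig = toy_signature
        with pytest.raises(ValueError, match="width"):
            classify_sequence("AAGT", sig)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(1, 30), st.integers(0, 2**31 - 1))
    def test_fractions_sum_to_100(self, n_sig, seed):
        rng = np.random.default_rng(seed)
        t1 = "".join(rng.choice(list("ACGT"), size=n_sig))
        t2 = "".join(
            {"A": "C", "C": "G", "G": "T", "T": "A"}[b] for b in t1
        )
        rows = {"t1_a": t1, "t1_b": t1, "t2_a": t2, "t2_b": t2}
        aln = make_alignment(rows)
        sig = find_signature(aln, labels_for(aln))
        query = "".join(rng.choice(list("ACGT"), size=n_sig))
        score = classify_sequence(query, sig)
        assert score.frac_type1 + score.frac_type2 + score.frac_other == 100


class TestReversions:
    def test_consistent_alignment_has_none(self, toy_signature):
        aln, sig = toy_signature
        assert detect_reversions(aln, labels_for(aln), sig) == []

    def test_single_reversion_flagged(self):
        aln = make_alignment(
            {"t1_a": "AAGTC", "t1_b": "AAGTC", "t1_c": "AAATC",
             "t2_a": "AAATG", "t2_b": "AAATG"}
        )
        sig = find_signature(aln, labels_for(aln), 0.6)
        assert sig.columns == [3, 5]
        hits = detect_reversions(aln, labels_for(aln), sig)
        assert len(hits) == 1
        (rev,) = hits
        assert rev.position == 3
        assert rev.from_type == "Type1"
        assert rev.seq_ids == ("t1_c",)
        assert rev.observed_base == "A"


class TestPrimers:
    def make_divergent_alignment(self, n_mismatch):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), size=40))
        other = list(base)
        # plant mismatches inside the window 11..30
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for k in range(n_mismatch):
            col = 12 + 4 * k
            other[col] = swap[other[col]]
        t2 = "".join(other)
        return make_alignment(
            {"t1_a": base, "t1_b": base, "t2_a": t2, "t2_b": t2}
        )

    def test_qualifying_window_found(self):
        aln = self.make_divergent_alignment(4)
        windows = design_type_primers(aln, labels_for(aln), (20, 20), 3)
        starts = {(w.start, w.end) for w in windows if w.target_type == "Type1"}
        assert (11, 30) in starts
        w = next(x for x in windows if (x.start, x.end) == (11, 30) and x.target_type == "Type1")
        assert w.cross_mismatches == 4
        # reverse primer is the reverse complement of the Type1 window
        t1_window = aln["t1_a"].residues[10:30]
        comp = str.maketrans("ACGT", "TGCA")
        assert w.primer == t1_window.translate(comp)[::-1]

    def test_identical_types_give_no_windows(self):
        aln = make_alignment(
            {"t1_a": "ACGT" * 10, "t1_b": "ACGT" * 10,
             "t2_a": "ACGT" * 10, "t2_b": "ACGT" * 10}
        )
        assert design_type_primers(aln, labels_for(aln), (20, 20), 3) == []

    def test_too_few_cross_mismatches_excluded(self):
        aln = self.make_divergent_alignment(1)
        windows = design_type_primers(aln, labels_for(aln), (20, 20), 3)
        assert all(w.cross_mismatches >= 3 for w in windows)
        assert not any(
            w.start <= 13 <= w.end and w.cross_mismatches < 3 for w in windows
        )

    def test_windows_with_gaps_or_within_type_variation_excluded(self):
        aln = make_alignment(
            {"t1_a": "AAAAAAAAAAAAAAAAAAAAAAAAA",
             "t1_b": "AAAAAAAAAAAAAAAAAAAAAAAAT",
             "t2_a": "CCCCCCCCCCCCCCCCCCCC-CCCC",
             "t2_b": "CCCCCCCCCCCCCCCCCCCC-CCCC"}
        )
        windows = design_type_primers(aln, labels_for(aln), (20, 20), 3)
        # the Type2 gap at column 21 blocks every window crossing it (as
        # target and as cross-consensus), and the within-Type1 variation
        # at column 25 blocks Type1 windows reaching it: only the
        # leftmost window survives, for each type
        assert {(w.start, w.end) for w in windows} == {(1, 20)}
        assert {w.target_type for w in windows} == {"Type1", "Type2"}

    def test_best_primer_ranking(self):
        aln = self.make_divergent_alignment(4)
        windows = design_type_primers(aln, labels_for(aln), (20, 22), 3)
        best = best_primer(windows, "Type1")
        assert best is not None
        assert best.cross_mismatches == max(
            w.cross_mismatches for w in windows if w.target_type == "Type1"
        )
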