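"""Alignment, indel normalization, clone classification, cohort summary."""

import numpy as np
import pytest
from Bio import Align

from nhejscope import (
    CloneSequence,
    ReferenceAmplicon,
    ScoringScheme,
    apply_calls,
    call_edits,
    global_align,
    left_align_calls,
    normalize_indels,
    summarize_cohort,
)
from nhejscope.errors import NhejscopeError, SequenceError
from nhejscope.indelcall import DEFAULT_SCORING, INDEL_FAITHFUL_SCORING, IndelCall


def _rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _biopython_score(ref, query, s: ScoringScheme) -> float:
    """Independent optimal-score oracle (Biopython's global aligner with the
    same affine costs: first gap base costs open+extend)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = s.match
    aligner.mismatch_score = s.mismatch
    aligner.open_gap_score = s.gap_open + s.gap_extend
    aligner.extend_gap_score = s.gap_extend
    return float(aligner.score(ref, query))


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.ref_row == aln.query_row == "ACGTACGT"
        assert aln.score == 2.0 * 8

    def test_single_deletion(self):
        aln = global_align("ACGTACGT", "ACGACGT")
        assert aln.query_row.count("-") == 1
        assert aln.ref_row.count("-") == 0
        assert aln.score == 7 * 2.0 - 6.0

    def test_all_mismatch_preferred_over_gaps(self):
        """Under the default scheme three substitutions beat a 3-nt
        deletion plus 3-nt insertion."""
        aln = global_align("AAA", "TTT")
        assert "-" not in aln.ref_row and "-" not in aln.query_row
        assert aln.score == 3 * -3.0

    def test_empty_input_rejected(self):
        with pytest.raises(SequenceError):
            global_align("", "ACGT")

    @pytest.mark.parametrize("scoring", [DEFAULT_SCORING, INDEL_FAITHFUL_SCORING])
    def test_score_matches_independent_aligner(self, rng, scoring):
        """Optimal score agrees with Biopython's aligner on random pairs."""
        for _ in range(30):
            ref = _rand_dna(rng, int(rng.integers(5, 40)))
            query = _rand_dna(rng, int(rng.integers(5, 40)))
            aln = global_align(ref, query, scoring)
            assert aln.score == pytest.approx(_biopython_score(ref, query, scoring))

    def test_self_score_is_maximal(self, rng):
        """score(ref, ref) >= score(ref, q) for random q of equal length."""
        ref = _rand_dna(rng, 30)
        best = global_align(ref, ref).score
        for _ in range(50):
            q = _rand_dna(rng, 30)
            assert global_align(ref, q).score <= best

    def test_rows_reconstruct_inputs(self, rng):
        ref, query = _rand_dna(rng, 25), _rand_dna(rng, 22)
        aln = global_align(ref, query)
        assert aln.ref == ref and aln.query == query


class TestNormalizeIndels:
    def test_repeat_deletion_left_aligned(self):
        """A 2-nt deletion in a TTT tract is placed at the leftmost T."""
        calls = normalize_indels(global_align("AAATTTCCC", "AAATCCC"))
        assert [str(c) for c in calls] == ["del:3-5"]

    def test_no_gaps_empty(self):
        assert normalize_indels(global_align("ACGT", "ACGT")) == []

    def test_unique_placement_unchanged(self):
        ref, clone = "AAACGTCCC", "AAACCC"
        calls = normalize_indels(global_align(ref, clone))
        assert [str(c) for c in calls] == ["del:3-6"]
        assert apply_calls(ref, calls) == clone

    def test_left_alignment_is_canonical(self, rng):
        """Shifting any reported deletion one base left changes the implied
        sequence (otherwise the placement was not canonical)."""
        for _ in range(50):
            ref = _rand_dna(rng, 40)
            s = int(rng.integers(5, 30))
            L = int(rng.integers(1, 6))
            clone = ref[:s] + ref[s + L:]
            calls = normalize_indels(global_align(ref, clone, INDEL_FAITHFUL_SCORING))
            assert len(calls) == 1 and calls[0].kind == "deletion"
            c = calls[0]
            assert apply_calls(ref, calls) == clone
            if c.start > 0:
                shifted = [IndelCall("deletion", c.start - 1, c.end - 1)]
                assert apply_calls(ref, shifted) != clone

    def test_left_align_idempotent(self, rng):
        ref = _rand_dna(rng, 50)
        calls = [
            IndelCall("deletion", 10, 14),
            IndelCall("insertion", 20, 20, "TTAG"),
            IndelCall("deletion", 30, 31),
        ]
        once = left_align_calls(ref, calls)
        assert left_align_calls(ref, once) == once

    def test_roundtrip_random_edit_sets(self):
        """Fuzz: 1,000 random edit sets; applying the normalized calls to
        the reference reproduces the clone exactly."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            ref = _rand_dna(rng, int(rng.integers(30, 80)))
            pos = sorted(rng.integers(0, len(ref) - 8, 2))
            s1, s2 = int(pos[0]), int(pos[1]) + 6
            clone = ref
            # one deletion and/or one insertion at separated loci
            if rng.random() < 0.8:
                L = int(rng.integers(1, 5))
                clone = clone[:s2] + clone[s2 + L:]
            if rng.random() < 0.6:
                ins = _rand_dna(rng, int(rng.integers(1, 5)))
                clone = clone[:s1] + ins + clone[s1:]
            if not clone:
                continue
            calls = normalize_indels(global_align(ref, clone, INDEL_FAITHFUL_SCORING))
            assert apply_calls(ref, calls) == clone


class TestCallEdits:
    def test_unmodified(self, small_ref):
        ref, _ = small_ref
        rec = call_edits(ref, CloneSequence("c", ref.seq))
        assert rec.edit_class == "unmodified"
        assert rec.net_change == 0 and rec.calls == ()

    def test_72_nt_deletion_single_call(self, small_ref):
        ref, cut = small_ref
        i = cut.interbase
        clone = ref.seq[:i - 36] + ref.seq[i + 36:]
        rec = call_edits(ref, CloneSequence("c", clone))
        assert rec.edit_class == "deletion"
        assert [c.length for c in rec.calls] == [72]
        assert rec.net_change == -72

    def test_deletion_plus_insertion_is_both(self):
        """5 nt removed at the cut with GG inserted -> two calls, class
        'both', net change -3 (indel-faithful scheme; inserted bases do not
        occur in the removed segment)."""
        ref = ReferenceAmplicon("r", "ACGTACGTAC" + "TCATT" + "ACGTACGTAC")
        clone = "ACGTACGTAC" + "GG" + "ACGTACGTAC"
        rec = call_edits(ref, CloneSequence("c", clone), INDEL_FAITHFUL_SCORING)
        assert rec.edit_class == "both"
        assert rec.net_change == -3
        kinds = sorted(c.kind for c in rec.calls)
        assert kinds == ["deletion", "insertion"]

    def test_substitutions_counted_not_called(self, small_ref):
        ref, _ = small_ref
        clone = list(ref.seq)
        clone[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[clone[10]]
        rec = call_edits(ref, CloneSequence("c", "".join(clone)))
        assert rec.edit_class == "unmodified"
        assert rec.substitutions == 1

    def test_truncated_clone_flagged_not_dropped(self, small_ref):
        ref, _ = small_ref
        rec = call_edits(ref, CloneSequence("c", ref.seq[:10]))
        assert "length_out_of_bounds" in rec.flags
        assert rec.edit_class == "deletion"


class TestSummarizeCohort:
    def _del_record(self, cid, ref, cut, length):
        i = cut.interbase
        u = length // 2
        clone = ref.seq[:i - u] + ref.seq[i - u + length:]
        return call_edits(ref, CloneSequence(cid, clone))

    def test_min_max_over_cohort(self, small_ref):
        """24 clones with total deletions spanning 3..72 summarize to
        min 3 / max 72 with n = 24."""
        ref, cut = small_ref
        sizes = [3, 72] + list(range(5, 49, 2))
        records = [
            self._del_record(f"c{k}", ref, cut, L) for k, L in enumerate(sizes)
        ]
        s = summarize_cohort(records)
        assert (s.n_clones, s.min_deletion, s.max_deletion) == (24, 3, 72)
        assert s.class_counts["deletion"] == 24

    def test_extremes_one_and_sixty_one(self, small_ref):
        ref, cut = small_ref
        records = [
            self._del_record("a", ref, cut, 1),
            self._del_record("b", ref, cut, 61),
        ]
        s = summarize_cohort(records)
        assert (s.min_deletion, s.max_deletion) == (1, 61)

    def test_unmodified_only(self, small_ref):
        ref, _ = small_ref
        s = summarize_cohort([call_edits(ref, CloneSequence("c", ref.seq))])
        assert s.class_counts == {
            "unmodified": 1, "deletion": 0, "insertion": 0, "both": 0,
        }
        assert s.min_deletion is None and s.max_deletion is None

    def test_order_invariance(self, small_ref):
        ref, cut = small_ref
        records = [self._del_record(f"c{k}", ref, cut, L) for k, L in enumerate([4, 9, 2])]
        a = summarize_cohort(records)
        b = summarize_cohort(records[::-1])
        assert a.class_counts == b.class_counts
        assert (a.min_deletion, a.max_deletion) == (b.min_deletion, b.max_deletion)

    def test_empty_cohort_rejected(self):
        with pytest.raises(NhejscopeError):
            summarize_cohort([])


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(match=-1)
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=-0.5, gap_extend=-1.0)
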