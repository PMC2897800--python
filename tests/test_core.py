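import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import jaccard_oracle, make_aln, random_pileup
from parmap.config import CoreParams
from parmap.core import (
    SiteOutOfBoundsError,
    classify_indel,
    collect_clip_events,
    gap_consensus,
    site_counts_from_alignments,
    variant_position,
)
from parmap.models import CallType, ClipDirection, ClipEvent, ReferenceSet


class TestCollectClipEvents:
    def test_right_clip_anchors_at_last_aligned_base(self):
        a = make_aln(100, 140, right=10, read_seq="A" * 40 + "TTAGCTTAGC")
        events = collect_clip_events([a])
        (key,) = events
        assert key == ("t", 139, ClipDirection.RIGHT)
        assert events[key][0].clipped_seq == "TTAGCTTAGC"

    def test_left_clip_anchors_at_first_base_and_is_reversed(self):
        a = make_aln(100, 140, left=10, read_seq="TTAGCTTAGC" + "A" * 40)
        events = collect_clip_events([a])
        (key,) = events
        assert key == ("t", 100, ClipDirection.LEFT)
        # outward from p: nearest-to-p base first
        assert events[key][0].clipped_seq == "CGATTCGATT"

    def test_fully_mapped_read_yields_no_events(self):
        assert collect_clip_events([make_aln(100, 150)]) == {}

    def test_read_clipped_at_both_ends_yields_two_events(self):
        a = make_aln(100, 140, left=5, right=5)
        assert len(collect_clip_events([a])) == 2

    def test_internal_indel_reads_excluded_by_default(self):
        a = make_aln(100, 140, right=10, has_internal_indel=True)
        assert collect_clip_events([a]) == {}
        assert len(collect_clip_events([a], include_mapper_indels=True)) == 1


class TestSiteCounts:
    def test_jaccard_arithmetic_mixed_pileup(self):
        # 6 reads span p and p+1; 4 additional reads end exactly at p.
        p = 50
        alns = [make_aln(40, 60) for _ in range(6)] + [make_aln(40, p + 1) for _ in range(4)]
        sc = site_counts_from_alignments(alns, "t", p, ClipDirection.RIGHT, 100)
        assert (sc.n_p, sc.n_pm1, sc.n_both) == (10, 6, 6)
        assert sc.r == pytest.approx(6 / (10 + 6 - 6))

    def test_all_reads_end_at_p_gives_r_zero(self):
        alns = [make_aln(10, 41) for _ in range(40)]
        sc = site_counts_from_alignments(alns, "t", 40, ClipDirection.RIGHT, 100)
        assert sc.n_both == 0 and sc.r == 0.0

    def test_identical_sets_give_r_one(self):
        alns = [make_aln(10, 60) for _ in range(7)]
        sc = site_counts_from_alignments(alns, "t", 30, ClipDirection.RIGHT, 100)
        assert sc.r == 1.0

    def test_no_coverage_gives_r_one_by_convention(self):
        sc = site_counts_from_alignments([], "t", 30, ClipDirection.LEFT, 100)
        assert (sc.n_p, sc.n_pm1, sc.r) == (0, 0, 1.0)

    def test_neighbour_out_of_bounds_is_signalled(self):
        alns = [make_aln(0, 10)]
        with pytest.raises(SiteOutOfBoundsError):
            site_counts_from_alignments(alns, "t", 0, ClipDirection.LEFT, 100)
        with pytest.raises(SiteOutOfBoundsError):
            site_counts_from_alignments(alns, "t", 99, ClipDirection.RIGHT, 100)

    @pytest.mark.parametrize("direction", list(ClipDirection))
    def test_matches_brute_force_oracle_on_random_pileups(self, direction):
        rng = np.random.default_rng(123 if direction is ClipDirection.RIGHT else 321)
        for _ in range(300):
            alns = random_pileup(rng)
            p = int(rng.integers(1, 59))
            sc = site_counts_from_alignments(alns, "t", p, direction, 60)
            assert sc.r == jaccard_oracle(alns, "t", p, direction)

    def test_adding_both_covering_read_never_decreases_r(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            alns = random_pileup(rng)
            p = int(rng.integers(1, 58))
            before = site_counts_from_alignments(alns, "t", p, ClipDirection.RIGHT, 60).r
            after = site_counts_from_alignments(
                alns + [make_aln(p, p + 2)], "t", p, ClipDirection.RIGHT, 60).r
            assert after >= before

    def test_adding_p_only_read_never_increases_r(self):
        rng = np.random.default_rng(98)
        for _ in range(100):
            alns = random_pileup(rng)
            p = int(rng.integers(1, 58))
            before = site_counts_from_alignments(alns, "t", p, ClipDirection.RIGHT, 60).r
            after = site_counts_from_alignments(
                alns + [make_aln(p, p + 1)], "t", p, ClipDirection.RIGHT, 60).r
            assert after <= before

    @given(n_both=st.integers(0, 30), only_p=st.integers(0, 30), only_n=st.integers(0, 30))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_r_symmetric_in_the_two_margins(self, n_both, only_p, only_n):
        p = 50
        def build(a_only_p, a_only_n):
            alns = [make_aln(p - 5, p + 5) for _ in range(n_both)]
            alns += [make_aln(p - 5, p + 1) for _ in range(a_only_p)]
            alns += [make_aln(p + 1, p + 6) for _ in range(a_only_n)]
            return site_counts_from_alignments(alns, "t", p, ClipDirection.RIGHT, 100).r
        assert build(only_p, only_n) == pytest.approx(build(only_n, only_p))


def ev(p, direction, seq, rid="r"):
    return ClipEvent(rid, p, direction, seq)


class TestGapConsensus:
    def test_unanimous_tails(self):
        events = [ev(10, ClipDirection.RIGHT, "TTAGC", f"r{i}") for i in range(5)]
        cons = gap_consensus(events, min_support=2)
        assert cons.sequence == "TTAGC"
        assert cons.support == 5
        assert all(a == 1.0 for a in cons.agreement)

    def test_per_position_plurality(self):
        tails = ["TTAGC", "TTAGC", "TTACC"]
        events = [ev(10, ClipDirection.RIGHT, t, f"r{i}") for i, t in enumerate(tails)]
        cons = gap_consensus(events, agreement=0.5, min_support=2)
        assert cons.sequence == "TTAGC"
        assert cons.agreement[3] == pytest.approx(2 / 3)

    def test_truncated_when_too_few_tails_extend(self):
        tails = ["TTAGC", "TTAGC", "TT"]
        events = [ev(10, ClipDirection.RIGHT, t, f"r{i}") for i, t in enumerate(tails)]
        cons = gap_consensus(events, min_support=3)
        assert cons.sequence == "TT"
        assert cons.support == 3

    def test_tie_breaks_lexicographically(self):
        events = [ev(10, ClipDirection.RIGHT, "G", "r0"), ev(10, ClipDirection.RIGHT, "A", "r1")]
        cons = gap_consensus(events, agreement=0.5, min_support=2)
        assert cons.sequence == "A"

    def test_truncated_when_agreement_drops(self):
        tails = ["TA", "TC", "TG", "TT"]
        events = [ev(10, ClipDirection.RIGHT, t, f"r{i}") for i, t in enumerate(tails)]
        cons = gap_consensus(events, agreement=0.5, min_support=2)
        assert cons.sequence == "T"

    def test_mixed_sites_rejected(self):
        with pytest.raises(ValueError):
            gap_consensus([ev(10, ClipDirection.RIGHT, "A"), ev(11, ClipDirection.RIGHT, "A")])


class TestClassifyIndel:
    def test_deletion_recovered_from_shifted_reference_match(self):
        # reference after p reads ACGTACGTA; a consensus starting at offset 4
        # implies a 3 nt deletion of ACG
        ref = ReferenceSet({"t": "AAAAA" + "ACGTACGTA" + "AAAAA"})
        call = classify_indel("TACGTA", ref, "t", 4, ClipDirection.RIGHT)
        assert call.call_type is CallType.DELETION
        assert call.length == 3
        assert call.sequence == "ACG"
        assert variant_position(call, 4, ClipDirection.RIGHT) == 5

    def test_insertion_recovered_after_skipping_novel_bases(self):
        ref = ReferenceSet({"t": "AAAAA" + "ACGT"})
        params = CoreParams(min_classify_span=2, min_classify_length=2)
        call = classify_indel("TTAAC", ref, "t", 4, ClipDirection.RIGHT, params)
        assert call.call_type is CallType.INSERTION
        assert call.length == 3
        assert call.sequence == "TTA"
        assert variant_position(call, 4, ClipDirection.RIGHT) == 4

    def test_reference_continuation_is_unresolved(self, toy_reference):
        p = 200
        cons = toy_reference["t"][p + 1:p + 9]
        call = classify_indel(cons, toy_reference, "t", p, ClipDirection.RIGHT)
        assert call.call_type is CallType.UNRESOLVED

    def test_short_consensus_is_unresolved(self, toy_reference):
        call = classify_indel("ACG", toy_reference, "t", 200, ClipDirection.RIGHT)
        assert call.call_type is CallType.UNRESOLVED

    @pytest.mark.parametrize("direction", list(ClipDirection))
    @pytest.mark.parametrize("kind", ["DEL", "INS"])
    @pytest.mark.parametrize("length", range(1, 10))
    def test_planted_indel_consensus_recovered_exhaustively(
        self, toy_reference, direction, kind, length
    ):
        """Building the consensus a planted indel would produce and
        classifying it must recover type, length and exact sequence."""
        ref = toy_reference
        p = 200
        rng = np.random.default_rng(1000 + length)
        window = 12
        if kind == "DEL":
            if direction is ClipDirection.RIGHT:
                cons = ref["t"][p + 1 + length:p + 1 + length + window]
                expected_seq = ref["t"][p + 1:p + 1 + length]
            else:
                cons = ref["t"][p - length - window:p - length][::-1]
                expected_seq = ref["t"][p - length:p]
            expected_type = CallType.DELETION
        else:
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            if direction is ClipDirection.RIGHT:
                cons = ins + ref["t"][p + 1:p + 1 + window]
            else:
                cons = ins[::-1] + ref["t"][p - window:p][::-1]
            expected_seq = ins
            expected_type = CallType.INSERTION
        call = classify_indel(cons, ref, "t", p, direction)
        assert call.call_type is expected_type
        assert call.length == length
        assert call.sequence == expected_seq
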