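import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplosv.gd import GenomeDiff, Mutation, apply_mutations
from haplosv.junctions import (JunctionCandidate, JunctionSide, Support,
                               build_junction_sequence, canonicalize,
                               collapse_candidates, make_candidate,
                               overlap_bound, pair_passes_guards,
                               pairs_for_read, prescore_and_select,
                               split_alignment_at_indels)
from haplosv.readmap import ReadAlignment, map_reads_all
from haplosv.refio import ReferenceSet, revcomp

from conftest import random_dna


def _aln(read_start, read_end, ref_start, ref_end, strand="+", score=None,
         ops=None, read_length=50, read_id="r"):
    n = read_end - read_start + 1
    return ReadAlignment(read_id, read_start, read_end, "chr1", ref_start,
                         ref_end, strand, score if score is not None else n,
                         tuple(ops) if ops else (("=", n),), read_length)


class TestGuards:
    def test_overlap_bound_at_36(self):
        # bound 12 + 0.4*(36-12) = 21.6
        s1 = _aln(1, 28, 100, 127, read_length=36)
        s2 = _aln(8, 36, 500, 528, read_length=36)   # V = 28-8+1 = 21
        ok, V, _ = pair_passes_guards(s1, s2, 36)
        assert ok and V == 21
        # V = 22 with both side-fraction guards still satisfied
        s1b = _aln(1, 29, 100, 128, read_length=36)
        s2b = _aln(8, 36, 500, 528, read_length=36)
        ok, V, _ = pair_passes_guards(s1b, s2b, 36)
        assert not ok and V == 22

    def test_final_base_required_at_50(self):
        s1 = _aln(1, 25, 100, 124)
        assert pair_passes_guards(s1, _aln(26, 49, 500, 523), 50)[0] is False
        assert pair_passes_guards(s1, _aln(26, 50, 500, 524), 50)[0] is True

    def test_tail_allowance_above_50(self):
        # L=100: allowed unaligned tail = 0.1*(100-50) = 5 bases
        s1 = _aln(1, 50, 100, 149, read_length=100)
        ok5, _, _ = pair_passes_guards(
            s1, _aln(51, 95, 500, 544, read_length=100), 100)
        ok6, _, _ = pair_passes_guards(
            s1, _aln(51, 94, 500, 543, read_length=100), 100)
        assert ok5 and not ok6

    def test_side_fraction_guard(self):
        # side 2 contributes only 9 non-overlap bases of a 50-base read
        s1 = _aln(1, 41, 100, 140)
        s2 = _aln(42, 50, 500, 508)
        assert pair_passes_guards(s1, s2, 50)[0] is False

    def test_first_base_anchoring(self):
        s1 = _aln(2, 26, 100, 124)
        s2 = _aln(27, 50, 500, 523)
        assert pair_passes_guards(s1, s2, 50)[0] is False

    @given(L=st.integers(13, 400), V=st.integers(0, 12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bound_monotone_in_read_length(self, L, V):
        # a V passing at length L still passes at any longer length
        assert overlap_bound(L + 1) >= overlap_bound(L)
        if V <= overlap_bound(L):
            assert V <= overlap_bound(L + 50)

    def test_max_span_selection(self):
        # guard 6: only pairs achieving the maximal spanned length survive;
        # both pairs here pass guards 1-5 (L=100 tolerates a 5-base tail)
        read = "A" * 100
        a = _aln(1, 50, 100, 149, read_length=100)
        b = _aln(51, 100, 500, 549, read_length=100)
        c = _aln(51, 95, 700, 744, read_length=100)
        pairs = pairs_for_read([a, b, c], read)
        assert len(pairs) == 1
        assert pairs[0].side2.ref_start == 500

    def test_spanning_alignment_suppresses_pairs(self):
        read = "A" * 50
        full = _aln(1, 46, 100, 145)  # spans >= 90% of the read
        a = _aln(1, 25, 100, 124)
        b = _aln(26, 50, 500, 524)
        assert pairs_for_read([full, a, b], read) == []


class TestSplitAtIndels:
    def _ref(self, rng, n=2000):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(n, rng))
        return ref

    def test_long_deletion_split(self, rng):
        ref = self._ref(rng)
        seq = ref.sequence("chr1")
        read = seq[100:125] + seq[130:155]  # 5-base deletion
        aln = _aln(1, 50, 101, 155, ops=[("=", 25), ("D", 5), ("=", 25)],
                   score=50 - 17)
        pieces = split_alignment_at_indels(aln, ref, read, min_indel=3)
        assert len(pieces) == 2
        assert pieces[0].ref_end == 125 and pieces[1].ref_start == 131

    def test_short_indel_retained(self, rng):
        ref = self._ref(rng)
        seq = ref.sequence("chr1")
        read = seq[100:125] + seq[127:152]
        aln = _aln(1, 50, 101, 152, ops=[("=", 25), ("D", 2), ("=", 25)],
                   score=50 - 8)
        assert split_alignment_at_indels(aln, ref, read, min_indel=3) == [aln]

    def test_tandem_duplication_rewritten_as_overlap(self, rng):
        # a 4-base insertion duplicating the preceding reference bases must
        # yield two alignments whose read intervals overlap by 4, identical
        # to what mapping the two halves separately would produce
        ref = self._ref(rng)
        seq = ref.sequence("chr1")
        read = seq[100:125] + seq[121:125] + seq[125:146]  # dup of 4
        aln = _aln(1, 50, 101, 146,
                   ops=[("=", 25), ("I", 4), ("=", 21)], score=50 - 4 - 14)
        pieces = split_alignment_at_indels(aln, ref, read, min_indel=3)
        assert len(pieces) == 2
        # the re-extended pieces share the duplicated reference bases
        ref_ov = pieces[0].ref_end - pieces[1].ref_start + 1
        assert ref_ov >= 4
        direct = map_reads_all([("r", read)], ref)["r"]
        got = {(p.read_start, p.read_end, p.ref_start, p.ref_end)
               for p in pieces}
        want = {(a.read_start, a.read_end, a.ref_start, a.ref_end)
                for a in direct if a.strand == "+"}
        assert got == want


class TestMakeCandidate:
    def test_flank_rule(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(5000, rng))
        s1 = JunctionSide("chr1", 2000, -1)
        s2 = JunctionSide("chr1", 3000, +1)
        seq, f1, f2, cs = build_junction_sequence(ref, s1, s2, 4, "", 45)
        # overlap V=4, max read length 50 -> 45 flank bases per side
        assert f1 == f2 == 45
        assert len(seq) == 45 + 4 + 45
        assert cs == 45

    def test_read_only_bases_in_sequence(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(5000, rng))
        s1 = JunctionSide("chr1", 2000, -1)
        s2 = JunctionSide("chr1", 3000, +1)
        seq, f1, _, cs = build_junction_sequence(ref, s1, s2, 0, "TT", 48)
        assert seq[cs : cs + 2] == "TT"
        assert seq == ref.subsequence("chr1", 2000 - 47, 2000) + "TT" + \
            ref.subsequence("chr1", 3000, 3000 + 47)

    def test_overlap_trimming_recovers_mutant_sequence(self, rng):
        # imperfect overlap: the overlap is trimmed until the remainder is a
        # perfect match and the final sequence is a substring of the mutant
        seq = random_dna(6000, rng)
        ref = ReferenceSet()
        ref.add_sequence("chr1", seq)
        mutant = seq[:3000] + seq[3600:]
        read = mutant[2975:3025]
        out = map_reads_all([("r", read)], ref)["r"]
        pairs = pairs_for_read(out, read)
        assert pairs
        cand = make_candidate(pairs[0], ref, 50)
        assert cand is not None
        assert cand.sequence in mutant or revcomp(cand.sequence) in mutant


class TestCanonicalize:
    def _cand(self, ref, s1, s2, V=0, U=""):
        seq, f1, f2, cs = build_junction_sequence(ref, s1, s2, V, U, 30)
        return JunctionCandidate(s1, s2, V, U, seq, f1, f2, cs)

    def test_cross_contig_ordering(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(1000, rng))
        ref.add_sequence("chr2", random_dna(1000, rng))
        c = self._cand(ref, JunctionSide("chr2", 500, -1),
                       JunctionSide("chr1", 400, +1))
        out = canonicalize(c)
        assert out.side1.seq_id == "chr1"
        assert out.sequence == revcomp(c.sequence)

    def test_same_contig_lower_coordinate_first(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(6000, rng))
        c = self._cand(ref, JunctionSide("chr1", 5000, -1),
                       JunctionSide("chr1", 2000, +1))
        out = canonicalize(c)
        assert out.side1.pos == 2000

    def test_idempotent(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(6000, rng))
        for _ in range(10):
            p1, p2 = sorted(rng.integers(100, 5900, 2))
            c = self._cand(ref, JunctionSide("chr1", int(p2), -1),
                           JunctionSide("chr1", int(p1), +1))
            once = canonicalize(c)
            twice = canonicalize(once)
            assert once.description == twice.description
            assert once.sequence == twice.sequence

    def test_opposite_strand_reads_collapse_to_one(self, rng):
        seq = random_dna(6000, rng)
        ref = ReferenceSet()
        ref.add_sequence("chr1", seq)
        mutant = seq[:3000] + seq[3600:]
        cands = []
        for off in (0, 3, 6):
            for rd in (mutant[2975 + off : 3025 + off],
                       revcomp(mutant[2975 + off : 3025 + off])):
                out = map_reads_all([("r", rd)], ref)["r"]
                for pair in pairs_for_read(out, rd):
                    c = make_candidate(pair, ref, 50)
                    if c:
                        cands.append(c)
        assert len(cands) >= 4
        merged = collapse_candidates(cands)
        assert len(merged) == 1
        assert len(merged[0].supports) == len(cands)


class TestCollapseAndSelect:
    def _simple(self, seq, side1, side2, score_reads=0):
        c = JunctionCandidate(side1, side2, 0, "", seq, 10, 10, 10)
        for i in range(score_reads):
            c.supports.append(Support(i, +1, f"s{i}", 50, True))
        return c

    def test_substring_merge_keeps_shorter(self, rng):
        long = random_dna(120, rng)
        short = long[10:110]
        a = self._simple(long, JunctionSide("chr1", 100, -1),
                         JunctionSide("chr1", 900, +1), 2)
        b = self._simple(short, JunctionSide("chr1", 100, -1),
                         JunctionSide("chr1", 900, +1), 3)
        out = collapse_candidates([a, b])
        assert len(out) == 1
        assert out[0].sequence == short
        assert len(out[0].supports) == 5

    def test_same_fragment_preferred_on_ties(self, rng):
        seq = random_dna(100, rng)
        same = self._simple(seq, JunctionSide("chr1", 100, -1),
                            JunctionSide("chr1", 900, +1))
        cross = self._simple(seq, JunctionSide("chr1", 100, -1),
                             JunctionSide("chr2", 900, +1))
        out = collapse_candidates([cross, same])
        assert len(out) == 1
        assert out[0].same_fragment()

    def test_low_evenness_dropped(self, rng):
        seq = random_dna(100, rng)
        weak = self._simple(seq, JunctionSide("chr1", 100, -1),
                            JunctionSide("chr1", 900, +1), 1)
        strong = self._simple(random_dna(100, rng),
                              JunctionSide("chr1", 200, -1),
                              JunctionSide("chr1", 800, +1), 5)
        out = prescore_and_select([weak, strong], reference_length=10_000)
        assert [c.score for c in out] == [5]

    def test_class_admission_with_budget(self, rng):
        # 100 candidates at S=10 fill min_kept; the S=9 class would blow the
        # budget and is rejected whole
        cands = []
        for i in range(100):
            cands.append(self._simple(random_dna(100, rng),
                                      JunctionSide("chr1", 10 + i, -1),
                                      JunctionSide("chr1", 5000 + i, +1), 10))
        for i in range(50):
            cands.append(self._simple(random_dna(100, rng),
                                      JunctionSide("chr1", 2000 + i, -1),
                                      JunctionSide("chr1", 8000 + i, +1), 9))
        out = prescore_and_select(cands, reference_length=120_000,
                                  max_candidates=5000,
                                  max_total_len_fraction=0.10, min_kept=100,
                                  min_score=2)
        assert len(out) == 100
        assert all(c.score == 10 for c in out)

    def test_selection_identity_when_budget_unreached(self, rng):
        cands = [self._simple(random_dna(100, rng),
                              JunctionSide("chr1", 10 + i, -1),
                              JunctionSide("chr1", 900 + i, +1), 3 + i)
                 for i in range(5)]
        out = prescore_and_select(cands, reference_length=10_000_000)
        assert len(out) == 5
        assert [c.score for c in out] == sorted(
            [c.score for c in cands], reverse=True)


class TestSequenceReconstruction:
    def test_candidates_are_substrings_of_mutant_genome(self, rng):
        # every candidate from error-free reads over a mutated genome must
        # reconstruct an exact substring of that genome
        from haplosv.simulate import (ReadSimModel, SimPlan, random_genome,
                                      simulate_reads, simulate_sv_genome)
        from haplosv.pipeline import run_pipeline

        ref = random_genome(length=60_000, n_elements=0, seed=21)
        mutant, truth = simulate_sv_genome(
            ref, SimPlan("unique-deletion", 3, seed=22))
        reads = simulate_reads(mutant, ReadSimModel(
            read_length=50, coverage=30, error_rate=0.0, seed=23))
        res = run_pipeline(reads, ref)
        genome = mutant.sequence("chr1")
        assert res.candidates
        for c in res.candidates:
            assert c.sequence in genome or revcomp(c.sequence) in genome
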