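import numpy as np
import pytest

from haplosv.coverage import CoverageModel
from haplosv.gd import GenomeDiff, Mutation, apply_mutations
from haplosv.junction_eval import (JunctionResolution, JunctionTestResult,
                                   continuation_lengths, evaluate_all_junctions,
                                   junction_skew_pvalue, max_evenness_score,
                                   place_breakpoint, remap_and_resolve,
                                   split_reads_onto_reference)
from haplosv.junctions import (JunctionCandidate, JunctionSide,
                               build_junction_sequence, make_candidate,
                               pairs_for_read)
from haplosv.readmap import ReadSet, map_reads_all, stage_mapping_params
from haplosv.refio import Feature, ReferenceSet, revcomp

from conftest import best_local_score_vs_reference, random_dna


def _candidate(ref, s1, s2, V=0, U="", flank=49):
    seq, f1, f2, cs = build_junction_sequence(ref, s1, s2, V, U, flank)
    return JunctionCandidate(s1, s2, V, U, seq, f1, f2, cs)


def _model(mu=40.0, alpha=1e4, p0=0.6, t=5, sids=("chr1",)):
    m = CoverageModel()
    for sid in sids:
        m.mu[sid] = mu
        m.alpha[sid] = alpha
        m.p0[sid] = p0
        m.threshold[sid] = t
    return m


class TestContinuationLengths:
    def test_tandem_repeat_deletion_overlap4_continuation3(self, rng):
        # a 4-base deletion in a short tandem repeat: the junction described
        # with the 4-base unit as overlap needs 3 extra continuation bases
        # (the partial repeat unit) before a read distinguishes it from the
        # unmutated reference
        L = random_dna(200, rng)
        R = random_dna(200, rng)
        if L[-1] == "A":
            L = L[:-1] + "G"
        if R[0] == "T":
            R = "G" + R[1:]
        refseq = L + "TCGA" + "TCGA" + "TCG" + R
        ref = ReferenceSet()
        ref.add_sequence("chr1", refseq)
        nL = len(L)
        cand = _candidate(ref, JunctionSide("chr1", nL + 4, -1),
                          JunctionSide("chr1", nL + 5, +1), V=4)
        C1, C2 = continuation_lengths(cand, ref)
        assert cand.overlap == 4
        assert C1 + C2 == 3
        assert max_evenness_score(50, 4, C1, C2) == 84

    def test_nonrepetitive_breakpoint_no_continuation(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(4000, rng))
        # deletion junction between two random flanks: with probability
        # ~1/4 per base a chance match extends the run; test several and
        # require the modal value 0 to occur
        zeros = 0
        for k in range(8):
            p1 = 500 + 300 * k
            cand = _candidate(ref, JunctionSide("chr1", p1, -1),
                              JunctionSide("chr1", p1 + 200, +1))
            C1, C2 = continuation_lengths(cand, ref)
            assert C1 >= 0 and C2 >= 0
            zeros += (C1 == 0) + (C2 == 0)
        assert zeros >= 8  # most sides need no continuation

    def test_matches_brute_force_alignment_oracle(self, rng):
        # C2 equals the minimal number of bases past the breakpoint a
        # left-anchored read must align before it scores strictly better on
        # the junction than anywhere on the reference
        for trial in range(5):
            refseq = random_dna(700, np.random.default_rng(100 + trial))
            ref = ReferenceSet()
            ref.add_sequence("chr1", refseq)
            s1 = JunctionSide("chr1", 300, -1)
            s2 = JunctionSide("chr1", 520, +1)
            cand = _candidate(ref, s1, s2, flank=30)
            C1, C2 = continuation_lengths(cand, ref)
            cs = cand.core_start
            # reads covering flank1 and k bases past the breakpoint
            brute = None
            for k in range(1, 25):
                read = cand.sequence[cs - 25 : cs + k]
                ref_best = best_local_score_vs_reference(read, refseq)
                if len(read) > ref_best:  # junction match strictly better
                    brute = k
                    break
            assert brute == C2 + 1


class TestMaxEvennessScore:
    def test_baseline(self):
        assert max_evenness_score(50, 0, 0, 0) == 98

    def test_overlap_and_continuation_reduce_slots(self):
        assert max_evenness_score(50, 4, 3, 0) == 84

    def test_two_slots_per_core_base(self):
        base = max_evenness_score(100, 0, 0, 0)
        for v in range(1, 6):
            assert max_evenness_score(100, v, 0, 0) == base - 2 * v

    def test_mean_length_ceiling(self):
        assert max_evenness_score(50.2, 0, 0, 0) == 2 * (51 - 1)


class TestSkewPvalue:
    def test_monotone_in_observed_score(self):
        ps = [junction_skew_pvalue(s, 84, 50, 10, 0.6)[0]
              for s in range(0, 85, 7)]
        assert all(a <= b + 1e-12 for a, b in zip(ps, ps[1:]))
        assert all(0 <= p <= 1 for p in ps)

    def test_degenerate_no_starts_anywhere(self):
        p, skew = junction_skew_pvalue(0, 84, 50, 10, 1.0)
        assert p == pytest.approx(1.0, abs=1e-5)
        assert skew == pytest.approx(0.0, abs=1e-5)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(0)
        mu, alpha, p0, smax, sobs = 50.0, 10.0, 0.6, 84, 10
        n, p = alpha, alpha / (alpha + mu)
        x = rng.negative_binomial(n, p, 1_000_000)
        succ = 1 - p0 ** (x / mu)
        mc = (rng.binomial(smax, succ) <= sobs).mean()
        pv, _ = junction_skew_pvalue(sobs, smax, mu, alpha, p0)
        se = np.sqrt(mc * (1 - mc) / 1_000_000)
        assert abs(pv - mc) < 3 * se

    def test_extreme_skew_stays_finite(self):
        p, skew = junction_skew_pvalue(0, 400, 200, 50, 0.2)
        assert p > 0 and np.isfinite(skew) and skew > 20

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            junction_skew_pvalue(10, 5, 50, 10, 0.5)
        with pytest.raises(ValueError):
            junction_skew_pvalue(1, 5, 50, 10, 1.5)


class TestRemapAndResolve:
    def _setup(self, rng):
        seq = random_dna(8000, rng)
        ref = ReferenceSet()
        ref.add_sequence("chr1", seq)
        mutant = seq[:4000] + seq[4700:]
        reads, expect = [], []
        for off in range(0, 30, 2):  # junction-crossing reads
            reads.append(mutant[3975 - off : 4025 - off])
            expect.append("junction")
        for start in (1000, 2000, 6000):  # plain reference reads
            reads.append(seq[start : start + 50])
            expect.append("reference")
        rs = ReadSet.from_sequences(reads)
        cands = []
        out = map_reads_all(rs, ref)
        for i in range(len(rs)):
            for pair in pairs_for_read(out[rs.read_id(i)], rs.sequence(i)):
                c = make_candidate(pair, ref, rs.max_length)
                if c:
                    cands.append(c)
        from haplosv.junctions import collapse_candidates

        return ref, rs, collapse_candidates(cands), expect

    def test_reference_better_reads_assigned_to_reference(self, rng):
        ref, rs, cands, expect = self._setup(rng)
        assert len(cands) == 1
        best_ref = np.array([50.0 if e == "reference" else 40.0
                             for e in expect])
        # pretend junction-crossing reads scored 40 on the reference
        stringent = stage_mapping_params(50, 50, "stringent")
        res = remap_and_resolve(rs, cands, best_ref, stringent)
        for i, e in enumerate(expect):
            if e == "junction":
                assert not res.ref_better[i]
                assert res.tied_reads.get(i) == [0]
        # plain reference reads tie the junction only if they fall inside
        # its flanks; reads far away must stay with the reference
        assert res.ref_better[len(expect) - 3 :].all()

    def test_claiming_removes_reads_from_later_candidates(self):
        # two candidates sharing every read: the first accepted claims them,
        # the second re-scores to zero support
        res = JunctionResolution(
            n_reads=30,
            cand_reads=[[(i, 10, 59, 1) for i in range(30)],
                        [(i, 10, 59, 1) for i in range(30)]],
            ref_better=np.zeros(30, bool),
            tied_reads={i: [0, 1] for i in range(30)},
        )
        ref = ReferenceSet()
        ref.add_sequence("chr1", "ACGT" * 1000)
        c1 = _candidate(ref, JunctionSide("chr1", 1000, -1),
                        JunctionSide("chr1", 2000, +1), flank=49)
        c2 = _candidate(ref, JunctionSide("chr1", 1200, -1),
                        JunctionSide("chr1", 2200, +1), flank=49)
        for c in (c1, c2):  # hide tandem-repeat effects of the toy genome
            c.sequence = random_dna(99, np.random.default_rng(id(c) % 2**31))
        accepted, marginal = evaluate_all_junctions(
            [c1, c2], res, _model(), 50.0, ref)
        assert len(accepted) <= 1
        if accepted:
            assert set(accepted[0].claimed_reads) == set(range(30))


class TestEvaluation:
    def _resolution(self, entries_per_cand, n_reads):
        return JunctionResolution(
            n_reads=n_reads,
            cand_reads=entries_per_cand,
            ref_better=np.zeros(n_reads, bool),
            tied_reads={},
        )

    def _plain_candidate(self, rng, flank=49):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(6000, rng))
        cand = _candidate(ref, JunctionSide("chr1", 2000, -1),
                          JunctionSide("chr1", 4000, +1), flank=flank)
        return ref, cand

    def test_even_support_accepted(self, rng):
        ref, cand = self._plain_candidate(rng)
        # reads starting in many registers on both strands
        entries = []
        rid = 0
        for start in range(10, 48):
            for strand in (1, -1):
                entries.append((rid, start, start + 49, strand))
                rid += 1
        res = self._resolution([entries], rid)
        accepted, marginal = evaluate_all_junctions([cand], res, _model(),
                                                    50.0, ref)
        assert len(accepted) == 1
        assert accepted[0].skew <= 3.0
        assert accepted[0].S_obs > 50

    def test_biased_start_artifact_rejected(self, rng):
        # 30 reads all sharing a single start position: high depth but
        # evenness score 1 -> rejected on skew despite the pileup
        ref, cand = self._plain_candidate(rng)
        entries = [(i, 20, 69, 1) for i in range(30)]
        res = self._resolution([entries], 30)
        accepted, marginal = evaluate_all_junctions([cand], res, _model(),
                                                    50.0, ref)
        assert accepted == []
        assert marginal and marginal[0].skew > 3.0
        assert marginal[0].S_obs == 1

    def test_deterministic_resolution(self, rng):
        ref, cand = self._plain_candidate(rng)
        entries = [(i, 10 + i % 30, 59 + i % 30, 1) for i in range(40)]
        outs = []
        for _ in range(2):
            res = self._resolution([entries], 40)
            accepted, marginal = evaluate_all_junctions(
                [cand], res, _model(), 50.0, ref)
            outs.append([(r.S_obs, r.S_max, round(r.skew, 9), r.status)
                         for r in accepted + marginal])
        assert outs[0] == outs[1]


class TestPlaceBreakpoint:
    def _result(self, ref, s1, s2, V):
        cand = _candidate(ref, s1, s2, V=V)
        return JunctionTestResult(cand, 10, 98, 0, 0, 0.5, 0.3, "accepted")

    def test_snap_to_feature_end_within_margin(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(6000, rng))
        feat = Feature("chr1", 3000, 4400, "+", "mobile_element", "ISx")
        ref.add_feature(feat)
        # side 2 enters the element 7 bases inside its start
        r = self._result(ref, JunctionSide("chr1", 1000, -1),
                         JunctionSide("chr1", 3007, +1), V=8)
        place_breakpoint(r, ref.features, repeat_margin=20)
        assert r.side2_resolved.pos == 3000

    def test_repeat_only_side_gives_overlap_to_unique_side(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(6000, rng))
        s1 = JunctionSide("chr1", 1000, -1, redundant=True)
        s2 = JunctionSide("chr1", 4000, +1)
        r = self._result(ref, s1, s2, V=5)
        place_breakpoint(r, [], repeat_margin=20)
        # all 5 ambiguous bases to the unique side: side1 retracts fully
        assert r.side1_resolved.pos == 995
        assert r.side2_resolved.pos == 4000

    def test_both_unique_priority_side_keeps_overlap(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(6000, rng))
        r = self._result(ref, JunctionSide("chr1", 1000, -1),
                         JunctionSide("chr1", 4000, +1), V=5)
        place_breakpoint(r, [], repeat_margin=20)
        assert r.side1_resolved.pos == 1000  # keeps all overlap
        assert r.side2_resolved.pos == 4005


class TestSplitReads:
    def test_pieces_and_base_conservation(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(6000, rng))
        cand = _candidate(ref, JunctionSide("chr1", 2000, -1),
                          JunctionSide("chr1", 4000, +1), flank=49)
        result = JunctionTestResult(cand, 40, 98, 0, 0, 0.5, 0.3, "accepted",
                                    claimed_reads=[0], cand_index=0)
        place_breakpoint(result, [], repeat_margin=20)
        cs = cand.core_start
        # a 50-base read crossing 30/20
        res = JunctionResolution(1, [[(0, cs - 30, cs + 19, 1)]],
                                 np.zeros(1, bool), {0: [0]})
        rs = ReadSet.from_sequences(["A" * 50])
        pieces = split_reads_onto_reference(result, res, rs, 0)
        assert len(pieces) == 2
        spans = sorted(p.ref_end - p.ref_start + 1 for p in pieces)
        assert spans == [20, 30]
        assert sum(spans) == 50  # aligned bases conserved
        left = min(pieces, key=lambda p: p.ref_start)
        assert left.ref_end == 2000
        right = max(pieces, key=lambda p: p.ref_start)
        assert right.ref_start == 4000
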