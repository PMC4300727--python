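import numpy as np
import pytest

from haplosv.calls import (call_structural_variants, compare_junction_sets,
                           infer_mobile_insertion_geometry,
                           junction_sequences_for_truth,
                           mutation_rate_estimate, mutations_equivalent)
from haplosv.gd import GenomeDiff, JCEntry, MCEntry, Mutation, apply_mutations
from haplosv.refio import Feature, ReferenceSet, revcomp

from conftest import random_dna


class TestMutationRate:
    def test_ma_experiment_arithmetic(self):
        rate, lo, hi = mutation_rate_estimate(53, 21, 6000)
        assert float(f"{rate:.2g}") == 0.00042
        assert float(f"{lo:.2g}") == 0.00032
        assert float(f"{hi:.2g}") == 0.00055

    def test_zero_events_closed_form(self):
        rate, lo, hi = mutation_rate_estimate(0, 21, 6000)
        assert rate == 0 and lo == 0
        assert hi == pytest.approx(3.6889 / 126000, rel=1e-4)

    def test_scale_equivariance(self):
        r1 = mutation_rate_estimate(53, 21, 6000)
        r2 = mutation_rate_estimate(53, 21, 12000)
        for a, b in zip(r1, r2):
            assert a == pytest.approx(2 * b)


class TestCompareJunctionSets:
    def test_identical_sets(self):
        seqs = ["ACGTACGTAC", "TTGGCCAATT"]
        sens, prec, pairs = compare_junction_sets(seqs, list(seqs))
        assert (sens, prec) == (1.0, 1.0)

    def test_subsequence_counts_as_match(self):
        truth = ["AAACGTACGTACGTTT"]
        pred = ["CGTACGTACG"]
        sens, prec, _ = compare_junction_sets(pred, truth)
        assert (sens, prec) == (1.0, 1.0)

    def test_reverse_complement_subsequence(self):
        truth = ["AAACGTACGTACGTTT"]
        pred = [revcomp("CGTACGTACG")]
        sens, prec, _ = compare_junction_sets(pred, truth)
        assert (sens, prec) == (1.0, 1.0)

    def test_disjoint_sets(self):
        sens, prec, _ = compare_junction_sets(["AAAA"], ["CCCC"])
        assert (sens, prec) == (0.0, 0.0)

    def test_symmetry_under_swap(self, rng):
        a = [random_dna(40, rng) for _ in range(5)]
        b = a[:3] + [random_dna(40, rng) for _ in range(2)]
        s1, p1, _ = compare_junction_sets(a, b)
        s2, p2, _ = compare_junction_sets(b, a)
        assert (s1, p1) == (p2, s2)


def _ref_with_elements(rng, n=40_000, copies=3, elen=400, family="ISx"):
    seq = random_dna(n, rng)
    elem = random_dna(elen, rng)
    ref = ReferenceSet()
    positions = [5000, 15_000, 25_000]
    out = []
    shift = 0
    built = seq
    for p in positions[:copies]:
        built = built[: p + shift] + elem + built[p + shift :]
        out.append(p + shift + 1)
        shift += elen
    ref.add_sequence("chr1", built)
    for start in out:
        ref.add_feature(Feature("chr1", start, start + elen - 1, "+",
                                "mobile_element", family))
    return ref, elem


class TestMobGeometry:
    def _jc(self, s1, s2, overlap=0, red1=False, red2=False, eid="1"):
        return JCEntry(id=eid, side1_seq_id="chr1", side1_position=s1[0],
                       side1_strand=s1[1], side2_seq_id="chr1",
                       side2_position=s2[0], side2_strand=s2[1],
                       overlap=overlap, side1_redundant=red1,
                       side2_redundant=red2)

    def test_tsd_recovery_from_clean_junctions(self, rng):
        ref, elem = _ref_with_elements(rng)
        el = ref.features[0]
        u, tsd = 30_500, 3
        jc_left = self._jc((u + tsd - 1, -1), (el.start, +1), red2=True,
                           eid="1")
        jc_right = self._jc((u, +1), (el.end, -1), red2=True, eid="2")
        mut = infer_mobile_insertion_geometry(jc_left, jc_right, ref,
                                              ref.features)
        assert mut is not None
        assert mut.duplication_size == tsd
        assert mut.position == u
        assert mut.strand == 1

    def test_minus_strand_element(self, rng):
        ref, elem = _ref_with_elements(rng)
        el = ref.features[1]
        u, tsd = 30_500, 5
        jc_left = self._jc((u + tsd - 1, -1), (el.end, -1), red2=True,
                           eid="1")
        jc_right = self._jc((u, +1), (el.start, +1), red2=True, eid="2")
        mut = infer_mobile_insertion_geometry(jc_left, jc_right, ref,
                                              ref.features)
        assert mut is not None and mut.strand == -1
        assert mut.duplication_size == tsd

    def test_margin_deletion_from_clipped_element_end(self, rng):
        # junction lands 2 bases inside the element start: the new copy is
        # missing 2 bases and the call must record that margin deletion
        ref, elem = _ref_with_elements(rng)
        el = ref.features[0]
        u, tsd = 30_500, 4
        jc_left = self._jc((u + tsd - 1, -1), (el.start + 2, +1), red2=True,
                           eid="1")
        jc_right = self._jc((u, +1), (el.end, -1), red2=True, eid="2")
        mut = infer_mobile_insertion_geometry(jc_left, jc_right, ref,
                                              ref.features)
        assert mut is not None
        assert int(mut.extras.get("del_start", 0)) == 2
        # apply-and-verify: the mutant genome contains both junctions
        gd = GenomeDiff()
        gd.add_mutation(mut)
        mut.id = "9"
        mutant = apply_mutations(gd, ref).sequence("chr1")
        assert elem[2:50] in mutant

    def test_different_families_rejected(self, rng):
        ref, elem = _ref_with_elements(rng)
        ref.add_feature(Feature("chr1", 100, 300, "+", "mobile_element",
                                "other"))
        el = ref.features[0]
        jc_left = self._jc((30_502, -1), (100, +1), red2=True, eid="1")
        jc_right = self._jc((30_500, +1), (el.end, -1), red2=True, eid="2")
        assert infer_mobile_insertion_geometry(jc_left, jc_right, ref,
                                               ref.features) is None


class TestCallRules:
    def test_del_from_jc_plus_mc(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(10_000, rng))
        jc = JCEntry(id="1", side1_seq_id="chr1", side1_position=3000,
                     side1_strand=-1, side2_seq_id="chr1",
                     side2_position=3701, side2_strand=1, overlap=0)
        mc = MCEntry(id="2", seq_id="chr1", start=3001, end=3700)
        gd, unassigned = call_structural_variants([jc], [mc], ref, [], 50.0)
        (m,) = gd.mutations
        assert (m.type, m.position, m.size) == ("DEL", 3001, 700)
        assert set(m.parent_ids) == {"1", "2"}
        assert unassigned == []

    def test_del_between_repeat_copies_mc_only(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(30_000, rng))
        f1 = Feature("chr1", 5000, 5400, "+", "repeat_region", "rep")
        f2 = Feature("chr1", 9000, 9400, "+", "repeat_region", "rep")
        mc = MCEntry(id="1", seq_id="chr1", start=5100, end=9300,
                     start_range=300, end_range=290, left_in_repeat=True,
                     right_in_repeat=True)
        gd, unassigned = call_structural_variants([], [mc], ref, [f1, f2],
                                                  50.0)
        (m,) = gd.mutations
        assert m.type == "DEL"
        assert m.position == f1.end + 1
        assert m.size == f2.end - f1.end

    def test_small_deletion_without_mc(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(10_000, rng))
        jc = JCEntry(id="1", side1_seq_id="chr1", side1_position=4000,
                     side1_strand=-1, side2_seq_id="chr1",
                     side2_position=4011, side2_strand=1, overlap=0)
        gd, _ = call_structural_variants([jc], [], ref, [], 50.0)
        (m,) = gd.mutations
        assert (m.type, m.position, m.size) == ("DEL", 4001, 10)

    def test_insertion_and_amplification(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(10_000, rng))
        ins = JCEntry(id="1", side1_seq_id="chr1", side1_position=2000,
                      side1_strand=-1, side2_seq_id="chr1",
                      side2_position=2001, side2_strand=1, overlap=0,
                      unique_read_seq="TTAA")
        amp = JCEntry(id="2", side1_seq_id="chr1", side1_position=7000,
                      side1_strand=1, side2_seq_id="chr1",
                      side2_position=7030, side2_strand=-1, overlap=0)
        gd, _ = call_structural_variants([ins, amp], [], ref, [], 50.0)
        kinds = {m.type: m for m in gd.mutations}
        assert kinds["INS"].new_seq == "TTAA"
        assert kinds["AMP"].size == 31
        assert kinds["AMP"].new_copy_number == 2

    def test_long_tandem_duplication_left_unassigned(self, rng):
        # amplification junction wider than the read length: not predicted
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(10_000, rng))
        amp = JCEntry(id="1", side1_seq_id="chr1", side1_position=7000,
                      side1_strand=1, side2_seq_id="chr1",
                      side2_position=7100, side2_strand=-1, overlap=0)
        gd, unassigned = call_structural_variants([amp], [], ref, [], 50.0)
        assert gd.mutations == []
        assert [e.id for e in unassigned] == ["1"]

    def test_both_sides_repeat_left_unassigned(self, rng):
        ref = ReferenceSet()
        ref.add_sequence("chr1", random_dna(10_000, rng))
        jc = JCEntry(id="1", side1_seq_id="chr1", side1_position=2000,
                     side1_strand=-1, side2_seq_id="chr1",
                     side2_position=5000, side2_strand=1, overlap=0,
                     side1_redundant=True, side2_redundant=True)
        gd, unassigned = call_structural_variants([jc], [], ref, [], 50.0)
        assert gd.mutations == []
        assert len(unassigned) == 1


class TestEquivalence:
    def test_homology_shifted_deletions_equivalent(self, rng):
        seq = random_dna(5000, rng)
        # create homology so the deletion has two equivalent placements
        seq = seq[:2000] + "ACGTAC" + seq[2006:2500] + "ACGTAC" + seq[2506:]
        ref = ReferenceSet()
        ref.add_sequence("chr1", seq)
        a = Mutation("DEL", "1", [], "chr1", 2001, size=500)
        b = Mutation("DEL", "2", [], "chr1", 2007, size=500)
        assert mutations_equivalent(a, b, ref)
        c = Mutation("DEL", "3", [], "chr1", 2010, size=500)
        assert not mutations_equivalent(a, c, ref)

    def test_truth_junction_sequences_cover_each_mutation(self, rng):
        from haplosv.simulate import SimPlan, random_genome, simulate_sv_genome

        ref = random_genome(length=100_000, n_elements=5, seed=41)
        mutant, truth = simulate_sv_genome(
            ref, SimPlan("is-insertion", 4, seed=42))
        seqs = junction_sequences_for_truth(truth, ref, flank=45)
        assert len(seqs) == 8  # two junctions per insertion
        genome = mutant.sequence("chr1")
        for s in seqs:
            assert s in genome or revcomp(s) in genome
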