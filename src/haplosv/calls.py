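"""Integrate junction (JC) and missing-coverage (MC) evidence into mutations.

Five prediction rules, applied in order, each consuming evidence at most
once:

(a) large deletion with a unique junction — an MC interval whose endpoints
    exactly match the breakpoints of a both-sides-unique JC;
(b) deletion between two same-family, same-orientation repeat copies — an
    MC interval whose both ends fall in annotated repeat copies (the
    deletion spans the intervening region plus the second copy);
(c) short deletion / insertion / substitution / tandem amplification — a
    single both-sides-unique JC whose breakpoints lie closer than the
    average read length;
(d) new mobile-element insertion — two JCs whose unique endpoints lie
    within 20 bp and whose other sides match opposite ends of the same
    repeat family, with target-site duplication (TSD) length and margin
    adjustments inferred so that applying the insertion reproduces both
    junction sequences;
(e) mobile-element-mediated deletion — an MC interval with one end in a
    repeat plus a JC joining the unique side of the interval to the
    proximal end of a copy of that repeat family.

Evidence not consumed by any rule is reported unassigned (e.g. junctions
supporting tandem duplications longer than the read length, or junctions
with both sides in repeats).
"""

from __future__ import annotations

from dataclasses import replace

from scipy import stats

from .gd import GenomeDiff, JCEntry, MCEntry, Mutation, apply_mutations
from .junctions import JunctionSide, build_junction_sequence
from .refio import Feature, ReferenceSet, revcomp

__all__ = [
    "call_structural_variants",
    "infer_mobile_insertion_geometry",
    "compare_junction_sets",
    "junction_sequences_for_truth",
    "jc_junction_sequence",
    "mutation_rate_estimate",
    "mutations_equivalent",
]


def _jc_sides(jc: JCEntry):
    s1 = JunctionSide(jc.side1_seq_id, jc.side1_position, jc.side1_strand,
                      jc.side1_redundant)
    s2 = JunctionSide(jc.side2_seq_id, jc.side2_position, jc.side2_strand,
                      jc.side2_redundant)
    return s1, s2


def jc_junction_sequence(jc: JCEntry, ref: ReferenceSet, flank: int) -> str:
    """Reconstruct a junction sequence from a JC entry with given flanks."""
    s1, s2 = _jc_sides(jc)
    seq, _, _, _ = build_junction_sequence(ref, s1, s2, jc.overlap,
                                           jc.unique_read_seq, flank)
    return seq


# ---------------------------------------------------------------------------
# rule helpers


def _mc_left_range(mc: MCEntry):
    return mc.start, mc.start + mc.start_range

def _mc_right_range(mc: MCEntry):
    return mc.end - mc.end_range, mc.end


def _repeat_feature_overlapping(features, seq_id, lo, hi, family=None):
    for f in features:
        if (f.seq_id == seq_id and f.is_repeat()
                and f.start <= hi and f.end >= lo
                and (family is None or f.family_name == family)):
            return f
    return None


def _nearest_family_boundary(features, side: JunctionSide, margin: int = 20):
    """Repeat feature whose proximal boundary the (redundant) side attaches:
    strand +1 sides enter a copy at its start, strand -1 at its end.
    Returns (feature, offset-into-element) or None."""
    best = None
    for f in features:
        if f.seq_id != side.seq_id or not f.is_repeat():
            continue
        boundary = f.start if side.strand == +1 else f.end
        delta = (side.pos - boundary) * side.strand
        # delta > 0: breakpoint inside the element (margin clipped)
        if abs(delta) <= margin or (f.start <= side.pos <= f.end):
            if best is None or abs(delta) < abs(best[1]):
                best = (f, delta)
    return best


def _unique_redundant(jc: JCEntry):
    """(unique_side, redundant_side) when exactly one side is redundant."""
    s1, s2 = _jc_sides(jc)
    if s1.redundant != s2.redundant:
        return (s2, s1) if s1.redundant else (s1, s2)
    return None


# ---------------------------------------------------------------------------
# MOB geometry


def infer_mobile_insertion_geometry(jc_left: JCEntry, jc_right: JCEntry,
                                    ref: ReferenceSet,
                                    features: list[Feature]):
    """Geometry of a new mobile-element insertion from its two junctions.

    ``jc_left`` joins the left unique flank to one end of the element,
    ``jc_right`` the other end to the right unique flank.  Returns a MOB
    :class:`Mutation` (unvalidated id/parents) or None when the junctions do
    not describe a consistent insertion.  The proposed geometry is accepted
    only if applying it to the reference reproduces both junction sequences.
    """
    ul = _unique_redundant(jc_left)
    ur = _unique_redundant(jc_right)
    if ul is None or ur is None:
        return None
    (u1, r1), (u2, r2) = ul, ur
    if u1.strand != -1 or u2.strand != +1:
        return None
    if u1.seq_id != u2.seq_id or abs(u1.pos - u2.pos) > 20:
        return None
    f1 = _nearest_family_boundary(features, r1)
    f2 = _nearest_family_boundary(features, r2)
    if f1 is None or f2 is None:
        return None
    if f1[0].family_name != f2[0].family_name or not f1[0].family_name:
        return None
    if r1.strand == r2.strand:
        return None  # must attach opposite element ends
    # element orientation: left junction entering a copy's start => '+'
    strand = +1 if r1.strand == +1 else -1
    tsd = u1.pos - u2.pos + 1
    extras = {}
    if tsd < 0:
        extras["target_del"] = -tsd
        tsd = 0
    # margin deletions: breakpoints inside the element clip its ends
    dl = max(int(f1[1]), 0)
    dr = max(int(f2[1]), 0)
    if strand == +1:
        if dl:
            extras["del_start"] = dl
        if dr:
            extras["del_end"] = dr
    else:
        if dl:
            extras["del_end"] = dl
        if dr:
            extras["del_start"] = dr
    mut = Mutation(
        type="MOB", id="", parent_ids=[], seq_id=u1.seq_id,
        position=u2.pos, size=0, repeat_name=f1[0].family_name,
        strand=strand, duplication_size=max(tsd, 0), extras=extras,
    )
    # margin insertions from read-only junction bases, trying both
    # orientations and keeping whichever reproduces the junctions
    candidates = [mut]
    for ins_l in ({jc_left.unique_read_seq, revcomp(jc_left.unique_read_seq)}
                  if jc_left.unique_read_seq else {""}):
        for ins_r in ({jc_right.unique_read_seq,
                       revcomp(jc_right.unique_read_seq)}
                      if jc_right.unique_read_seq else {""}):
            if not ins_l and not ins_r:
                continue
            e = dict(extras)
            if ins_l:
                e["ins_start"] = ins_l
            if ins_r:
                e["ins_end"] = ins_r
            candidates.append(replace(mut, extras=e))
    for cand in candidates:
        if _mob_reproduces_junctions(cand, ref, jc_left, jc_right):
            return cand
    return None


def _mob_reproduces_junctions(mut: Mutation, ref: ReferenceSet,
                              jc_left: JCEntry, jc_right: JCEntry,
                              flank: int = 30) -> bool:
    gd = GenomeDiff()
    gd.add_mutation(replace(mut, id="1"))
    try:
        mutant = apply_mutations(gd, ref)
    except ValueError:
        return False
    from .gd import mob_insert_sequence

    ins_len = len(mob_insert_sequence(ref, mut))
    cut = mut.position + mut.duplication_size - 1
    mseq = mutant.sequence(mut.seq_id)
    windows = []
    for b in (cut, cut + ins_len):
        lo = max(0, b - flank)
        hi = min(len(mseq), b + flank)
        windows.append(mseq[lo:hi])
    for jc in (jc_left, jc_right):
        jseq = jc_junction_sequence(jc, ref, flank=flank // 2)
        if not any(jseq in w or revcomp(jseq) in w for w in windows):
            return False
    return True


# ---------------------------------------------------------------------------
# the five rules


def call_structural_variants(jc: list[JCEntry], mc: list[MCEntry],
                             ref: ReferenceSet, features: list[Feature],
                             mean_read_length: float):
    """Resolve evidence into mutation calls; returns (GenomeDiff, unassigned).

    The returned GenomeDiff holds every evidence entry plus the mutations
    predicted from them; ``unassigned`` lists the evidence entries consumed
    by no rule.
    """
    gd = GenomeDiff()
    for e in list(jc) + list(mc):
        gd.add_evidence(e)
    used: set[str] = set()

    def unused(items):
        return [e for e in items if e.id not in used]

    # (a) DEL from JC + MC with exactly matching breakpoints
    for j in unused(jc):
        s1, s2 = _jc_sides(j)
        if (s1.redundant or s2.redundant or s1.seq_id != s2.seq_id
                or s1.strand != -1 or s2.strand != +1
                or s2.pos <= s1.pos + 1):
            continue
        del_lo, del_hi = s1.pos + 1, s2.pos - 1
        for m in unused(mc):
            if m.seq_id != s1.seq_id:
                continue
            llo, lhi = _mc_left_range(m)
            rlo, rhi = _mc_right_range(m)
            if llo <= del_lo <= lhi and rlo <= del_hi <= rhi:
                gd.add_mutation(Mutation(
                    "DEL", "", [j.id, m.id], s1.seq_id, del_lo,
                    size=del_hi - del_lo + 1))
                used.update((j.id, m.id))
                break

    # (b) DEL between two same-orientation copies of one repeat family
    for m in unused(mc):
        if not (m.left_in_repeat and m.right_in_repeat):
            continue
        f1 = _repeat_feature_overlapping(features, m.seq_id,
                                         *_mc_left_range(m))
        if f1 is None:
            continue
        f2 = _repeat_feature_overlapping(features, m.seq_id,
                                         *_mc_right_range(m),
                                         family=f1.family_name)
        if f2 is None or f2 is f1 or f2.strand != f1.strand:
            continue
        gd.add_mutation(Mutation(
            "DEL", "", [m.id], m.seq_id, f1.end + 1,
            size=f2.end - f1.end,
            extras={"mediated": f1.family_name, "between": "repeat_copies"}))
        used.add(m.id)

    # (c) short DEL/INS/SUB/AMP from one unique junction
    for j in unused(jc):
        s1, s2 = _jc_sides(j)
        if (s1.redundant or s2.redundant or s1.seq_id != s2.seq_id):
            continue
        dist = abs(s2.pos - s1.pos)
        if dist >= mean_read_length:
            continue
        if s1.strand == -1 and s2.strand == +1 and s2.pos > s1.pos:
            gap = s2.pos - s1.pos - 1
            if gap > 0 and not j.unique_read_seq:
                gd.add_mutation(Mutation("DEL", "", [j.id], s1.seq_id,
                                         s1.pos + 1, size=gap))
            elif gap == 0 and j.unique_read_seq:
                gd.add_mutation(Mutation("INS", "", [j.id], s1.seq_id,
                                         s1.pos, new_seq=j.unique_read_seq))
            elif gap > 0 and j.unique_read_seq:
                gd.add_mutation(Mutation("SUB", "", [j.id], s1.seq_id,
                                         s1.pos + 1, size=gap,
                                         new_seq=j.unique_read_seq))
            else:
                continue
            used.add(j.id)
        elif s1.strand == +1 and s2.strand == -1 and s2.pos >= s1.pos:
            size = s2.pos - s1.pos + 1
            gd.add_mutation(Mutation("AMP", "", [j.id], s1.seq_id, s1.pos,
                                     size=size, new_copy_number=2))
            used.add(j.id)

    # (d) MOB from two junctions flanking one element family
    lefts = [j for j in unused(jc)
             if (_unique_redundant(j) and _unique_redundant(j)[0].strand == -1)]
    rights = [j for j in unused(jc)
              if (_unique_redundant(j) and _unique_redundant(j)[0].strand == +1)]
    for jl in lefts:
        if jl.id in used:
            continue
        for jr in rights:
            if jr.id in used or jl.id in used:
                continue
            mut = infer_mobile_insertion_geometry(jl, jr, ref, features)
            if mut is not None:
                mut.parent_ids = [jl.id, jr.id]
                gd.add_mutation(mut)
                used.update((jl.id, jr.id))
                break

    # (e) deletion mediated by an existing mobile element copy
    for m in unused(mc):
        if m.left_in_repeat == m.right_in_repeat:
            continue
        done = False
        for j in unused(jc):
            pair = _unique_redundant(j)
            if pair is None or done:
                continue
            u, r = pair
            if u.seq_id != m.seq_id:
                continue
            if m.left_in_repeat:
                # element adjacent on the left; deletion up to its right end
                el = _repeat_feature_overlapping(features, m.seq_id,
                                                 *_mc_left_range(m))
                if el is None or not el.family_name:
                    continue
                fb = _nearest_family_boundary(features, r)
                if (u.strand == +1 and u.pos == m.end + 1 and r.strand == -1
                        and fb is not None
                        and fb[0].family_name == el.family_name):
                    gd.add_mutation(Mutation(
                        "DEL", "", [m.id, j.id], m.seq_id, el.end + 1,
                        size=m.end - el.end,
                        extras={"mediated": el.family_name}))
                    used.update((m.id, j.id))
                    done = True
            else:
                el = _repeat_feature_overlapping(features, m.seq_id,
                                                 *_mc_right_range(m))
                if el is None or not el.family_name:
                    continue
                fb = _nearest_family_boundary(features, r)
                if (u.strand == -1 and u.pos == m.start - 1 and r.strand == +1
                        and fb is not None
                        and fb[0].family_name == el.family_name):
                    gd.add_mutation(Mutation(
                        "DEL", "", [m.id, j.id], m.seq_id, m.start,
                        size=el.start - m.start,
                        extras={"mediated": el.family_name}))
                    used.update((m.id, j.id))
                    done = True

    unassigned = [e for e in gd.evidence if e.id not in used]
    return gd, unassigned


# ---------------------------------------------------------------------------
# benchmark comparison


def _equivalent(a: str, b: str) -> bool:
    return a in b or b in a or revcomp(a) in b or b in revcomp(a)


def compare_junction_sets(predicted: list[str], truth: list[str]):
    """Sensitivity and precision of predicted junction sequences.

    Two junctions are equivalent when one sequence is an exact subsequence
    of the other or of its reverse complement.  Returns (sensitivity,
    precision, matched_pairs)."""
    pairs = []
    truth_hit = [False] * len(truth)
    pred_hit = [False] * len(predicted)
    for i, p in enumerate(predicted):
        for k, t in enumerate(truth):
            if _equivalent(p, t):
                pairs.append((i, k))
                truth_hit[k] = True
                pred_hit[i] = True
    sens = sum(truth_hit) / len(truth) if truth else 1.0
    prec = sum(pred_hit) / len(predicted) if predicted else (
        1.0 if not truth else 0.0)
    return sens, prec, pairs


def junction_sequences_for_truth(gd: GenomeDiff, ref: ReferenceSet,
                                 flank: int) -> list[str]:
    """Junction sequences each truth mutation creates, with ``flank`` bases
    on each side of the breakpoint (the benchmark uses mean read length - 5).

    Each mutation is applied on its own so coordinates are those of the
    reference; mutations are assumed well separated (> 2*flank apart)."""
    from .gd import mob_insert_sequence

    out = []
    for m in gd.mutations:
        single = GenomeDiff()
        single.add_mutation(replace(m, id="1", parent_ids=[]))
        mutant = apply_mutations(single, ref)
        mseq = mutant.sequence(m.seq_id)

        def window(b, half=flank):
            lo = max(0, b - half)
            hi = min(len(mseq), b + half)
            return mseq[lo:hi]

        if m.type in ("DEL", "SUB"):
            if m.type == "SUB":
                out.append(window(m.position - 1 + len(m.new_seq) // 2))
            else:
                out.append(window(m.position - 1))
        elif m.type == "INS":
            out.append(window(m.position + len(m.new_seq) // 2))
        elif m.type == "AMP":
            out.append(window(m.position + m.size - 1))
        elif m.type == "MOB":
            ins_len = len(mob_insert_sequence(ref, m))
            cut = m.position + m.duplication_size - 1
            out.append(window(cut))
            out.append(window(cut + ins_len))
    return out


def mutations_equivalent(a: Mutation, b: Mutation, ref: ReferenceSet) -> bool:
    """Two mutations are equivalent when applying either to the reference
    yields the same genome (this absorbs breakpoint-placement ambiguity from
    sequence homology at junctions)."""
    if a.type != b.type or a.seq_id != b.seq_id:
        return False
    if abs(a.position - b.position) > 1000:
        return False
    seqs = []
    for m in (a, b):
        gd = GenomeDiff()
        gd.add_mutation(replace(m, id="1", parent_ids=[]))
        try:
            seqs.append(apply_mutations(gd, ref).sequence(m.seq_id))
        except ValueError:
            return False
    return seqs[0] == seqs[1]


# ---------------------------------------------------------------------------
# mutation-rate arithmetic


def mutation_rate_estimate(n_events: int, n_lineages: int,
                           generations_per_lineage: float):
    """Poisson point estimate and exact 95% CI for a per-genome-per-
    generation mutation rate from pooled event counts.

    rate = n / (lineages * generations); the CI uses the chi-square form of
    the exact Poisson interval, scaled identically."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    denom = n_lineages * generations_per_lineage
    rate = n_events / denom
    lo = (stats.chi2.ppf(0.025, 2 * n_events) / 2 / denom
          if n_events > 0 else 0.0)
    hi = stats.chi2.ppf(0.975, 2 * (n_events + 1)) / 2 / denom
    return rate, lo, hi
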