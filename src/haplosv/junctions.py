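"""Junction candidates from split-read alignment pairs.

A read whose two local alignments land on discontinuous reference locations
implies a *new sequence junction*: the sequence the sample would contain if
those locations were joined.  A junction is fully described by six
parameters: two reference positions, two continuation directions, the number
of breakpoint *overlap* bases (``V``, read bases assignable to either side
without changing the junction sequence), and any *read-only* inserted bases
(``U``, present in the read but in neither reference flank).

Side convention: each side is ``(seq_id, pos, strand)`` with ``strand = -1``
meaning the reference flank occupies coordinates <= pos and enters the
junction in forward orientation when that side is side 1 (the left end of
the junction sequence), ``strand = +1`` meaning the flank occupies
coordinates >= pos.  With this labelling, reverse-complementing a junction
sequence swaps the two sides but leaves each side's strand unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .readmap import ReadAlignment, mismatch_penalty
from .refio import ReferenceSet, revcomp

__all__ = [
    "JunctionSide",
    "AlignmentPair",
    "JunctionCandidate",
    "split_alignment_at_indels",
    "pair_passes_guards",
    "pairs_for_read",
    "make_candidate",
    "canonicalize",
    "collapse_candidates",
    "prescore_and_select",
    "build_junction_sequence",
    "overlap_bound",
]


def overlap_bound(read_length: int) -> float:
    """Maximum allowed overlap V or read-only length |U|: 12 + 0.4(L-12)."""
    return 12.0 + 0.4 * (read_length - 12)


@dataclass(frozen=True)
class JunctionSide:
    seq_id: str
    pos: int  # 1-based reference coordinate of the outermost matched base
    strand: int  # -1: flank occupies coords <= pos; +1: coords >= pos
    redundant: bool = False  # side matches multiple reference places equally

    def key(self):
        return (self.seq_id, self.pos, self.strand)


@dataclass
class Support:
    """One read supporting a candidate: its first-base position projected to
    candidate-sequence coordinates, its strand there, and whether it spans
    the breakpoint core (overlap / read-only bases)."""

    offset: int  # 0-based start of the read on the candidate sequence
    strand: int
    read_id: str
    read_length: int
    crosses: bool


@dataclass
class AlignmentPair:
    """Two alignments of one read flanking a putative junction.

    ``r1..s1`` / ``r2..s2`` are the 1-based read intervals of side 1 / side 2
    (side 1 contains read base 1); ``a1,a2`` / ``b1,b2`` are the reference
    coordinates matching ``r1,s1`` / ``r2,s2``.  ``V`` counts overlap bases
    (``s1 >= r2``); ``U`` holds read-only bases (``r2 > s1 + 1``).
    """

    side1: ReadAlignment
    side2: ReadAlignment
    read_seq: str
    r1: int
    s1: int
    r2: int
    s2: int
    a1: int
    a2: int
    b1: int
    b2: int
    V: int
    U: str

    @property
    def read_span(self) -> int:
        return self.s2 - self.r1 + 1


# ---------------------------------------------------------------------------
# indel splitting


def _aln_mismatch_read_positions(aln: ReadAlignment) -> set[int]:
    """1-based as-sequenced read positions inside X runs."""
    out = set()
    pos = aln.read_start
    for op, length in aln.edit_ops:
        if op == "X":
            out.update(range(pos, pos + length))
        if op in ("=", "X", "I"):
            pos += length
    return out


def _extend_scores(read_codes: list[str], ref: ReferenceSet, seq_id: str,
                   read_pos: int, ref_pos: int, dr: int, dref: int,
                   limit: int, pen: float) -> int:
    """Greedy maximal-score ungapped extension; returns #bases to extend."""
    n = len(read_codes)
    reflen = ref.length(seq_id)
    best, bestk, cur = 0.0, 0, 0.0
    k = 0
    while k < limit:
        rp = read_pos + dr * (k + 1)
        gp = ref_pos + dref * (k + 1)
        if not (1 <= rp <= n and 1 <= gp <= reflen):
            break
        rb = read_codes[rp - 1]
        gb = ref.sequence(seq_id)[gp - 1]
        if dref * dr < 0:
            gb = revcomp(gb)
        if rb == gb and rb != "N":
            cur += 1.0
        else:
            cur -= pen
        k += 1
        if cur > best:
            best, bestk = cur, k
    return bestk


def split_alignment_at_indels(aln: ReadAlignment, ref: ReferenceSet,
                              read_seq: str, min_indel: int = 3,
                              base_quality: float = 40.0) -> list[ReadAlignment]:
    """Split a gapped alignment into separate alignments at indels >= min_indel.

    Each piece is then re-extended maximally (score-wise, ungapped) across
    the split point so that short tandem-duplication insertions yield the
    same two overlapping alignments a split-read mapper would have reported
    directly.  Indels shorter than ``min_indel`` are retained in place.
    """
    if not any(op in "ID" and ln >= min_indel for op, ln in aln.edit_ops):
        return [aln]
    # work in alignment orientation: query positions increase, ref increases
    # for '+', decreases for '-' (as-sequenced read coords kept throughout)
    pieces: list[tuple[int, int, int, int, list]] = []
    rpos = aln.read_start
    gpos = aln.ref_start if aln.strand == "+" else aln.ref_end
    dg = 1 if aln.strand == "+" else -1
    cur_ops: list = []
    cur_r, cur_g = rpos, gpos
    for op, length in aln.edit_ops:
        if op in "ID" and length >= min_indel:
            if cur_ops:
                pieces.append((cur_r, rpos - 1, cur_g, gpos - dg, cur_ops))
            if op == "I":
                rpos += length
            else:
                gpos += dg * length
            cur_ops = []
            cur_r, cur_g = rpos, gpos
        else:
            cur_ops.append((op, length))
            if op in ("=", "X"):
                rpos += length
                gpos += dg * length
            elif op == "I":
                rpos += length
            elif op == "D":
                gpos += dg * length
    if cur_ops:
        pieces.append((cur_r, rpos - 1, cur_g, gpos - dg, cur_ops))

    pen = float(mismatch_penalty(base_quality))
    out = []
    limit = len(read_seq)
    for i, (r0, r1, g0, g1, ops) in enumerate(pieces):
        ext_l = ext_r = 0
        if i > 0:  # extend start backwards across the split
            ext_l = _extend_scores(read_seq, ref, aln.seq_id, r0, g0,
                                   -1, -dg, limit, pen)
        if i < len(pieces) - 1:  # extend end forwards
            ext_r = _extend_scores(read_seq, ref, aln.seq_id, r1, g1,
                                   +1, dg, limit, pen)
        nr0, nr1 = r0 - ext_l, r1 + ext_r
        ng0, ng1 = g0 - dg * ext_l, g1 + dg * ext_r
        new_ops = _recompute_match_ops(read_seq, ref, aln.seq_id,
                                       nr0, nr1, ng0, dg, ops, r0, g0)
        from .readmap import score_alignment

        score = score_alignment(read_seq[nr0 - 1 : nr1], base_quality, new_ops)
        out.append(
            ReadAlignment(
                read_id=aln.read_id,
                read_start=nr0,
                read_end=nr1,
                seq_id=aln.seq_id,
                ref_start=min(ng0, ng1),
                ref_end=max(ng0, ng1),
                strand=aln.strand,
                score=score,
                edit_ops=new_ops,
                read_length=aln.read_length,
            )
        )
    return out


def _recompute_match_ops(read_seq, ref, seq_id, nr0, nr1, ng0, dg,
                         inner_ops, r0, g0):
    """Rebuild =/X runs for an extended piece (small indels kept inside)."""
    seq = ref.sequence(seq_id)
    ops = []

    def emit(op, n=1):
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1][1] += n
        else:
            ops.append([op, n])

    # leading extension
    rp, gp = nr0, ng0
    while rp < r0:
        gb = seq[gp - 1] if dg == 1 else revcomp(seq[gp - 1])
        emit("=" if read_seq[rp - 1] == gb else "X")
        rp += 1
        gp += dg
    for op, length in inner_ops:
        emit(op, length)
        if op in ("=", "X"):
            rp += length
            gp += dg * length
        elif op == "I":
            rp += length
        elif op == "D":
            gp += dg * length
    while rp <= nr1:
        gb = seq[gp - 1] if dg == 1 else revcomp(seq[gp - 1])
        emit("=" if read_seq[rp - 1] == gb else "X")
        rp += 1
        gp += dg
    return tuple(tuple(o) for o in ops)


# ---------------------------------------------------------------------------
# guards and pairing


def pair_passes_guards(side1: ReadAlignment, side2: ReadAlignment,
                       L: int) -> tuple[bool, int, int]:
    """Apply the per-pair junction guards; returns (ok, V, u_len).

    side 1 must begin at read base 1; side 2 must reach (or nearly reach,
    for reads > 50 bases) the final base; each side must contribute at least
    20% of the read outside the overlap; overlap and read-only lengths are
    bounded by 12 + 0.4(L - 12).
    """
    r1, s1 = side1.read_start, side1.read_end
    r2, s2 = side2.read_start, side2.read_end
    if r1 != 1:
        return False, 0, 0
    if L <= 50:
        if s2 != L:
            return False, 0, 0
    elif s2 < L - 0.1 * (L - 50):
        return False, 0, 0
    if min(s1, r2) - r1 + 1 < 0.2 * L:
        return False, 0, 0
    if s2 - max(s1, r2) + 1 < 0.2 * L:
        return False, 0, 0
    V = s1 - r2 + 1 if s1 >= r2 else 0
    u_len = r2 - s1 - 1 if r2 > s1 + 1 else 0
    bound = overlap_bound(L)
    if V > bound or u_len > bound:
        return False, V, u_len
    return True, V, u_len


def pairs_for_read(alignments: list[ReadAlignment], read_seq: str,
                   max_span_fraction: float = 0.9) -> list[AlignmentPair]:
    """All guard-passing alignment pairs for one read.

    Skipped entirely when any single alignment spans >= 90% of the read.
    Among passing pairs, only those achieving the read's maximum spanned
    length (s2 - r1 + 1) survive (guard 6).
    """
    L = len(read_seq)
    if any(a.read_span >= max_span_fraction * L for a in alignments):
        return []
    raw = []
    for i, s1 in enumerate(alignments):
        if s1.read_start != 1:
            continue
        for j, s2 in enumerate(alignments):
            if i == j:
                continue
            ok, V, u_len = pair_passes_guards(s1, s2, L)
            if not ok:
                continue
            raw.append((s1, s2, V, u_len))
    if not raw:
        return []
    best_span = max(s2.read_end - s1.read_start + 1 for s1, s2, _, _ in raw)
    out = []
    for s1, s2, V, u_len in raw:
        if s2.read_end - s1.read_start + 1 != best_span:
            continue
        U = read_seq[s1.read_end : s2.read_start - 1] if u_len else ""
        out.append(
            AlignmentPair(
                side1=s1, side2=s2, read_seq=read_seq,
                r1=s1.read_start, s1=s1.read_end,
                r2=s2.read_start, s2=s2.read_end,
                a1=s1.ref_pos_of_read_pos(s1.read_start),
                a2=s1.ref_pos_of_read_pos(s1.read_end),
                b1=s2.ref_pos_of_read_pos(s2.read_start),
                b2=s2.ref_pos_of_read_pos(s2.read_end),
                V=V, U=U,
            )
        )
    return out


# ---------------------------------------------------------------------------
# candidate construction


@dataclass
class JunctionCandidate:
    side1: JunctionSide
    side2: JunctionSide
    overlap: int  # V (0 when unique_seq is nonempty)
    unique_seq: str  # U in junction orientation
    sequence: str
    flank1: int  # achieved flank length left of the core
    flank2: int  # achieved flank length right of the core
    core_start: int  # 0-based start of core within sequence (len V or |U|)
    supports: list[Support] = field(default_factory=list)
    score: int = 0  # coverage evenness score S

    @property
    def core_len(self) -> int:
        return self.overlap if self.overlap else len(self.unique_seq)

    @property
    def description(self):
        return (self.side1.key(), self.side2.key(), self.overlap,
                self.unique_seq)

    def same_fragment(self) -> bool:
        return self.side1.seq_id == self.side2.seq_id

    def coordinate_distance(self) -> int:
        if not self.same_fragment():
            return 1 << 40
        return abs(self.side2.pos - self.side1.pos)


def _flank_left(ref: ReferenceSet, side: JunctionSide, length: int) -> str:
    """Reference flank entering the junction from the left, in junction
    orientation, ending at (and including) side.pos."""
    if side.strand == -1:
        start = max(1, side.pos - length + 1)
        return ref.subsequence(side.seq_id, start, side.pos, "+")
    end = min(ref.length(side.seq_id), side.pos + length - 1)
    return ref.subsequence(side.seq_id, side.pos, end, "-")


def _flank_right(ref: ReferenceSet, side: JunctionSide, length: int,
                 skip: int = 0) -> str:
    """Flank leaving the junction to the right, starting ``skip`` bases past
    side.pos in the side's own direction."""
    if side.strand == +1:
        start = side.pos + skip
        end = min(ref.length(side.seq_id), start + length - 1)
        if start > end:
            return ""
        return ref.subsequence(side.seq_id, start, end, "+")
    start = side.pos - skip
    lo = max(1, start - length + 1)
    if lo > start:
        return ""
    return ref.subsequence(side.seq_id, lo, start, "-")


def build_junction_sequence(ref: ReferenceSet, side1: JunctionSide,
                            side2: JunctionSide, overlap: int,
                            unique_seq: str, flank: int):
    """Construct the junction sequence with up-to-``flank`` reference bases
    beyond the breakpoint core on each side.

    Returns ``(sequence, flank1, flank2, core_start)`` with achieved flank
    lengths after clipping at sequence ends.  For an overlap junction the
    core bases are drawn from side 1's reference (identical to side 2's by
    construction); for a read-only junction they are ``unique_seq``.
    """
    if overlap and unique_seq:
        raise ValueError("junction cannot have both overlap and read-only bases")
    if overlap:
        left = _flank_left(ref, side1, flank + overlap)
        right = _flank_right(ref, side2, flank, skip=overlap)
        f1 = len(left) - overlap
        if f1 < 0:
            raise ValueError("flank shorter than overlap at a sequence end")
        return left + right, f1, len(right), f1
    left = _flank_left(ref, side1, flank)
    right = _flank_right(ref, side2, flank, skip=0)
    return left + unique_seq + right, len(left), len(right), len(left)


def _trim_overlap(pair: AlignmentPair) -> AlignmentPair | None:
    """Trim imperfect overlap: each side's alignment is pulled back until its
    portion of the overlap region is a perfect match (no mismatches/indels)."""
    if pair.V <= 0:
        return pair
    mm1 = _aln_mismatch_read_positions(pair.side1)
    mm2 = _aln_mismatch_read_positions(pair.side2)
    if pair.side1.has_indel() or pair.side2.has_indel():
        # indels inside the overlap invalidate linear coordinates; treat every
        # overlap position of that side as imperfect
        if pair.side1.has_indel():
            mm1 |= set(range(pair.r2, pair.s1 + 1))
        if pair.side2.has_indel():
            mm2 |= set(range(pair.r2, pair.s1 + 1))
    s1 = pair.s1
    while s1 >= pair.r2 and any(p in mm1 for p in range(pair.r2, s1 + 1)):
        s1 -= 1
    r2 = pair.r2
    while r2 <= pair.s1 and any(p in mm2 for p in range(r2, pair.s1 + 1)):
        r2 += 1
    if s1 < pair.r1 or r2 > pair.s2:
        return None  # trimming consumed a whole side
    if s1 == pair.s1 and r2 == pair.r2:
        return pair
    V = s1 - r2 + 1 if s1 >= r2 else 0
    U = pair.read_seq[s1 : r2 - 1] if r2 > s1 + 1 else ""
    return replace(
        pair,
        s1=s1, r2=r2, V=V, U=U,
        a2=pair.side1.ref_pos_of_read_pos(s1),
        b1=pair.side2.ref_pos_of_read_pos(r2),
    )


def make_candidate(pair: AlignmentPair, ref: ReferenceSet,
                   max_read_length: int,
                   side1_redundant: bool = False,
                   side2_redundant: bool = False) -> JunctionCandidate | None:
    """Build the junction candidate a guard-passing alignment pair implies.

    Overlap regions containing mismatches or indels are first trimmed back
    until the remainder perfectly matches both reference locations; if a
    whole side is consumed the candidate is discarded (returns None).  The
    junction sequence gets ``max_read_length - 1 - core`` flanking reference
    bases per side so any read crossing the breakpoint aligns better to the
    junction than to the reference.
    """
    trimmed = _trim_overlap(pair)
    if trimmed is None:
        return None
    p = trimmed
    strand1 = -1 if p.a2 >= p.a1 else +1
    strand2 = +1 if p.b2 >= p.b1 else -1
    side1 = JunctionSide(p.side1.seq_id, p.a2, strand1, side1_redundant)
    side2 = JunctionSide(p.side2.seq_id, p.b1, strand2, side2_redundant)
    core = p.V if p.V else len(p.U)
    flank = (max_read_length - 1) - core
    if flank < 1:
        return None
    try:
        seq, f1, f2, cs = build_junction_sequence(
            ref, side1, side2, p.V, p.U, flank
        )
    except ValueError:
        return None
    cand = JunctionCandidate(
        side1=side1, side2=side2, overlap=p.V, unique_seq=p.U,
        sequence=seq, flank1=f1, flank2=f2, core_start=cs,
    )
    # project the read onto the candidate sequence: the junction was built in
    # the read's own orientation (side 1 holds read base 1), so the read runs
    # forward along it; side 1 covers junction coords up to cs + V - 1
    # (cs - 1 for a read-only core) and the read's first base sits d bases
    # before that endpoint.
    d = abs(side1.pos - p.a1)
    end1 = cs + p.V - 1 if p.V else cs - 1
    offset = end1 - d
    rlen = len(p.read_seq)
    crosses = offset <= cs - 1 and offset + rlen - 1 >= cs + cand.core_len
    cand.supports.append(
        Support(offset=offset, strand=+1, read_id=p.side1.read_id,
                read_length=rlen, crosses=crosses)
    )
    return canonicalize(cand)


def canonicalize(cand: JunctionCandidate) -> JunctionCandidate:
    """Put side 1 on the alphabetically-first sequence (or lower coordinate
    on the same sequence), reverse-complementing the junction sequence when
    the sides swap.  Idempotent."""
    k1 = (cand.side1.seq_id, cand.side1.pos, cand.side1.strand)
    k2 = (cand.side2.seq_id, cand.side2.pos, cand.side2.strand)
    if k1 <= k2:
        return cand
    n = len(cand.sequence)
    new_supports = [
        Support(
            offset=n - (s.offset + s.read_length),
            strand=-s.strand,
            read_id=s.read_id,
            read_length=s.read_length,
            crosses=s.crosses,
        )
        for s in cand.supports
    ]
    return JunctionCandidate(
        side1=cand.side2,
        side2=cand.side1,
        overlap=cand.overlap,
        unique_seq=revcomp(cand.unique_seq),
        sequence=revcomp(cand.sequence),
        flank1=cand.flank2,
        flank2=cand.flank1,
        core_start=n - cand.core_start - cand.core_len,
        supports=new_supports,
        score=cand.score,
    )


# ---------------------------------------------------------------------------
# collapse and selection


def _merge_supports_into(target: JunctionCandidate, other: JunctionCandidate):
    """Transfer ``other``'s supports onto ``target`` (whose sequence is a
    subsequence of other's, possibly reverse-complemented)."""
    shift = other.sequence.find(target.sequence)
    if shift >= 0:
        for s in other.supports:
            target.supports.append(replace(s, offset=s.offset - shift))
        return
    rc = revcomp(other.sequence)
    shift = rc.find(target.sequence)
    if shift < 0:
        # sequences equivalent only through exact equality handled earlier
        target.supports.extend(other.supports)
        return
    n = len(other.sequence)
    for s in other.supports:
        off = n - (s.offset + s.read_length)
        target.supports.append(
            replace(s, offset=off - shift, strand=-s.strand)
        )


def collapse_candidates(cands: list[JunctionCandidate]) -> list[JunctionCandidate]:
    """Merge duplicate and sequence-equivalent candidates.

    Candidates with identical description and sequence are merged outright.
    Among candidates whose sequences are subsequences of one another (or of
    reverse complements), the shortest sequence survives, preferring
    junctions with both sides on the same reference fragment and then
    minimal coordinate distance; supports are unioned onto the survivor and
    per-side redundancy flags are OR-ed for exact duplicates.
    """
    # 1. exact merge
    by_desc: dict[tuple, JunctionCandidate] = {}
    for c in cands:
        key = (c.description, c.sequence)
        if key in by_desc:
            tgt = by_desc[key]
            tgt.supports.extend(c.supports)
            tgt.side1 = replace(tgt.side1,
                                redundant=tgt.side1.redundant or c.side1.redundant)
            tgt.side2 = replace(tgt.side2,
                                redundant=tgt.side2.redundant or c.side2.redundant)
        else:
            by_desc[key] = c
    unique = list(by_desc.values())
    # 2. subsequence merge, shortest survivor
    unique.sort(key=lambda c: (len(c.sequence), not c.same_fragment(),
                               c.coordinate_distance(), c.description))
    survivors: list[JunctionCandidate] = []
    for c in unique:
        merged = False
        for s in survivors:
            fwd = s.sequence in c.sequence
            if fwd or s.sequence in revcomp(c.sequence):
                _merge_supports_into(s, c)
                # a side is redundant if any merged description had
                # repeat-multiple placements for it
                o1, o2 = (c.side1, c.side2) if fwd else (c.side2, c.side1)
                s.side1 = replace(s.side1,
                                  redundant=s.side1.redundant or o1.redundant)
                s.side2 = replace(s.side2,
                                  redundant=s.side2.redundant or o2.redundant)
                merged = True
                break
        if not merged:
            survivors.append(c)
    return survivors


def evenness_score(cand: JunctionCandidate) -> int:
    """Count distinct (start position, strand) classes among supports that
    span the breakpoint core; opposite-strand reads with the same start
    each count once."""
    return len({(s.offset, s.strand) for s in cand.supports if s.crosses})


def prescore_and_select(cands: list[JunctionCandidate],
                        reference_length: int,
                        max_candidates: int = 5000,
                        max_total_len_fraction: float = 0.10,
                        min_kept: int = 100,
                        min_score: int = 2) -> list[JunctionCandidate]:
    """Score candidates by coverage evenness and keep the best.

    Candidates scoring below ``min_score`` are dropped.  The rest are sorted
    by score descending and admitted whole score-class at a time until a
    class would push the count past ``max_candidates`` or the cumulative
    sequence length past ``max_total_len_fraction`` of the reference, once
    at least ``min_kept`` candidates are already in.
    """
    for c in cands:
        c.score = evenness_score(c)
    pool = [c for c in cands if c.score >= min_score]
    pool.sort(key=lambda c: (-c.score, c.description))
    budget = max_total_len_fraction * reference_length
    selected: list[JunctionCandidate] = []
    total_len = 0
    i = 0
    while i < len(pool):
        j = i
        while j < len(pool) and pool[j].score == pool[i].score:
            j += 1
        cls = pool[i:j]
        cls_len = sum(len(c.sequence) for c in cls)
        if len(selected) >= min_kept and (
            len(selected) + len(cls) > max_candidates
            or total_len + cls_len > budget
        ):
            break
        selected.extend(cls)
        total_len += cls_len
        i = j
    return selected
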