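"""Statistical evaluation of junction candidates.

All input reads are re-mapped against the candidate junction sequences with
the stringent mapping criteria.  A read that matches the reference better
than every candidate is assigned to the reference; otherwise it is held,
with every candidate it ties, in an unresolved pool.  Candidates are then
evaluated in descending order of their recomputed coverage evenness score
``S`` — the number of distinct (start position, strand) classes of reads
that extend across the breakpoint core (overlap or read-only bases) and any
ambiguous continuation bases.

The expected maximum score for a junction is

    S_max = 2 * (ceil(L_bar) - 1 - overlap - C1 - C2)

(two strands; one slot per read start position that can unambiguously
support the junction), and the chance of observing a score as low as S under
typical genome-wide coverage is

    p = sum_x NegBinom(x; mu_cov, alpha_cov) * BinomCDF(S; S_max, p_succ(x))

with per-slot success probability p_succ(x) = 1 - p0_bar^(x / mu_cov), the
chance that at least one read starts in a slot when local coverage is x.
The junction's *skew* is -log10(p); candidates whose skew exceeds the
threshold (default 3.0) are rejected, the best of them kept as marginal
predictions.  Accepted junctions claim their unresolved reads, which then
no longer count toward later candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .coverage import CoverageModel, nbinom_params
from .junctions import JunctionCandidate, JunctionSide
from .readmap import MapperParams, ReadSet, GenomeIndex, _stage_map
from .refio import ReferenceSet, Feature

__all__ = [
    "JunctionTestResult",
    "JunctionResolution",
    "SplitPiece",
    "remap_and_resolve",
    "continuation_lengths",
    "max_evenness_score",
    "junction_skew_pvalue",
    "evaluate_all_junctions",
    "place_breakpoint",
    "split_reads_onto_reference",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class JunctionTestResult:
    candidate: JunctionCandidate
    S_obs: int
    S_max: int
    C1: int
    C2: int
    p_value: float
    skew: float
    status: str  # accepted | rejected-marginal | rejected | rejected-unscorable
    claimed_reads: list[int] = field(default_factory=list)
    # breakpoint placement (filled by place_breakpoint)
    side1_resolved: JunctionSide | None = None
    side2_resolved: JunctionSide | None = None
    overlap_kept1: int = 0  # core bases finally assigned to side 1
    cand_index: int = -1  # position in the evaluated candidate list


@dataclass
class JunctionResolution:
    """Read assignments after re-mapping to candidate sequences."""

    n_reads: int
    # per candidate: list of (read_index, jstart, jend, strand) with 0-based
    # inclusive coordinates on the candidate sequence
    cand_reads: list[list[tuple[int, int, int, int]]]
    ref_better: np.ndarray  # reads the reference claims outright
    tied_reads: dict[int, list[int]]  # read -> tied candidate indices


def candidate_id(i: int) -> str:
    return f"jc{i:06d}"


def remap_and_resolve(reads: ReadSet, candidates: list[JunctionCandidate],
                      best_ref_scores: np.ndarray,
                      stringent: MapperParams) -> JunctionResolution:
    """Map all reads to the candidate sequences and resolve best matches.

    ``best_ref_scores`` holds each read's best alignment score against the
    reference (-inf when unmapped there).  A read goes to the reference when
    the reference score strictly beats every candidate; otherwise it is held
    unresolved with every candidate whose score ties its best junction score.
    """
    n = len(reads)
    res = JunctionResolution(
        n_reads=n,
        cand_reads=[[] for _ in candidates],
        ref_better=np.ones(n, dtype=bool),
        tied_reads={},
    )
    if not candidates or n == 0:
        return res
    jref = ReferenceSet()
    for i, c in enumerate(candidates):
        jref.add_sequence(candidate_id(i), c.sequence)
    gidx = GenomeIndex(jref, pad=max(512, reads.max_length + 1))
    batch = _stage_map(reads, gidx, stringent, np.arange(n), 0)
    if not len(batch):
        return res
    bestj = np.full(n, -np.inf)
    np.maximum.at(bestj, batch.read, batch.score)
    keep = batch.score >= bestj[batch.read] - 1e-6
    junction_wins = bestj >= best_ref_scores - 1e-6
    keep &= junction_wins[batch.read]
    res.ref_better = ~junction_wins
    cidx, local = gidx.locate_batch(batch.gstart)
    for k in np.flatnonzero(keep):
        read = int(batch.read[k])
        ci = int(cidx[k])
        jstart = int(local[k])
        jend = jstart + int(batch.qend[k] - batch.qstart[k])
        strand = int(batch.strand[k])
        res.cand_reads[ci].append((read, jstart, jend, strand))
        res.tied_reads.setdefault(read, []).append(ci)
    return res


# ---------------------------------------------------------------------------
# continuation and S_max


def continuation_lengths(cand: JunctionCandidate, ref: ReferenceSet):
    """Ambiguous continuation lengths (C1 left of the core, C2 right).

    A read anchored on one side of a junction only supports the junction —
    rather than the unmutated reference — once it aligns past the point
    where the junction sequence diverges from the reference continuation of
    the anchored side.  For short tandem-repeat deletions this requires
    extending several bases beyond the breakpoint overlap.
    """
    J = cand.sequence
    cs = cand.core_start
    core = cand.core_len
    ce = cs + core - 1
    V = cand.overlap

    # left: junction bases left of the core vs side 2's reference
    # continuation; junction coord x maps through side 2 with anchor x_b1
    s2 = cand.side2
    x_b1 = cs if V else ce + 1
    run = 0
    idx0 = cs - 1 if V else ce
    while True:
        x = idx0 - run
        if x < 0:
            break
        refc = s2.pos + (x - x_b1) * s2.strand
        if refc < 1 or refc > ref.length(s2.seq_id):
            break
        base = ref.sequence(s2.seq_id)[refc - 1]
        if s2.strand == -1:
            base = base.translate(_COMP)
        if x <= len(J) - 1 and J[x] == base and base != "N":
            run += 1
        else:
            break
    s_req = idx0 - run
    C1 = (cs - 1) - min(s_req, cs - 1)

    # right: junction bases right of the core vs side 1's continuation
    s1 = cand.side1
    x_a2 = ce if V else cs - 1
    d1 = 1 if s1.strand == -1 else -1  # junction coord vs ref coord direction
    run = 0
    idx0 = ce + 1 if V else cs
    while True:
        x = idx0 + run
        if x > len(J) - 1:
            break
        refc = s1.pos + d1 * (x - x_a2)
        if refc < 1 or refc > ref.length(s1.seq_id):
            break
        base = ref.sequence(s1.seq_id)[refc - 1]
        if s1.strand == +1:
            base = base.translate(_COMP)
        if J[x] == base and base != "N":
            run += 1
        else:
            break
    e_req = idx0 + run
    C2 = max(e_req, ce + 1) - (ce + 1)
    return C1, C2


def max_evenness_score(mean_read_length: float, overlap: int,
                       C1: int, C2: int) -> int:
    """Expected maximum evenness score: two strand slots per unambiguous
    read start position."""
    return 2 * (int(np.ceil(mean_read_length)) - 1 - overlap - C1 - C2)


def junction_skew_pvalue(S_obs: int, S_max: int, mu: float, alpha: float,
                         p0: float) -> tuple[float, float]:
    """Skew p-value: the chance of an evenness score <= ``S_obs`` at a
    typical reference position, integrating over the coverage distribution.

    Computed in log space so extreme skews never underflow to a hard zero.
    Returns ``(p_value, skew)`` with skew = -log10(p).
    """
    if not (0 <= S_obs <= S_max):
        raise ValueError("require 0 <= S_obs <= S_max")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must be a probability")
    n, p = nbinom_params(mu, alpha)
    xmax = int(stats.nbinom.ppf(1 - 1e-6, n, p)) + 1
    x = np.arange(xmax + 1)
    logw = stats.nbinom.logpmf(x, n, p)
    with np.errstate(divide="ignore"):
        if p0 == 0.0:
            psucc = np.where(x > 0, 1.0, 0.0)
        else:
            psucc = 1.0 - np.power(p0, x / mu)
        logcdf = stats.binom.logcdf(S_obs, S_max, psucc)
    logp = float(logsumexp(logw + logcdf))
    logp = min(logp, 0.0)
    pval = float(np.exp(logp))
    if pval == 0.0 and np.isfinite(logp):
        pval = float(np.nextafter(0.0, 1.0))
    skew = -logp / np.log(10.0)
    return pval, max(skew, 0.0)


# ---------------------------------------------------------------------------
# iterative evaluation


def _score_candidate(cand: JunctionCandidate, entries, claimed,
                     C1: int, C2: int) -> tuple[int, list[int]]:
    """Evenness score from re-mapped reads plus the reads involved."""
    cs = cand.core_start
    ce = cs + cand.core_len - 1
    ls = cs - 1 - C1
    rs = ce + 1 + C2
    classes = set()
    involved = []
    for read, jstart, jend, strand in entries:
        if claimed[read]:
            continue
        involved.append(read)
        if jstart <= ls and jend >= rs:
            first = jstart if strand == 1 else jend
            classes.add((first, strand))
    return len(classes), involved


def evaluate_all_junctions(candidates: list[JunctionCandidate],
                           resolution: JunctionResolution,
                           model: CoverageModel,
                           mean_read_length: float,
                           ref: ReferenceSet,
                           skew_threshold: float = 3.0,
                           max_marginal: int = 100):
    """Accept or reject candidates in descending recomputed-score order.

    Unresolved reads count toward the candidate currently under evaluation;
    once a candidate is accepted it permanently claims its reads, removing
    them from the pools of candidates evaluated later.  Returns
    ``(accepted, marginal)`` result lists; ``marginal`` holds the
    best-scoring rejected candidates.
    """
    claimed = np.zeros(resolution.n_reads, dtype=bool)
    remaining = set(range(len(candidates)))
    cont_cache: dict[int, tuple[int, int]] = {}
    accepted: list[JunctionTestResult] = []
    rejected: list[JunctionTestResult] = []
    while remaining:
        scored = []
        for i in remaining:
            if i not in cont_cache:
                cont_cache[i] = continuation_lengths(candidates[i], ref)
            C1, C2 = cont_cache[i]
            S, involved = _score_candidate(candidates[i],
                                           resolution.cand_reads[i],
                                           claimed, C1, C2)
            scored.append((S, candidates[i].description, i, involved))
        scored.sort(key=lambda t: (-t[0], t[1]))
        S, _desc, i, involved = scored[0]
        remaining.discard(i)
        cand = candidates[i]
        C1, C2 = cont_cache[i]
        S_max = max_evenness_score(mean_read_length, cand.core_len, C1, C2)
        if S_max <= 0:
            rejected.append(JunctionTestResult(
                cand, S, 0, C1, C2, 1.0, 0.0, "rejected-unscorable",
                cand_index=i))
            continue
        S_obs = min(S, S_max)
        sids = {cand.side1.seq_id, cand.side2.seq_id}
        pvals = []
        for sid in sids:
            pv, _ = junction_skew_pvalue(S_obs, S_max, model.mu[sid],
                                         model.alpha[sid], model.p0[sid])
            pvals.append(pv)
        pval = max(pvals)  # least significant side
        skew = -np.log10(pval) if pval > 0 else np.inf
        if skew <= skew_threshold:
            result = JunctionTestResult(cand, S_obs, S_max, C1, C2, pval,
                                        float(skew), "accepted",
                                        claimed_reads=involved, cand_index=i)
            claimed[involved] = True
            accepted.append(result)
        else:
            rejected.append(JunctionTestResult(
                cand, S_obs, S_max, C1, C2, pval, float(skew),
                "rejected-marginal", cand_index=i))
    rejected.sort(key=lambda r: -r.S_obs)
    for r in rejected[max_marginal:]:
        if r.status == "rejected-marginal":
            r.status = "rejected"
    marginal = [r for r in rejected if r.status == "rejected-marginal"]
    return accepted, marginal


# ---------------------------------------------------------------------------
# breakpoint placement


def _retract(side: JunctionSide, amount: int) -> JunctionSide:
    """Move a side's endpoint ``amount`` bases back toward its own flank
    (negative amounts extend it outward across the breakpoint)."""
    return replace(side, pos=side.pos - amount if side.strand == -1
                   else side.pos + amount)


def _snap_delta(side: JunctionSide, features: list[Feature],
                margin: int) -> int | None:
    """Retraction that lands this side exactly on the nearest repeat or
    mobile-element feature boundary within ``margin``; None if none."""
    best = None
    for f in features:
        if f.seq_id != side.seq_id or not f.is_repeat():
            continue
        boundary = f.start if side.strand == +1 else f.end
        dist = abs(side.pos - boundary)
        if dist <= margin and (best is None or dist < abs(best)):
            best = (side.pos - boundary) if side.strand == -1 \
                else (boundary - side.pos)
    return best


def place_breakpoint(result: JunctionTestResult, features: list[Feature],
                     repeat_margin: int = 20) -> JunctionTestResult:
    """Assign ambiguous overlap bases to the two junction sides.

    Rules in order: (1) snap a side to a repeat/mobile-element feature end
    within ``repeat_margin`` bases (possibly assigning overlap bases to both
    sides); (2) give all overlap to the side with only unique alignments
    when the other side is repeat-only; (3) give all overlap to the
    higher-priority side (sequence id, then coordinate).
    """
    cand = result.candidate
    V = cand.overlap
    w1 = _snap_delta(cand.side1, features, repeat_margin)
    w2 = _snap_delta(cand.side2, features, repeat_margin)
    if w1 is None and w2 is None:
        if cand.side1.redundant and not cand.side2.redundant:
            w1, w2 = V, 0
        elif cand.side2.redundant and not cand.side1.redundant:
            w1, w2 = 0, V
        else:
            w1, w2 = 0, V  # canonical side 1 has sort priority
    elif w1 is None:
        w1 = max(V - max(w2, 0), 0)
    elif w2 is None:
        w2 = max(V - max(w1, 0), 0)
    result.side1_resolved = _retract(cand.side1, w1)
    result.side2_resolved = _retract(cand.side2, w2)
    result.overlap_kept1 = V - min(max(w1, 0), V)
    return result


# ---------------------------------------------------------------------------
# read splitting


@dataclass(frozen=True)
class SplitPiece:
    read_id: str
    seq_id: str
    ref_start: int
    ref_end: int
    strand: str
    # False when the side maps to multiple reference locations equally well
    # (the piece was arbitrarily placed on one repeat copy and must count as
    # repeat coverage, not unique coverage)
    unique: bool = True


def split_reads_onto_reference(result: JunctionTestResult,
                               resolution: JunctionResolution,
                               reads: ReadSet,
                               candidate_index: int) -> list[SplitPiece]:
    """Split an accepted junction's reads at the placed breakpoint into
    reference alignments, one per junction side; pieces shorter than one
    base are dropped and read-only (inserted) bases belong to neither side.
    """
    cand = result.candidate
    cs = cand.core_start
    ce = cs + cand.core_len - 1
    V = cand.overlap
    if V:
        e1 = cs - 1 + result.overlap_kept1
        e2 = e1 + 1
    else:
        e1 = cs - 1
        e2 = ce + 1
    x_a2 = ce if V else cs - 1  # junction coord anchored at side1.pos
    x_b1 = cs if V else ce + 1  # junction coord anchored at side2.pos
    s1, s2 = cand.side1, cand.side2
    d1 = 1 if s1.strand == -1 else -1
    d2 = s2.strand
    out: list[SplitPiece] = []
    claimed = set(result.claimed_reads)
    for read, jstart, jend, strand in resolution.cand_reads[candidate_index]:
        if read not in claimed:
            continue
        rid = reads.read_id(read)
        # side-1 piece
        lo, hi = jstart, min(jend, e1)
        if hi >= lo:
            ra = s1.pos + d1 * (lo - x_a2)
            rb = s1.pos + d1 * (hi - x_a2)
            piece_strand = "+" if (d1 == 1) == (strand == 1) else "-"
            out.append(SplitPiece(rid, s1.seq_id, min(ra, rb), max(ra, rb),
                                  piece_strand, unique=not s1.redundant))
        # side-2 piece
        lo, hi = max(jstart, e2), jend
        if hi >= lo:
            ra = s2.pos + d2 * (lo - x_b1)
            rb = s2.pos + d2 * (hi - x_b1)
            piece_strand = "+" if (d2 == 1) == (strand == 1) else "-"
            out.append(SplitPiece(rid, s2.seq_id, min(ra, rb), max(ra, rb),
                                  piece_strand, unique=not s2.redundant))
    return out
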