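"""Read-depth statistics: censored negative-binomial fit and missing coverage.

Read depth across a haploid genome is well described by an overdispersed
Poisson (negative binomial) distribution with mean ``mu_cov`` and size
(overdispersion) parameter ``alpha_cov``.  The fit uses only *unique-only*
positions — those not matched by any read that maps to multiple reference
locations equally well — and is censored on the left at half the average
coverage (deleted regions with residual stray coverage) and on the right at
1.5 times the average (spurious pileups, amplified regions).

The same table yields ``p0_bar``, the average chance that no read starts at
a given (position, strand) slot, which calibrates the junction evenness
statistics, and the propagation threshold used to extend zero-coverage seed
regions into missing-coverage (MC) deletion evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CoverageTable",
    "CoverageModel",
    "MCEvidence",
    "tabulate_coverage",
    "tabulate_coverage_batch",
    "fit_censored_negbinom",
    "estimate_no_start_probability",
    "propagation_threshold",
    "find_missing_coverage",
    "nbinom_params",
]


def nbinom_params(mu: float, alpha: float):
    """scipy (n, p) parameters for a negative binomial with mean ``mu`` and
    size ``alpha`` (variance mu + mu^2/alpha)."""
    return alpha, alpha / (alpha + mu)


@dataclass
class CoverageTable:
    """Per-position depth and read-start tallies for one or more sequences."""

    unique: dict[str, np.ndarray] = field(default_factory=dict)
    repeat: dict[str, np.ndarray] = field(default_factory=dict)
    starts_fwd: dict[str, np.ndarray] = field(default_factory=dict)
    starts_rev: dict[str, np.ndarray] = field(default_factory=dict)

    def add_sequence(self, seq_id: str, length: int) -> None:
        self.unique[seq_id] = np.zeros(length, np.int32)
        self.repeat[seq_id] = np.zeros(length, np.int32)
        self.starts_fwd[seq_id] = np.zeros(length, np.int32)
        self.starts_rev[seq_id] = np.zeros(length, np.int32)

    @property
    def seq_ids(self) -> list[str]:
        return sorted(self.unique)

    def unique_only_mask(self, seq_id: str) -> np.ndarray:
        return self.repeat[seq_id] == 0

    def n_unique_only(self, seq_id: str) -> int:
        return int(self.unique_only_mask(seq_id).sum())

    def zero_start_slots(self, seq_id: str) -> int:
        """(position, strand) slots at unique-only positions with no starts."""
        m = self.unique_only_mask(seq_id)
        return int((self.starts_fwd[seq_id][m] == 0).sum()
                   + (self.starts_rev[seq_id][m] == 0).sum())

    def add_interval(self, seq_id: str, start: int, end: int,
                     unique: bool = True, start_pos: int | None = None,
                     strand: str = "+") -> None:
        """Add one aligned interval (1-based inclusive) to the depth tallies."""
        arr = self.unique[seq_id] if unique else self.repeat[seq_id]
        arr[start - 1 : end] += 1
        if start_pos is not None:
            tgt = self.starts_fwd if strand == "+" else self.starts_rev
            tgt[seq_id][start_pos - 1] += 1


@dataclass
class CoverageModel:
    """Fitted per-sequence coverage model."""

    mu: dict[str, float] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)
    p0: dict[str, float] = field(default_factory=dict)
    threshold: dict[str, int] = field(default_factory=dict)


@dataclass
class MCEvidence:
    """A missing-coverage interval with possibly ambiguous boundaries.

    Boundary ranges are 1-based inclusive; a range wider than one position
    occurs only when the corresponding margin runs through repeat-read
    coverage (flag set), in which case the true deletion endpoint may lie
    anywhere in the range.
    """

    seq_id: str
    left_lo: int
    left_hi: int
    right_lo: int
    right_hi: int
    left_in_repeat: bool = False
    right_in_repeat: bool = False

    @property
    def start(self) -> int:
        return self.left_lo

    @property
    def end(self) -> int:
        return self.right_hi

    @property
    def length(self) -> int:
        return self.right_hi - self.left_lo + 1


# ---------------------------------------------------------------------------
# tabulation


def tabulate_coverage(alignments: dict[str, list], ref) -> CoverageTable:
    """Tabulate depth from per-read alignment lists (best placements only).

    A read with a single best-scoring placement contributes unique depth over
    its interval and one start count at the reference position matching its
    first read base (``ref_start`` on +, ``ref_end`` on −); reads with
    multiple equal-best placements contribute repeat depth at every placement.
    """
    table = CoverageTable()
    for sid in ref.seq_ids:
        table.add_sequence(sid, ref.length(sid))
    for _rid, alns in alignments.items():
        if not alns:
            continue
        best = max(a.score for a in alns)
        top = [a for a in alns if a.score >= best - 1e-6]
        if len(top) == 1:
            a = top[0]
            start_pos = a.ref_start if a.strand == "+" else a.ref_end
            table.add_interval(a.seq_id, a.ref_start, a.ref_end,
                               unique=True, start_pos=start_pos,
                               strand=a.strand)
        else:
            for a in top:
                table.add_interval(a.seq_id, a.ref_start, a.ref_end,
                                   unique=False)
    return table


def tabulate_coverage_batch(batch, reads, gidx) -> CoverageTable:
    """Vectorized tabulation from a :class:`BatchAlignments` result."""
    ref = gidx.ref
    table = CoverageTable()
    for sid in ref.seq_ids:
        table.add_sequence(sid, ref.length(sid))
    if not len(batch):
        return table
    n_reads = len(reads)
    best = np.full(n_reads, -np.inf)
    np.maximum.at(best, batch.read, batch.score)
    is_best = batch.score >= best[batch.read] - 1e-6
    nbest = np.zeros(n_reads, np.int64)
    np.add.at(nbest, batch.read[is_best], 1)
    uniq = is_best & (nbest[batch.read] == 1)
    rep = is_best & (nbest[batch.read] > 1)

    total = gidx.total
    for mask, uflag in ((uniq, True), (rep, False)):
        if not mask.any():
            continue
        g0 = batch.gstart[mask]
        alen = batch.aln_len[mask]
        diff = np.zeros(total + 1, np.int64)
        np.add.at(diff, g0, 1)
        np.add.at(diff, g0 + alen, -1)
        depth = np.cumsum(diff[:-1])
        for i, sid in enumerate(gidx.seq_ids):
            off = gidx.offsets[i]
            L = ref.length(sid)
            tgt = table.unique[sid] if uflag else table.repeat[sid]
            tgt += depth[off : off + L].astype(np.int32)
        if uflag:
            plus = batch.strand[mask] == 1
            sp = g0[plus]
            sm = g0[~plus] + alen[~plus] - 1
            for pos, strand_arr in ((sp, "fwd"), (sm, "rev")):
                cnt = np.zeros(total, np.int64)
                np.add.at(cnt, pos, 1)
                for i, sid in enumerate(gidx.seq_ids):
                    off = gidx.offsets[i]
                    L = ref.length(sid)
                    tgt = (table.starts_fwd if strand_arr == "fwd"
                           else table.starts_rev)[sid]
                    tgt += cnt[off : off + L].astype(np.int32)
    return table


# ---------------------------------------------------------------------------
# model fit


def _censored_nll(logpar, counts, lo, hi):
    mu = np.exp(logpar[0])
    alpha = np.exp(np.clip(logpar[1], -10, 20))
    n, p = nbinom_params(mu, alpha)
    depths = np.arange(len(counts))
    interior = (depths >= lo) & (depths <= hi) & (counts > 0)
    ll = np.sum(counts[interior] * stats.nbinom.logpmf(depths[interior], n, p))
    n_left = counts[depths < lo].sum()
    n_right = counts[depths > hi].sum()
    if n_left:
        ll += n_left * stats.nbinom.logcdf(lo - 1, n, p)
    if n_right:
        ll += n_right * stats.nbinom.logsf(hi, n, p)
    return -ll


def _fit_once(counts: np.ndarray, lo: int, hi: int) -> tuple[float, float, bool]:
    depths = np.arange(len(counts))
    tot = counts.sum()
    mean = float((depths * counts).sum() / tot)
    var = float((counts * (depths - mean) ** 2).sum() / tot)
    alpha0 = mean * mean / (var - mean) if var > mean * 1.0001 else 1e4
    x0 = np.log([max(mean, 1e-3), np.clip(alpha0, 1e-3, 1e6)])
    res = optimize.minimize(_censored_nll, x0, args=(counts, lo, hi),
                            method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-7,
                                     "maxiter": 4000, "maxfev": 4000})
    mu = float(np.exp(res.x[0]))
    alpha = float(np.exp(np.clip(res.x[1], -10, 20)))
    return mu, alpha, bool(res.success)


def fit_censored_negbinom(table: CoverageTable, seq_id: str | None = None,
                          min_positions: int = 1000):
    """Censored maximum-likelihood negative-binomial fit of unique-only depth.

    Depths below 0.5× and above 1.5× the average are treated as censored
    (their CDF/SF mass enters the likelihood) so that deleted regions and
    spurious pileups do not bias the fit.  The censoring bounds are computed
    from the raw mean and recomputed once from the first fit to stabilize
    them when the raw mean itself is biased.  Returns ``(mu, alpha)`` for one
    sequence, or a dict over sequences when ``seq_id`` is None.  Falls back
    to method-of-moments with a warning if the optimizer fails.
    """
    if seq_id is None:
        return {sid: fit_censored_negbinom(table, sid, min_positions)
                for sid in table.seq_ids}
    depths = table.unique[seq_id][table.unique_only_mask(seq_id)]
    if len(depths) < min_positions:
        raise ValueError(
            f"{seq_id}: only {len(depths)} unique-only positions "
            f"(need >= {min_positions})"
        )
    counts = np.bincount(depths)
    mean0 = float(depths.mean())
    mu = mean0
    result = None
    for _ in range(2):  # bounds from raw mean, then once from the fit
        lo = int(np.floor(0.5 * mu))
        hi = int(np.ceil(1.5 * mu))
        mu_f, alpha_f, ok = _fit_once(counts, lo, hi)
        if not ok:
            warnings.warn(f"{seq_id}: censored NB fit did not converge; "
                          "using method-of-moments estimates")
            var = float(depths.var())
            alpha_f = (mean0 ** 2 / (var - mean0)
                       if var > mean0 * 1.0001 else 1e6)
            result = (mean0, float(np.clip(alpha_f, 1e-3, 1e8)))
            break
        mu = mu_f
        result = (mu_f, alpha_f)
    return result


def estimate_no_start_probability(table: CoverageTable,
                                  seq_id: str | None = None):
    """Average chance that no read starts at a (position, strand) slot:
    zero-start slots over twice the number of unique-only positions."""
    if seq_id is None:
        return {sid: estimate_no_start_probability(table, sid)
                for sid in table.seq_ids}
    n = table.n_unique_only(seq_id)
    if n == 0:
        raise ValueError(f"{seq_id}: no unique-only positions "
                         "(reference entirely repetitive)")
    return table.zero_start_slots(seq_id) / (2.0 * n)


def propagation_threshold(mu: float, alpha: float, seq_length: int) -> int:
    """Largest depth c whose NB CDF stays within 0.05 / sqrt(L); >= 0."""
    target = 0.05 / np.sqrt(seq_length)
    n, p = nbinom_params(mu, alpha)
    c = int(stats.nbinom.ppf(target, n, p))
    while c >= 0 and stats.nbinom.cdf(c, n, p) > target:
        c -= 1
    while stats.nbinom.cdf(c + 1, n, p) <= target:
        c += 1
    return max(c, 0)


def fit_coverage_model(table: CoverageTable, ref,
                       min_positions: int = 1000) -> CoverageModel:
    """Fit the full per-sequence model (NB parameters, p0, threshold)."""
    model = CoverageModel()
    for sid in table.seq_ids:
        mu, alpha = fit_censored_negbinom(table, sid, min_positions)
        model.mu[sid] = mu
        model.alpha[sid] = alpha
        model.p0[sid] = estimate_no_start_probability(table, sid)
        model.threshold[sid] = propagation_threshold(mu, alpha,
                                                     ref.length(sid))
    return model


# ---------------------------------------------------------------------------
# missing coverage


def find_missing_coverage(table: CoverageTable, threshold,
                          seq_id: str | None = None) -> list[MCEvidence]:
    """Missing-coverage evidence: zero-total seed regions propagated through
    sub-threshold unique coverage.

    Seeds are positions with zero coverage of both uniquely- and
    multiply-mapped reads.  Seeds extend outward (and join) through positions
    whose unique-only depth is <= the propagation threshold — in particular
    straight through regions covered only by repeat reads.  A margin crossed
    through repeat coverage leaves that boundary as an ambiguous range.
    """
    if seq_id is None:
        out = []
        for sid in table.seq_ids:
            t = threshold[sid] if isinstance(threshold, dict) else threshold
            out.extend(find_missing_coverage(table, t, sid))
        return out
    u = table.unique[seq_id]
    r = table.repeat[seq_id]
    passable = u <= threshold
    seed = (u + r) == 0
    out: list[MCEvidence] = []
    n = len(u)
    i = 0
    while i < n:
        if not passable[i]:
            i += 1
            continue
        j = i
        while j < n and passable[j]:
            j += 1
        # run [i, j); keep only if it contains a zero-total seed
        seeds = np.flatnonzero(seed[i:j])
        if len(seeds):
            seed_lo = i + int(seeds[0])
            seed_hi = i + int(seeds[-1])
            left_rep = bool((r[i:seed_lo] > 0).any())
            right_rep = bool((r[seed_hi + 1 : j] > 0).any())
            left_lo = i + 1
            left_hi = seed_lo + 1 if left_rep else i + 1
            right_hi = j
            right_lo = seed_hi + 1 if right_rep else j
            out.append(
                MCEvidence(
                    seq_id=seq_id,
                    left_lo=left_lo, left_hi=left_hi,
                    right_lo=right_lo, right_hi=right_hi,
                    left_in_repeat=left_rep, right_in_repeat=right_rep,
                )
            )
        i = j
    return out
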