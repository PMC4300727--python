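"""All-alignments local read mapping with staged stringent/relaxed parameters.

The mapper is a hash-seeded, ungapped local aligner that reports *every*
placement of a read scoring at or above the stage threshold, including all
placements inside repeats.  Reads are first mapped in a "stringent" stage
(long sparse seeds, score threshold 0.9 per read base); reads left without
any stringent alignment are retried in a "relaxed" stage (short seeds, low
threshold) so that split-read matches surface as two local alignments on
different seed diagonals.

Scoring: +1 per matching base; a mismatch costs between 1 (base quality <= 2)
and 3 (quality >= 40), linearly interpolated; gaps (only present in
externally supplied SAM alignments) cost 2 to open plus 3 per base.

Internally all work is done on numpy code arrays (A=0 C=1 G=2 T=3 N=4) so
that mapping a few million short reads stays within minutes on one core.
:class:`ReadAlignment` objects are materialized only where the pipeline needs
per-read structure (split-read candidates, SAM ingest, small test inputs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .refio import ReferenceSet, revcomp

__all__ = [
    "MapperParams",
    "ReadAlignment",
    "ReadSet",
    "GenomeIndex",
    "stage_mapping_params",
    "mismatch_penalty",
    "score_alignment",
    "map_reads_all",
    "map_reads_batch",
    "read_alignments_sam",
]

_CODE = np.full(256, 6, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMP_LUT = np.array([3, 2, 1, 0, 4, 5, 6], dtype=np.uint8)
_PAD = 6  # padding beyond read length / genome bounds
_NEG = -1000.0  # score for aligning onto N or past a contig end


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class MapperParams:
    """Seeding and score-threshold parameters for one mapping stage."""

    seed_length: int
    seed_spacing: int
    min_score: float
    stage: str  # "stringent" | "relaxed"

    def __post_init__(self) -> None:
        if not (9 <= self.seed_length <= 31):
            raise ValueError(f"seed_length {self.seed_length} outside [9, 31]")
        if self.seed_spacing < 1 or self.min_score <= 0:
            raise ValueError("seed_spacing >= 1 and min_score > 0 required")

    def score_threshold(self, read_length: int) -> float:
        """Stage score threshold for a read of the given length."""
        if self.stage == "stringent":
            return 0.9 * read_length
        return 6.0 + 0.2 * read_length


def stage_mapping_params(mean_read_length: float, max_read_length: int,
                         stage: str) -> MapperParams:
    """Derive seeding parameters for a mapping stage.

    Stringent: seed length 0.5·L̄ clamped to [9, 31], score threshold 0.9·L.
    Relaxed: seed length 5 + 0.1·L̄ clamped to [9, 31], threshold 6 + 0.2·L.
    Both stages space seeds every floor(1 + 0.25·sqrt(L)) read positions.
    """
    if mean_read_length < 9:
        raise ValueError("mean read length must be >= 9")
    if stage == "stringent":
        seed = int(np.clip(int(0.5 * mean_read_length), 9, 31))
        min_score = 0.9 * mean_read_length
    elif stage == "relaxed":
        seed = int(np.clip(int(5 + 0.1 * mean_read_length), 9, 31))
        min_score = 6 + 0.2 * mean_read_length
    else:
        raise ValueError(f"unknown stage {stage!r}")
    spacing = int(1 + 0.25 * np.sqrt(mean_read_length))
    return MapperParams(seed_length=seed, seed_spacing=spacing,
                        min_score=min_score, stage=stage)


def mismatch_penalty(quality) -> np.ndarray | float:
    """Mismatch cost: 1 at Q<=2 rising linearly to 3 at Q>=40."""
    q = np.clip(np.asarray(quality, dtype=np.float64), 2.0, 40.0)
    pen = 1.0 + 2.0 * (q - 2.0) / 38.0
    return float(pen) if pen.ndim == 0 else pen


def score_alignment(read_bases: str, base_qualities, edit_operations) -> float:
    """Score an alignment from its edit operations.

    ``edit_operations`` is a sequence of ``(op, length)`` with op one of
    ``"="`` (match run), ``"X"`` (mismatch run), ``"I"`` (read insertion),
    ``"D"`` (reference deletion).  ``base_qualities`` is a scalar phred
    quality or per-base array aligned with ``read_bases``; mismatches are
    down-weighted for low-quality calls.  The read position at which the
    alignment starts does not matter for the score, but mismatch penalties
    are taken from the consumed read bases, so operations must consume
    exactly the aligned portion of ``read_bases``.
    """
    quals = np.asarray(base_qualities, dtype=np.float64)
    if quals.ndim == 0:
        quals = np.full(len(read_bases), float(quals))
    score = 0.0
    pos = 0
    for op, length in edit_operations:
        if op == "=":
            score += length
            pos += length
        elif op == "X":
            score -= float(np.sum(mismatch_penalty(quals[pos : pos + length])))
            pos += length
        elif op == "I":
            score -= 2.0 + 3.0 * length
            pos += length
        elif op == "D":
            score -= 2.0 + 3.0 * length
        else:
            raise ValueError(f"unknown edit operation {op!r}")
    return score


# ---------------------------------------------------------------------------
# alignments


@dataclass
class ReadAlignment:
    """A local alignment of a read to the reference.

    Read coordinates are 1-based on the read *as sequenced*; reference
    coordinates are 1-based with ``ref_start <= ref_end``.  For minus-strand
    alignments the first aligned read base corresponds to ``ref_end``.
    ``edit_ops`` runs along the read as sequenced.
    """

    read_id: str
    read_start: int
    read_end: int
    seq_id: str
    ref_start: int
    ref_end: int
    strand: str
    score: float
    edit_ops: tuple = ()
    read_length: int = 0

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start + 1

    def ref_pos_of_read_pos(self, read_pos: int) -> int:
        """Reference coordinate matching an aligned read position (ungapped)."""
        if not (self.read_start <= read_pos <= self.read_end):
            raise ValueError("read position outside aligned interval")
        if self.strand == "+":
            return self.ref_start + (read_pos - self.read_start)
        return self.ref_end - (read_pos - self.read_start)

    def has_indel(self) -> bool:
        return any(op in "ID" for op, _ in self.edit_ops)


class ReadSet:
    """Reads held as a padded code matrix for batch mapping.

    ``codes`` is (n_reads, max_len) uint8 with pad value 6 beyond each read's
    length; ``quality`` is either a scalar phred value applying to every base
    or an (n_reads, max_len) uint8 array.
    """

    def __init__(self, codes: np.ndarray, lengths: np.ndarray,
                 ids: list[str] | None = None, quality=40):
        self.codes = codes
        self.lengths = lengths.astype(np.int64)
        self.ids = ids
        self.quality = quality
        self._rc_codes: np.ndarray | None = None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_sequences(cls, seqs, ids=None, quality=40) -> "ReadSet":
        seqs = list(seqs)
        n = len(seqs)
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        lmax = int(lengths.max()) if n else 0
        codes = np.full((n, lmax), _PAD, dtype=np.uint8)
        for i, s in enumerate(seqs):
            codes[i, : len(s)] = _CODE[np.frombuffer(s.upper().encode(), np.uint8)]
        return cls(codes, lengths, ids=list(ids) if ids is not None else None,
                   quality=quality)

    @classmethod
    def from_fastq(cls, path: str) -> "ReadSet":
        import pysam

        ids, seqs, quals = [], [], []
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                ids.append(rec.name)
                seqs.append(rec.sequence)
                quals.append(rec.get_quality_array())
        if not seqs:
            warnings.warn(f"{path}: no reads found")
            return cls(np.zeros((0, 0), np.uint8), np.zeros(0, np.int64), ids=[])
        rs = cls.from_sequences(seqs, ids=ids)
        lmax = rs.codes.shape[1]
        qmat = np.zeros((len(seqs), lmax), dtype=np.uint8)
        for i, q in enumerate(quals):
            qmat[i, : len(q)] = q
        rs.quality = qmat
        return rs

    # -- access ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.lengths)

    @property
    def max_length(self) -> int:
        return self.codes.shape[1]

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean()) if len(self) else 0.0

    def read_id(self, i: int) -> str:
        return self.ids[i] if self.ids is not None else f"read{i}"

    _DECODE = np.frombuffer(b"ACGTNNN", dtype=np.uint8)

    def sequence(self, i: int) -> str:
        return bytes(self._DECODE[self.codes[i, : self.lengths[i]]]).decode()

    def qual_row(self, i: int) -> np.ndarray:
        if np.ndim(self.quality) == 0:
            return np.full(int(self.lengths[i]), int(self.quality))
        return np.asarray(self.quality[i, : self.lengths[i]])

    def rc_codes(self) -> np.ndarray:
        """Per-read reverse-complement codes, padded like ``codes``."""
        if self._rc_codes is None:
            n, lmax = self.codes.shape
            j = self.lengths[:, None] - 1 - np.arange(lmax)[None, :]
            valid = j >= 0
            rc = np.full((n, lmax), _PAD, dtype=np.uint8)
            rows = np.broadcast_to(np.arange(n)[:, None], j.shape)
            rc[valid] = _COMP_LUT[self.codes[rows[valid], j[valid]]]
            self._rc_codes = rc
        return self._rc_codes

    def rc_quality(self):
        if np.ndim(self.quality) == 0:
            return self.quality
        n, lmax = self.codes.shape
        j = np.clip(self.lengths[:, None] - 1 - np.arange(lmax)[None, :], 0, None)
        return np.take_along_axis(np.asarray(self.quality), j, axis=1)

    def reverse_complemented(self) -> "ReadSet":
        rs = ReadSet(self.rc_codes().copy(), self.lengths.copy(),
                     ids=self.ids, quality=self.rc_quality())
        return rs


# ---------------------------------------------------------------------------
# genome index


def _kmer_hashes(codes: np.ndarray, k: int):
    """Rolling 2-bit hashes of all k-windows; invalid where a window holds N."""
    n = codes.shape[-1] - k + 1
    if n <= 0:
        shape = codes.shape[:-1] + (0,)
        return np.zeros(shape, np.uint64), np.zeros(shape, bool)
    h = np.zeros(codes.shape[:-1] + (n,), dtype=np.uint64)
    bad = np.zeros(h.shape, dtype=bool)
    for j in range(k):
        c = codes[..., j : j + n]
        h = (h << np.uint64(2)) | (c.astype(np.uint64) & np.uint64(3))
        bad |= c > 3
    return h, bad


class GenomeIndex:
    """Concatenated, padded code array over all reference sequences plus
    sorted k-mer seed indexes (cached per seed length)."""

    def __init__(self, ref: ReferenceSet, pad: int = 512):
        self.ref = ref
        self.pad = pad
        self.seq_ids = ref.seq_ids
        parts, offsets = [], []
        pos = 0
        for sid in self.seq_ids:
            offsets.append(pos)
            s = ref.sequence(sid)
            parts.append(_CODE[np.frombuffer(s.encode(), np.uint8)])
            parts.append(np.full(1, _PAD, np.uint8))  # contig separator
            pos += len(s) + 1
        self.offsets = np.array(offsets, dtype=np.int64)
        self.total = pos
        body = (np.concatenate(parts) if parts
                else np.zeros(0, np.uint8))
        self.padded = np.concatenate(
            [np.full(pad, _PAD, np.uint8), body, np.full(2 * pad, _PAD, np.uint8)]
        )
        self._seed_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def codes_window(self, gstart: np.ndarray, width: int) -> np.ndarray:
        """Gather (len(gstart), width) code windows; out-of-range = pad."""
        idx = gstart[:, None] + np.arange(width)[None, :] + self.pad
        return self.padded[np.clip(idx, 0, len(self.padded) - 1)]

    def seed_index(self, k: int):
        if k not in self._seed_cache:
            body = self.padded[self.pad : self.pad + self.total]
            h, bad = _kmer_hashes(body, k)
            valid = ~bad
            pos = np.flatnonzero(valid).astype(np.int64)
            hv = h[valid]
            order = np.argsort(hv, kind="stable")
            self._seed_cache[k] = (hv[order], pos[order])
        return self._seed_cache[k]

    def locate(self, gpos: int) -> tuple[str, int]:
        """Concatenated position -> (seq_id, 0-based local position)."""
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.seq_ids[i], int(gpos - self.offsets[i])

    def locate_batch(self, gpos: np.ndarray):
        i = np.searchsorted(self.offsets, gpos, side="right") - 1
        return i, gpos - self.offsets[i]

    def gpos(self, seq_id: str, local0: int) -> int:
        return int(self.offsets[self.seq_ids.index(seq_id)]) + local0


# ---------------------------------------------------------------------------
# batch mapping


class BatchAlignments:
    """Struct-of-arrays alignment results from one or two mapping stages.

    Fields (parallel arrays): ``read``, ``strand`` (+1/-1), ``gstart``
    (concatenated 0-based reference start), ``qstart``/``qend`` (0-based
    inclusive read interval *as sequenced*), ``score``, ``stage``
    (0 stringent, 1 relaxed).
    """

    FIELDS = ("read", "strand", "gstart", "qstart", "qend", "score", "stage")

    def __init__(self, read, strand, gstart, qstart, qend, score, stage):
        self.read = read
        self.strand = strand
        self.gstart = gstart
        self.qstart = qstart
        self.qend = qend
        self.score = score
        self.stage = stage

    def __len__(self) -> int:
        return len(self.read)

    @classmethod
    def empty(cls) -> "BatchAlignments":
        z = np.zeros(0, np.int64)
        return cls(z, z.copy(), z.copy(), z.copy(), z.copy(),
                   np.zeros(0, np.float64), z.copy())

    @classmethod
    def concat(cls, parts) -> "BatchAlignments":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(*[np.concatenate([getattr(p, f) for p in parts])
                     for f in cls.FIELDS])

    @property
    def aln_len(self) -> np.ndarray:
        return self.qend - self.qstart + 1

    def select(self, mask) -> "BatchAlignments":
        return BatchAlignments(*[getattr(self, f)[mask] for f in self.FIELDS])


def _best_local_interval(scores: np.ndarray):
    """Per-row maximum-sum contiguous interval of a score matrix.

    Returns (best, j1, j2): ``best`` the maximal interval score and
    ``[j1, j2)`` the leftmost interval attaining it.
    """
    m, width = scores.shape
    ps = np.zeros((m, width + 1), dtype=np.float64)
    np.cumsum(scores, axis=1, out=ps[:, 1:])
    runmin = np.minimum.accumulate(ps[:, :-1], axis=1)
    gains = ps[:, 1:] - runmin
    end = np.argmax(gains, axis=1)  # first maximal end
    best = gains[np.arange(m), end]
    j2 = end + 1
    minval = runmin[np.arange(m), end]
    # leftmost prefix index attaining the running min before j2
    hit = (ps[:, :-1] == minval[:, None]) & (np.arange(width)[None, :] <= end[:, None])
    j1 = np.argmax(hit, axis=1)
    return best, j1, j2


def _map_one_strand(reads: ReadSet, query: np.ndarray, qual,
                    gidx: GenomeIndex, params: MapperParams,
                    subset: np.ndarray, max_seed_hits: int = 64,
                    chunk: int = 400_000):
    """Seed+extend one query orientation for reads[subset].

    ``query`` is the full (n, lmax) code matrix in query orientation (forward
    reads or their reverse complements); returns compact candidate results as
    (read_index, diag, qstart, qend, score) arrays with coordinates in query
    orientation.
    """
    k = params.seed_length
    lmax = reads.max_length
    if lmax < k or len(subset) == 0:
        return [np.zeros(0, np.int64)] * 4 + [np.zeros(0, np.float64)]
    sorted_h, pos_sorted = gidx.seed_index(k)
    qcodes = query[subset]
    lengths = reads.lengths[subset]

    cand_read, cand_diag = [], []
    offsets = range(0, lmax - k + 1, params.seed_spacing)
    for off in offsets:
        win = qcodes[:, off : off + k]
        ok = lengths >= off + k
        h = np.zeros(len(qcodes), dtype=np.uint64)
        bad = np.zeros(len(qcodes), dtype=bool)
        for j in range(k):
            c = win[:, j]
            h = (h << np.uint64(2)) | (c.astype(np.uint64) & np.uint64(3))
            bad |= c > 3
        ok &= ~bad
        qi = np.flatnonzero(ok)
        if not len(qi):
            continue
        hq = h[qi]
        lo = np.searchsorted(sorted_h, hq, side="left")
        hi = np.searchsorted(sorted_h, hq, side="right")
        counts = np.minimum(hi - lo, max_seed_hits)
        nz = counts > 0
        if not nz.any():
            continue
        qi, lo, counts = qi[nz], lo[nz], counts[nz]
        total = int(counts.sum())
        rep_q = np.repeat(qi, counts)
        base = np.repeat(np.cumsum(counts) - counts, counts)
        gpos = pos_sorted[np.repeat(lo, counts) + (np.arange(total) - base)]
        cand_read.append(rep_q)
        cand_diag.append(gpos - off)
    if not cand_read:
        return [np.zeros(0, np.int64)] * 4 + [np.zeros(0, np.float64)]
    cr = np.concatenate(cand_read)
    cd = np.concatenate(cand_diag)
    # dedupe (read, diag)
    key = cr * np.int64(gidx.total + 2 * lmax + 2) + (cd + lmax)
    _, keep = np.unique(key, return_index=True)
    cr, cd = cr[keep], cd[keep]

    out = [[], [], [], [], []]
    pen_scalar = (float(mismatch_penalty(qual)) if np.ndim(qual) == 0 else None)
    for s in range(0, len(cr), chunk):
        r = cr[s : s + chunk]
        d = cd[s : s + chunk]
        win = gidx.codes_window(d, lmax)
        q = qcodes[r]
        match = win == q
        valid = q <= 3  # real A/C/G/T read bases
        bad_ref = (win > 4) & valid  # contig separators / out-of-bounds
        mism = valid & ~match & ~bad_ref
        sc = np.zeros(win.shape, dtype=np.float64)
        sc[match & valid] = 1.0
        if pen_scalar is not None:
            sc[mism] = -pen_scalar
        else:
            pen = mismatch_penalty(np.asarray(qual)[subset][r])
            sc[mism] = -pen[mism]
        sc[bad_ref] = _NEG
        best, j1, j2 = _best_local_interval(sc)
        rlen = lengths[r]
        if params.stage == "stringent":
            thr = 0.9 * rlen
        else:
            thr = 6.0 + 0.2 * rlen
        ok = best >= thr - 1e-9
        if ok.any():
            out[0].append(r[ok])
            out[1].append(d[ok])
            out[2].append(j1[ok])
            out[3].append(j2[ok] - 1)
            out[4].append(best[ok])
    if not out[0]:
        return [np.zeros(0, np.int64)] * 4 + [np.zeros(0, np.float64)]
    return [np.concatenate(x) for x in out]


def _stage_map(reads: ReadSet, gidx: GenomeIndex, params: MapperParams,
               subset: np.ndarray, stage_code: int) -> BatchAlignments:
    parts = []
    for strand, query, qual in (
        (+1, reads.codes, reads.quality),
        (-1, reads.rc_codes(), reads.rc_quality()),
    ):
        r, d, j1, j2, sc = _map_one_strand(reads, query, qual, gidx, params, subset)
        if not len(r):
            continue
        ridx = subset[r]
        rlen = reads.lengths[ridx]
        if strand == +1:
            qstart, qend = j1, j2
        else:  # flip query-orientation coords to as-sequenced
            qstart, qend = rlen - 1 - j2, rlen - 1 - j1
        parts.append(BatchAlignments(
            read=ridx,
            strand=np.full(len(r), strand, np.int64),
            gstart=d + j1,
            qstart=qstart.astype(np.int64),
            qend=qend.astype(np.int64),
            score=sc,
            stage=np.full(len(r), stage_code, np.int64),
        ))
    return BatchAlignments.concat(parts)


def map_reads_batch(reads: ReadSet, ref_or_index,
                    stringent: MapperParams | None = None,
                    relaxed: MapperParams | None = None) -> BatchAlignments:
    """Two-stage batch mapping: stringent first, relaxed for unmapped reads."""
    gidx = (ref_or_index if isinstance(ref_or_index, GenomeIndex)
            else GenomeIndex(ref_or_index, pad=max(512, reads.max_length + 1)))
    if len(reads) == 0:
        warnings.warn("empty read set")
        return BatchAlignments.empty()
    lbar = reads.mean_length
    lmax = reads.max_length
    if stringent is None:
        stringent = stage_mapping_params(lbar, lmax, "stringent")
    res1 = _stage_map(reads, gidx, stringent, np.arange(len(reads)), 0)
    mapped = np.zeros(len(reads), dtype=bool)
    if len(res1):
        mapped[res1.read] = True
    unmapped = np.flatnonzero(~mapped)
    if relaxed is None:
        relaxed = stage_mapping_params(lbar, lmax, "relaxed")
    res2 = (_stage_map(reads, gidx, relaxed, unmapped, 1)
            if len(unmapped) else BatchAlignments.empty())
    return BatchAlignments.concat([res1, res2])


# ---------------------------------------------------------------------------
# object materialization and the per-read public surface


def _edit_ops_for(reads: ReadSet, gidx: GenomeIndex, read: int, strand: int,
                  gstart: int, qstart: int, qend: int):
    """Match/mismatch runs for an ungapped batch alignment (read order)."""
    length = qend - qstart + 1
    if strand == +1:
        q = reads.codes[read, qstart : qend + 1]
    else:
        rlen = int(reads.lengths[read])
        q = reads.rc_codes()[read, rlen - 1 - qend : rlen - qstart]
    w = gidx.padded[gidx.pad + gstart : gidx.pad + gstart + length]
    match = (q == w) & (q <= 3) & (w <= 3)
    if strand == -1:
        match = match[::-1]
    ops = []
    i = 0
    while i < length:
        j = i
        while j < length and match[j] == match[i]:
            j += 1
        ops.append(("=" if match[i] else "X", j - i))
        i = j
    return tuple(ops)


def materialize(reads: ReadSet, gidx: GenomeIndex, batch: BatchAlignments,
                indices=None) -> dict[int, list[ReadAlignment]]:
    """Convert (a subset of) batch alignments to ReadAlignment objects,
    keyed by read index.  Scores are recomputed with :func:`score_alignment`
    so the object invariant holds exactly."""
    if indices is None:
        indices = np.arange(len(batch))
    out: dict[int, list[ReadAlignment]] = {}
    for i in indices:
        read = int(batch.read[i])
        strand = int(batch.strand[i])
        gstart = int(batch.gstart[i])
        qstart = int(batch.qstart[i])
        qend = int(batch.qend[i])
        length = qend - qstart + 1
        sid, local = gidx.locate(gstart)
        ops = _edit_ops_for(reads, gidx, read, strand, gstart, qstart, qend)
        quals = reads.qual_row(read)[qstart : qend + 1]
        seq = reads.sequence(read)[qstart : qend + 1]
        score = score_alignment(seq, quals, ops)
        aln = ReadAlignment(
            read_id=reads.read_id(read),
            read_start=qstart + 1,
            read_end=qend + 1,
            seq_id=sid,
            ref_start=local + 1,
            ref_end=local + length,
            strand="+" if strand == 1 else "-",
            score=score,
            edit_ops=ops,
            read_length=int(reads.lengths[read]),
        )
        out.setdefault(read, []).append(aln)
    return out


def map_reads_all(reads, ref: ReferenceSet,
                  params: MapperParams | None = None) -> dict[str, list[ReadAlignment]]:
    """Map reads (ReadSet, FASTQ path, or (id, seq) pairs) against a reference.

    Runs the stringent stage and retries stringently-unmapped reads with
    relaxed parameters; returns every valid alignment per read id.
    """
    if isinstance(reads, ReadSet):
        rs = reads
    elif isinstance(reads, str):
        rs = ReadSet.from_fastq(reads)
    else:
        items = list(reads)
        if items and isinstance(items[0], str):
            rs = ReadSet.from_sequences(items)
        else:
            rs = ReadSet.from_sequences([s for _, s in items],
                                        ids=[i for i, _ in items])
    gidx = GenomeIndex(ref, pad=max(512, rs.max_length + 1))
    if params is not None:
        batch = _stage_map(rs, gidx, params, np.arange(len(rs)),
                           0 if params.stage == "stringent" else 1)
    else:
        batch = map_reads_batch(rs, gidx)
    objs = materialize(rs, gidx, batch)
    return {rs.read_id(i): alns for i, alns in sorted(objs.items())}


# ---------------------------------------------------------------------------
# SAM ingest


def read_alignments_sam(path: str, ref: ReferenceSet) -> dict[str, list[ReadAlignment]]:
    """Load externally produced alignments (SAM/BAM, all alignments kept).

    CIGAR and strand are converted to read-as-sequenced coordinates and the
    score is recomputed with :func:`score_alignment`, so downstream junction
    finding behaves identically to the built-in mapper.  Hard-clipped records
    are rejected because they destroy read coordinates.
    """
    import pysam

    out: dict[str, list[ReadAlignment]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            if any(op == 5 for op, _ in rec.cigartuples):
                raise ValueError(
                    f"{rec.query_name}: hard-clipped alignment; re-run the "
                    "mapper with soft-clipping so read coordinates survive"
                )
            if rec.reference_name not in ref:
                raise ValueError(f"unknown reference {rec.reference_name!r}")
            qseq = rec.query_sequence
            quals = (np.array(rec.query_qualities, dtype=np.uint8)
                     if rec.query_qualities is not None
                     else np.full(len(qseq), 40, np.uint8))
            refseq = ref.sequence(rec.reference_name)
            # walk CIGAR in SEQ orientation
            ops = []
            qpos = 0
            rpos = rec.reference_start  # 0-based
            qstart = None
            for op, length in rec.cigartuples:
                if op == 4:  # soft clip
                    qpos += length
                elif op in (0, 7, 8):  # M/=/X -> compare to reference
                    if qstart is None:
                        qstart = qpos
                    for t in range(length):
                        m = (qseq[qpos + t].upper() == refseq[rpos + t]
                             and refseq[rpos + t] != "N")
                        if ops and ops[-1][0] == ("=" if m else "X"):
                            ops[-1][1] += 1
                        else:
                            ops.append(["=" if m else "X", 1])
                    qpos += length
                    rpos += length
                elif op == 1:  # I
                    if qstart is None:
                        qstart = qpos
                    ops.append(["I", length])
                    qpos += length
                elif op == 2:  # D
                    ops.append(["D", length])
                    rpos += length
                elif op == 3:  # N (skip) treated as deletion
                    ops.append(["D", length])
                    rpos += length
            qend = qpos - 1
            # trailing soft clip already handled (qpos only advanced inside)
            aligned_len = qend - qstart + 1
            seq_aln = qseq[qstart : qend + 1].upper()
            qual_aln = quals[qstart : qend + 1]
            if rec.is_reverse:
                # SEQ is the reverse complement; flip to as-sequenced
                rl = len(qseq)
                read_start = rl - 1 - qend
                read_end = rl - 1 - qstart
                ops = [tuple(o) for o in reversed(ops)]
                seq_aln = revcomp(seq_aln)
                qual_aln = qual_aln[::-1]
            else:
                read_start, read_end = qstart, qend
                ops = [tuple(o) for o in ops]
            score = score_alignment(seq_aln, qual_aln, ops)
            aln = ReadAlignment(
                read_id=rec.query_name,
                read_start=read_start + 1,
                read_end=read_end + 1,
                seq_id=rec.reference_name,
                ref_start=rec.reference_start + 1,
                ref_end=rpos,
                strand="-" if rec.is_reverse else "+",
                score=score,
                edit_ops=tuple(ops),
                read_length=len(qseq),
            )
            out.setdefault(rec.query_name, []).append(aln)
    return out
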