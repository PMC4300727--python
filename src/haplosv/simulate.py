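"""Simulation of mutated genomes and short single-end reads.

The generator mirrors the benchmark protocol the pipeline is tested
against: a (synthetic or supplied) reference genome carrying annotated
insertion-sequence (IS) element copies is mutated with one class of
structural variant per genome — unique-junction deletions of 400–1000 bp,
new IS insertions duplicating 1–10 target-site bases, or IS-mediated
deletions extending from one margin of an existing element copy — with
every affected site at least 1,000 bases from every other site and from
every exact sequence repeat of >= 36 bases.  Reads have fixed lengths or
Gaussian-variable lengths (SD 10% of the mean, truncated at 18), start
uniformly on both strands, and carry i.i.d. substitution errors.

The truth Genome Diff records every event (and the seed), and the mutated
genome is produced by applying it, so ``apply(truth) == simulated genome``
holds by construction and the whole pipeline can be exercised end to end
with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gd import GenomeDiff, Mutation, apply_mutations
from .readmap import ReadSet, _CODE
from .refio import Feature, ReferenceSet, enumerate_exact_repeats

__all__ = [
    "SimPlan",
    "ReadSimModel",
    "random_genome",
    "simulate_sv_genome",
    "simulate_reads",
    "write_fastq",
]

MUTATION_CLASSES = ("unique-deletion", "is-insertion", "is-mediated-deletion")
_DECODE = np.frombuffer(b"ACGTNNN", dtype=np.uint8)


@dataclass
class SimPlan:
    mutation_class: str
    count: int
    deletion_size: tuple[int, int] = (400, 1000)
    tsd_range: tuple[int, int] = (1, 10)
    min_spacing: int = 1000
    repeat_min_len: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")
        if self.count <= 0 or self.min_spacing < 0:
            raise ValueError("count and spacing must be positive")


@dataclass
class ReadSimModel:
    style: str = "fixed"  # fixed | variable
    read_length: int = 50  # exact length, or the mean for variable style
    coverage: float = 40.0
    error_rate: float = 0.001
    seed: int = 0
    length_sd_fraction: float = 0.10
    min_length: int = 18

    def __post_init__(self) -> None:
        if self.style not in ("fixed", "variable"):
            raise ValueError(f"unknown read style {self.style!r}")
        if self.read_length < self.min_length or self.coverage <= 0:
            raise ValueError("read length >= 18 and coverage > 0 required")


def random_genome(length: int = 1_000_000, n_elements: int = 10,
                  element_length: int = 1443, gc: float = 0.5,
                  seed: int = 0, seq_id: str = "chr1",
                  family: str = "ISsim1") -> ReferenceSet:
    """Seeded random genome with identical planted IS-like element copies.

    The element copies are annotated as mobile_element features sharing one
    family name; they are the only large repeats in the sequence, standing
    in for the annotated IS complement of a real bacterial chromosome.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    element = rng.choice(4, size=element_length, p=p).astype(np.uint8)
    ref = ReferenceSet()
    positions = []
    margin = 2000
    tries = 0
    while len(positions) < n_elements:
        tries += 1
        if tries > 10000:
            raise ValueError("could not place elements; genome too small")
        pos = int(rng.integers(margin, length - element_length - margin))
        if all(abs(pos - q) > element_length + 2000 for q in positions):
            positions.append(pos)
    for pos in positions:
        codes[pos : pos + element_length] = element
    seq = bytes(_DECODE[codes]).decode()
    ref.add_sequence(seq_id, seq)
    for pos in sorted(positions):
        ref.add_feature(Feature(seq_id, pos + 1, pos + element_length, "+",
                                "mobile_element", family))
    return ref


# ---------------------------------------------------------------------------
# mutated genomes


def _interval_clear(lo: int, hi: int, blocked: list[tuple[int, int]],
                    spacing: int) -> bool:
    for b_lo, b_hi in blocked:
        if lo - spacing <= b_hi and hi + spacing >= b_lo:
            return False
    return True


def simulate_sv_genome(ref: ReferenceSet, plan: SimPlan):
    """Plant one class of structural variant; returns (mutant, truth GD).

    Event sites are sampled uniformly, rejected unless at least
    ``min_spacing`` bases from every exact repeat >= ``repeat_min_len`` and
    from every previously placed event.  IS insertions copy a randomly
    chosen annotated element; IS-mediated deletions extend from the left or
    right margin of a randomly chosen copy (equal probability), and a copy
    is never reused for a second deletion.
    """
    rng = np.random.default_rng(plan.seed)
    sid = ref.seq_ids[0]
    L = ref.length(sid)
    repeats = enumerate_exact_repeats(ref, plan.repeat_min_len)
    blocked = [(r.start, r.end) for r in repeats if r.seq_id == sid]
    elements = [f for f in ref.features
                if f.seq_id == sid and f.kind == "mobile_element"]

    truth = GenomeDiff({"seed": plan.seed,
                        "mutation_class": plan.mutation_class})
    placed: list[tuple[int, int]] = []
    used_elements: set[int] = set()
    max_tries = 200 * plan.count
    tries = 0
    n_done = 0
    while n_done < plan.count:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {plan.count} events under spacing "
                f"constraints; achieved {n_done}")
        if plan.mutation_class == "unique-deletion":
            size = int(rng.integers(plan.deletion_size[0],
                                    plan.deletion_size[1] + 1))
            pos = int(rng.integers(plan.min_spacing + 1,
                                   L - size - plan.min_spacing))
            lo, hi = pos, pos + size - 1
            if not _interval_clear(lo, hi, blocked + placed,
                                   plan.min_spacing):
                continue
            truth.add_mutation(Mutation("DEL", "", [], sid, pos, size=size))
        elif plan.mutation_class == "is-insertion":
            tsd = int(rng.integers(plan.tsd_range[0], plan.tsd_range[1] + 1))
            pos = int(rng.integers(plan.min_spacing + 1,
                                   L - tsd - plan.min_spacing))
            lo, hi = pos, pos + tsd - 1
            if not _interval_clear(lo, hi, blocked + placed,
                                   plan.min_spacing):
                continue
            elem = elements[int(rng.integers(len(elements)))]
            strand = int(rng.choice([1, -1]))
            truth.add_mutation(Mutation(
                "MOB", "", [], sid, pos, repeat_name=elem.family_name,
                strand=strand, duplication_size=tsd))
        else:  # is-mediated-deletion
            if len(used_elements) >= len(elements):
                raise ValueError("all element copies already mediate a "
                                 "deletion; cannot place more events")
            ei = int(rng.integers(len(elements)))
            if ei in used_elements:
                continue
            elem = elements[ei]
            size = int(rng.integers(plan.deletion_size[0],
                                    plan.deletion_size[1] + 1))
            right = bool(rng.integers(2))
            if right:
                lo, hi = elem.end + 1, elem.end + size
            else:
                lo, hi = elem.start - size, elem.start - 1
            if lo < 1 or hi > L:
                continue
            # the deleted region must stay clear of other repeats/events,
            # excluding the mediating element itself
            other_blocked = [b for b in blocked
                             if not (b[0] <= elem.end and b[1] >= elem.start)]
            if not _interval_clear(lo, hi, other_blocked + placed,
                                   plan.min_spacing):
                continue
            used_elements.add(ei)
            truth.add_mutation(Mutation(
                "DEL", "", [], sid, lo, size=size,
                extras={"mediated": elem.family_name}))
        placed.append((lo, hi))
        n_done += 1
    truth.mutations.sort(key=lambda m: m.position)
    mutant = apply_mutations(truth, ref)
    return mutant, truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(genome: ReferenceSet, model: ReadSimModel) -> ReadSet:
    """Uniform-start single-end reads with i.i.d. substitution errors.

    The expected read count is coverage * genome_length / mean_length; base
    qualities reflect the error rate on the phred scale.  Returns an
    in-memory :class:`ReadSet`; use :func:`write_fastq` to serialize.
    """
    rng = np.random.default_rng(model.seed)
    sid = genome.seq_ids[0]
    if len(genome.seq_ids) > 1:
        lengths = {s: genome.length(s) for s in genome.seq_ids}
        total = sum(lengths.values())
    else:
        total = genome.length(sid)
    reads_parts = []
    lens_parts = []
    for s in genome.seq_ids:
        Ls = genome.length(s)
        n = int(round(model.coverage * Ls / model.read_length))
        if n == 0:
            continue
        codes = _CODE[np.frombuffer(genome.sequence(s).encode(), np.uint8)]
        if model.style == "fixed":
            rl = np.full(n, model.read_length, dtype=np.int64)
        else:
            rl = rng.normal(model.read_length,
                            model.length_sd_fraction * model.read_length,
                            size=n)
            rl = np.maximum(np.rint(rl).astype(np.int64), model.min_length)
            rl = np.minimum(rl, Ls)
        starts = (rng.random(n) * (Ls - rl + 1)).astype(np.int64)
        lmax = int(rl.max())
        idx = starts[:, None] + np.arange(lmax)[None, :]
        mat = codes[np.minimum(idx, Ls - 1)]
        pad_mask = np.arange(lmax)[None, :] >= rl[:, None]
        # substitution errors
        if model.error_rate > 0:
            err = (rng.random(mat.shape) < model.error_rate) & ~pad_mask
            err &= mat <= 3
            shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat = np.where(err, (mat + shift) % 4, mat)
        # reverse complement half the reads
        flip = rng.random(n) < 0.5
        sub = mat[flip]
        rl_f = rl[flip]
        rev_idx = rl_f[:, None] - 1 - np.arange(lmax)[None, :]
        rows = np.broadcast_to(np.arange(len(sub))[:, None], rev_idx.shape)
        rc = np.where(rev_idx >= 0,
                      np.where(sub[rows, np.clip(rev_idx, 0, None)] <= 3,
                               3 - sub[rows, np.clip(rev_idx, 0, None)],
                               sub[rows, np.clip(rev_idx, 0, None)]),
                      6)
        mat[flip] = rc.astype(np.uint8)
        mat[pad_mask] = 6
        reads_parts.append(mat)
        lens_parts.append(rl)
    if not reads_parts:
        return ReadSet(np.zeros((0, 0), np.uint8), np.zeros(0, np.int64))
    lmax = max(m.shape[1] for m in reads_parts)
    padded = []
    for m in reads_parts:
        if m.shape[1] < lmax:
            pad = np.full((m.shape[0], lmax - m.shape[1]), 6, np.uint8)
            m = np.hstack([m, pad])
        padded.append(m)
    codes = np.vstack(padded)
    lengths = np.concatenate(lens_parts)
    q = 40 if model.error_rate <= 0 else int(
        np.clip(round(-10 * np.log10(model.error_rate)), 2, 40))
    return ReadSet(codes, lengths, ids=None, quality=q)


def write_fastq(reads: ReadSet, path: str) -> None:
    lut = np.frombuffer(b"ACGTNNN", dtype=np.uint8)
    with open(path, "w") as fh:
        q = reads.quality
        for i in range(len(reads)):
            n = int(reads.lengths[i])
            seq = bytes(lut[reads.codes[i, :n]]).decode()
            if np.ndim(q) == 0:
                qual = chr(int(q) + 33) * n
            else:
                qual = "".join(chr(int(x) + 33) for x in q[i, :n])
            fh.write(f"@{reads.read_id(i)}\n{seq}\n+\n{qual}\n")
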