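"""Genome Diff: typed mutation calls linked to their supporting evidence.

A Genome Diff (GD) file is a tab-delimited flat file with one entry per
line.  Mutation entries (DEL, INS, SUB, MOB, AMP) reference the evidence
entries (JC: new junction; MC: missing coverage) that support them through
parent ids.  The dialect written here uses the field orders documented in
:func:`write_genome_diff`; trailing ``key=value`` pairs carry optional
fields and survive round trips byte-for-byte.

``apply_mutations`` edits a reference genome according to a GD, which both
generates simulated mutant genomes and verifies that a predicted mutation
reproduces its observed junction sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .refio import Feature, ReferenceSet, revcomp

__all__ = [
    "Mutation",
    "JCEntry",
    "MCEntry",
    "GenomeDiff",
    "read_genome_diff",
    "write_genome_diff",
    "apply_mutations",
]

MUTATION_TYPES = ("DEL", "INS", "SUB", "MOB", "AMP")
EVIDENCE_TYPES = ("JC", "MC")


@dataclass
class Mutation:
    type: str
    id: str
    parent_ids: list[str]
    seq_id: str
    position: int  # 1-based; for DEL/SUB/AMP the first affected base
    size: int = 0  # DEL/SUB/AMP span length
    new_seq: str = ""  # INS/SUB inserted sequence
    repeat_name: str = ""  # MOB element family
    strand: int = 1  # MOB element orientation
    duplication_size: int = 0  # MOB target-site duplication length
    new_copy_number: int = 2  # AMP
    extras: dict = field(default_factory=dict)

    def affected_interval(self) -> tuple[int, int]:
        """1-based inclusive reference interval this mutation rewrites."""
        if self.type in ("DEL", "SUB", "AMP"):
            return self.position, self.position + self.size - 1
        if self.type == "MOB":
            hi = self.position + max(self.duplication_size, 1) - 1
            return self.position, hi
        return self.position, self.position  # INS (insertion after position)

    def length_change(self, element_length: int | None = None) -> int:
        if self.type == "DEL":
            return -self.size
        if self.type == "INS":
            return len(self.new_seq)
        if self.type == "SUB":
            return len(self.new_seq) - self.size
        if self.type == "AMP":
            return self.size * (self.new_copy_number - 1)
        if self.type == "MOB":
            if element_length is None:
                raise ValueError("MOB length change needs the element length")
            dels = int(self.extras.get("del_start", 0)) + int(
                self.extras.get("del_end", 0))
            ins = len(self.extras.get("ins_start", "")) + len(
                self.extras.get("ins_end", ""))
            return (element_length - dels + ins + self.duplication_size
                    - int(self.extras.get("target_del", 0)))
        raise ValueError(self.type)


@dataclass
class JCEntry:
    id: str
    side1_seq_id: str
    side1_position: int
    side1_strand: int
    side2_seq_id: str
    side2_position: int
    side2_strand: int
    overlap: int
    unique_read_seq: str = ""
    score: int = 0
    skew: float = 0.0
    status: str = "accepted"
    side1_redundant: bool = False
    side2_redundant: bool = False

    type: str = "JC"


@dataclass
class MCEntry:
    id: str
    seq_id: str
    start: int
    end: int
    start_range: int = 0  # width - 1 of the left boundary range
    end_range: int = 0
    left_in_repeat: bool = False
    right_in_repeat: bool = False

    type: str = "MC"


class GenomeDiff:
    def __init__(self, metadata: dict | None = None):
        self.metadata = dict(metadata or {})
        self.mutations: list[Mutation] = []
        self.evidence: list = []
        self._next = 1

    def new_id(self) -> str:
        i = str(self._next)
        self._next += 1
        return i

    def add_mutation(self, mut: Mutation) -> Mutation:
        if not mut.id:
            mut.id = self.new_id()
        self.mutations.append(mut)
        return mut

    def add_evidence(self, ev) -> object:
        if not ev.id:
            ev.id = self.new_id()
        self.evidence.append(ev)
        return ev

    def evidence_by_id(self) -> dict:
        return {e.id: e for e in self.evidence}

    def validate(self) -> None:
        ids = [e.id for e in self.evidence] + [m.id for m in self.mutations]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate entry ids in Genome Diff")
        known = set(e.id for e in self.evidence)
        for m in self.mutations:
            for p in m.parent_ids:
                if p not in known:
                    raise ValueError(
                        f"mutation {m.id}: unresolvable evidence id {p!r}")


def _fmt_extras(extras: dict) -> list[str]:
    return [f"{k}={v}" for k, v in sorted(extras.items())]


def write_genome_diff(gd: GenomeDiff, path: str) -> None:
    """Write a GD file.  Field orders after ``type, id, parent-ids``:

    DEL seq position size | INS seq position new_seq |
    SUB seq position size new_seq | AMP seq position size copies |
    MOB seq position repeat_name strand duplication_size |
    JC seq1 pos1 strand1 seq2 pos2 strand2 overlap |
    MC seq start end start_range end_range
    """
    lines = ["#=GENOME_DIFF\t1.0"]
    for k, v in sorted(gd.metadata.items()):
        lines.append(f"#={k.upper()}\t{v}")
    for m in gd.mutations:
        parents = ",".join(m.parent_ids) if m.parent_ids else "."
        base = [m.type, m.id, parents, m.seq_id, str(m.position)]
        extras = dict(m.extras)
        if m.type == "DEL":
            base.append(str(m.size))
        elif m.type == "INS":
            base.append(m.new_seq)
        elif m.type == "SUB":
            base += [str(m.size), m.new_seq]
        elif m.type == "AMP":
            base += [str(m.size), str(m.new_copy_number)]
        elif m.type == "MOB":
            base += [m.repeat_name, str(m.strand), str(m.duplication_size)]
        else:
            raise ValueError(f"unknown mutation type {m.type!r}")
        lines.append("\t".join(base + _fmt_extras(extras)))
    for e in gd.evidence:
        if e.type == "JC":
            base = ["JC", e.id, ".", e.side1_seq_id, str(e.side1_position),
                    str(e.side1_strand), e.side2_seq_id,
                    str(e.side2_position), str(e.side2_strand),
                    str(e.overlap)]
            extras = {}
            if e.unique_read_seq:
                extras["unique_read_sequence"] = e.unique_read_seq
            extras["score"] = e.score
            extras["skew"] = f"{e.skew:.4f}"
            extras["status"] = e.status
            if e.side1_redundant:
                extras["side_1_redundant"] = 1
            if e.side2_redundant:
                extras["side_2_redundant"] = 1
            lines.append("\t".join(base + _fmt_extras(extras)))
        elif e.type == "MC":
            base = ["MC", e.id, ".", e.seq_id, str(e.start), str(e.end),
                    str(e.start_range), str(e.end_range)]
            extras = {}
            if e.left_in_repeat:
                extras["left_in_repeat"] = 1
            if e.right_in_repeat:
                extras["right_in_repeat"] = 1
            lines.append("\t".join(base + _fmt_extras(extras)))
        else:
            raise ValueError(f"unknown evidence type {e.type!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _split_extras(fields: list[str]):
    plain, extras = [], {}
    for f in fields:
        if "=" in f and not f.startswith("="):
            k, v = f.split("=", 1)
            extras[k] = v
        else:
            plain.append(f)
    return plain, extras


def read_genome_diff(path: str) -> GenomeDiff:
    gd = GenomeDiff()
    max_id = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#="):
                key = line[2:].split("\t", 1)
                if key[0] != "GENOME_DIFF" and len(key) == 2:
                    gd.metadata[key[0].lower()] = key[1]
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            etype = fields[0]
            try:
                if etype in MUTATION_TYPES:
                    _, eid, parents = fields[0], fields[1], fields[2]
                    pids = [] if parents == "." else parents.split(",")
                    rest, extras = _split_extras(fields[3:])
                    seq_id, pos = rest[0], int(rest[1])
                    m = Mutation(etype, eid, pids, seq_id, pos, extras=extras)
                    if etype == "DEL":
                        m.size = int(rest[2])
                    elif etype == "INS":
                        m.new_seq = rest[2]
                    elif etype == "SUB":
                        m.size, m.new_seq = int(rest[2]), rest[3]
                    elif etype == "AMP":
                        m.size, m.new_copy_number = int(rest[2]), int(rest[3])
                    elif etype == "MOB":
                        m.repeat_name = rest[2]
                        m.strand = int(rest[3])
                        m.duplication_size = int(rest[4])
                    gd.mutations.append(m)
                elif etype == "JC":
                    rest, extras = _split_extras(fields[3:])
                    gd.evidence.append(JCEntry(
                        id=fields[1],
                        side1_seq_id=rest[0], side1_position=int(rest[1]),
                        side1_strand=int(rest[2]),
                        side2_seq_id=rest[3], side2_position=int(rest[4]),
                        side2_strand=int(rest[5]),
                        overlap=int(rest[6]),
                        unique_read_seq=extras.get("unique_read_sequence", ""),
                        score=int(extras.get("score", 0)),
                        skew=float(extras.get("skew", 0.0)),
                        status=extras.get("status", "accepted"),
                        side1_redundant=bool(int(extras.get("side_1_redundant", 0))),
                        side2_redundant=bool(int(extras.get("side_2_redundant", 0))),
                    ))
                elif etype == "MC":
                    rest, extras = _split_extras(fields[3:])
                    gd.evidence.append(MCEntry(
                        id=fields[1],
                        seq_id=rest[0], start=int(rest[1]), end=int(rest[2]),
                        start_range=int(rest[3]), end_range=int(rest[4]),
                        left_in_repeat=bool(int(extras.get("left_in_repeat", 0))),
                        right_in_repeat=bool(int(extras.get("right_in_repeat", 0))),
                    ))
                else:
                    raise ValueError(f"unknown entry type {etype!r}")
            except (IndexError, ValueError) as err:
                raise ValueError(f"{path}:{lineno}: malformed GD line "
                                 f"({err})") from err
            try:
                max_id = max(max_id, int(fields[1]))
            except ValueError:
                pass
    gd._next = max_id + 1
    return gd


# ---------------------------------------------------------------------------
# applying mutations


def element_sequence(ref: ReferenceSet, family: str) -> tuple[str, Feature]:
    """Sequence (reference orientation) of the first annotated copy of a
    repeat family."""
    for f in sorted(ref.features, key=lambda f: (f.seq_id, f.start)):
        if f.is_repeat() and f.family_name == family:
            seq = ref.subsequence(f.seq_id, f.start, f.end, "+")
            return seq, f
    raise ValueError(f"no annotated copy of repeat family {family!r}")


def mob_insert_sequence(ref: ReferenceSet, mut: Mutation) -> str:
    """The sequence a MOB mutation splices in after its target duplication."""
    elem, feat = element_sequence(ref, mut.repeat_name)
    ds = int(mut.extras.get("del_start", 0))
    de = int(mut.extras.get("del_end", 0))
    elem = elem[ds: len(elem) - de if de else len(elem)]
    if mut.strand == -1:
        elem = revcomp(elem)
    return (mut.extras.get("ins_start", "") + elem
            + mut.extras.get("ins_end", ""))


def apply_mutations(gd: GenomeDiff, ref: ReferenceSet) -> ReferenceSet:
    """Apply GD mutations to a reference, returning the mutated genome.

    Mutations must not overlap; they are applied from high to low coordinate
    per sequence so positions stay valid.  Features are lifted over: shifted
    when downstream of an edit, dropped when overlapping one, and a new
    mobile_element annotation is added for every MOB insertion.
    """
    by_seq: dict[str, list[Mutation]] = {}
    for m in gd.mutations:
        by_seq.setdefault(m.seq_id, []).append(m)
    for sid, muts in by_seq.items():
        muts.sort(key=lambda m: m.position)
        for a, b in zip(muts, muts[1:]):
            if a.affected_interval()[1] >= b.affected_interval()[0]:
                raise ValueError(
                    f"overlapping mutations {a.id} and {b.id} on {sid}")

    out = ReferenceSet()
    for sid in ref.seq_ids:
        seq = ref.sequence(sid)
        feats = [replace(f) for f in ref.features if f.seq_id == sid]
        for m in sorted(by_seq.get(sid, []), key=lambda m: -m.position):
            p = m.position
            if m.type == "DEL":
                seq = seq[: p - 1] + seq[p - 1 + m.size:]
                feats = _liftover(feats, p, p + m.size - 1, -m.size)
            elif m.type == "INS":
                seq = seq[:p] + m.new_seq + seq[p:]
                feats = _liftover(feats, p + 1, p, len(m.new_seq))
            elif m.type == "SUB":
                seq = seq[: p - 1] + m.new_seq + seq[p - 1 + m.size:]
                feats = _liftover(feats, p, p + m.size - 1,
                                  len(m.new_seq) - m.size)
            elif m.type == "AMP":
                unit = seq[p - 1: p - 1 + m.size]
                extra = unit * (m.new_copy_number - 1)
                seq = seq[: p - 1 + m.size] + extra + seq[p - 1 + m.size:]
                feats = _liftover(feats, p + m.size, p + m.size - 1,
                                  len(extra))
            elif m.type == "MOB":
                ins = mob_insert_sequence(ref, m)
                dup = m.duplication_size
                k = int(m.extras.get("target_del", 0))  # target bases lost
                # left part ends with the target site (bases p..p+dup-1);
                # the right part repeats them, creating the duplication
                cut = p + dup - 1
                seq = seq[:cut] + ins + seq[p - 1 + k:]
                feats = _liftover(feats, p, p - 1 + k, len(ins) + dup - k)
                feats.append(Feature(
                    seq_id=sid, start=cut + 1, end=cut + len(ins),
                    strand="+" if m.strand == 1 else "-",
                    kind="mobile_element", family_name=m.repeat_name,
                ))
            else:
                raise ValueError(m.type)
        out.add_sequence(sid, seq, ref.topology.get(sid, "linear"))
        for f in sorted(feats, key=lambda f: (f.start, f.end)):
            out.add_feature(f)
    return out


def _liftover(feats: list[Feature], lo: int, hi: int,
              delta: int) -> list[Feature]:
    """Shift features after an edit of reference interval [lo, hi] whose
    length changed by ``delta``; features overlapping the edit are dropped."""
    out = []
    for f in feats:
        if f.end < lo:
            out.append(f)
        elif f.start > hi:
            out.append(replace(f, start=f.start + delta, end=f.end + delta))
        # overlapping the edited interval: dropped
    return out
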