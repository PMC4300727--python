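"""Reference genomes with annotations, exact-repeat inventory, sequence extraction.

A :class:`ReferenceSet` holds one or more nucleotide sequences (uppercase
``ACGTN``; other IUPAC ambiguity codes are normalized to ``N``) together with
their feature annotations.  Features of type ``repeat_region`` /
``mobile_element`` (plus GenBank/GFF3 dialect variants) drive breakpoint
placement and mobile-element (MOB) calling downstream, so their family names
(e.g. ``IS150``) are retained.

Coordinates are 0-based half-open internally; every public operation and all
serialized formats (FASTA/GenBank/GFF3/GD) use 1-based inclusive positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "Feature",
    "RepeatInterval",
    "ReferenceSet",
    "load_reference",
    "enumerate_exact_repeats",
    "revcomp",
    "write_fasta",
    "write_gff3",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

#: feature types treated as repeat/mobile-element annotations (lower-cased)
REPEAT_FEATURE_TYPES = frozenset(
    {"repeat_region", "mobile_element", "mobile_element_insertion"}
)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse non-ACGT ambiguity codes to N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass
class Feature:
    """An annotated interval on a reference sequence (1-based inclusive)."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"  # repeat_region | mobile_element | gene | other
    family_name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.kind}/{self.family_name} on {self.seq_id}: "
                f"start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def is_repeat(self) -> bool:
        return self.kind in ("repeat_region", "mobile_element")


@dataclass
class RepeatInterval:
    """One occurrence of an exact sequence repeat, with its other copies.

    ``mates`` lists the other exact occurrences as ``(seq_id, start, strand)``
    where strand ``-`` means the mate carries the reverse complement.
    """

    seq_id: str
    start: int  # 1-based inclusive
    end: int
    mates: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ReferenceSet:
    """Ordered collection of reference sequences plus feature annotations.

    Sequence ids are unique; iteration order is alphabetical by id, which
    defines the "first reference sequence" priority used when canonicalizing
    junctions and assigning breakpoint overlap.
    """

    def __init__(self) -> None:
        self._sequences: dict[str, str] = {}
        self.features: list[Feature] = []
        self.topology: dict[str, str] = {}

    # -- construction -----------------------------------------------------

    def add_sequence(self, seq_id: str, seq: str, topology: str = "linear") -> None:
        if seq_id in self._sequences:
            raise ValueError(f"duplicate sequence id: {seq_id!r}")
        if topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {topology!r}")
        self._sequences[seq_id] = normalize_sequence(seq)
        self.topology[seq_id] = topology

    def add_feature(self, feature: Feature) -> None:
        if feature.seq_id not in self._sequences:
            raise ValueError(f"feature on unknown sequence {feature.seq_id!r}")
        if not (1 <= feature.start <= feature.end <= self.length(feature.seq_id)):
            raise ValueError(
                f"feature {feature.kind}/{feature.family_name} at "
                f"{feature.seq_id}:{feature.start}-{feature.end} outside "
                f"sequence bounds (length {self.length(feature.seq_id)})"
            )
        self.features.append(feature)

    # -- access ------------------------------------------------------------

    @property
    def seq_ids(self) -> list[str]:
        return sorted(self._sequences)

    def sequence(self, seq_id: str) -> str:
        return self._sequences[seq_id]

    def length(self, seq_id: str) -> int:
        return len(self._sequences[seq_id])

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._sequences

    def __iter__(self):
        for sid in self.seq_ids:
            yield sid, self._sequences[sid]

    def sort_priority(self, seq_id: str) -> int:
        """Rank of a sequence in alphabetical id order (0 = highest)."""
        return self.seq_ids.index(seq_id)

    def subsequence(self, seq_id: str, start: int, end: int, strand: str = "+") -> str:
        """Extract bases ``start..end`` (1-based inclusive) on ``strand``.

        For circular sequences ``start > end`` wraps around the origin.
        """
        seq = self._sequences[seq_id]
        n = len(seq)
        if start < 1 or end < 1:
            raise IndexError(f"coordinates must be >= 1: ({start},{end})")
        if start <= end:
            if end > n:
                if self.topology.get(seq_id) != "circular":
                    raise IndexError(
                        f"{seq_id}:{start}-{end} out of bounds (length {n})"
                    )
                reps = seq * (end // n + 1)
                out = reps[start - 1 : end]
            else:
                out = seq[start - 1 : end]
        else:
            if self.topology.get(seq_id) != "circular":
                raise IndexError(
                    f"{seq_id}: start {start} > end {end} on a linear sequence"
                )
            out = seq[start - 1 :] + seq[:end]
        return out if strand == "+" else revcomp(out)

    def repeat_features(self, extra_types: tuple[str, ...] = ()) -> list[Feature]:
        kinds = {"repeat_region", "mobile_element"} | set(extra_types)
        return [f for f in self.features if f.kind in kinds]

    def validate(self) -> None:
        for f in self.features:
            if f.seq_id not in self._sequences:
                raise ValueError(f"feature on unknown sequence {f.seq_id!r}")
            if not (1 <= f.start <= f.end <= self.length(f.seq_id)):
                raise ValueError(
                    f"feature {f.kind}/{f.family_name} at "
                    f"{f.seq_id}:{f.start}-{f.end} outside sequence bounds"
                )


# ---------------------------------------------------------------------------
# loading


def _classify_feature_type(ftype: str, extra_types: tuple[str, ...]) -> str:
    t = ftype.lower()
    if t in ("mobile_element", "mobile_element_insertion"):
        return "mobile_element"
    if t == "repeat_region" or t in {x.lower() for x in extra_types}:
        return "repeat_region"
    if t == "gene":
        return "gene"
    return "other"


def _family_from_qualifiers(quals: dict) -> str:
    for key in ("rpt_family", "mobile_element_type", "mobile_element", "label",
                "Name", "name", "gene", "note", "ID"):
        if key in quals:
            val = quals[key]
            if isinstance(val, (list, tuple)):
                val = val[0] if val else ""
            val = str(val)
            # GenBank style "insertion sequence:IS150"
            if ":" in val:
                val = val.split(":", 1)[1]
            if val:
                return val.strip()
    return ""


def _sniff_format(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("LOCUS"):
                return "genbank"
            if s.startswith("##gff-version") or s.startswith("##sequence-region"):
                return "gff3"
            if s.startswith(">"):
                return "fasta"
            # GFF3 body line without header
            if len(s.split("\t")) == 9:
                return "gff3"
            raise ValueError(f"{path}: unrecognized reference format")
    raise ValueError(f"{path}: empty file")


def _load_gff3(path: str, ref: ReferenceSet,
               extra_types: tuple[str, ...]) -> list[Feature]:
    """Minimal GFF3 reader (9-column lines; optional embedded ##FASTA)."""
    feats: list[Feature] = []
    fasta_lines: list[str] = []
    in_fasta = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if in_fasta:
                fasta_lines.append(line)
                continue
            if line.startswith("##FASTA"):
                in_fasta = True
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            quals = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    quals[k.strip()] = v.strip()
            feats.append(
                Feature(
                    seq_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    kind=_classify_feature_type(ftype, extra_types),
                    family_name=_family_from_qualifiers(quals),
                )
            )
    if fasta_lines:
        sid = None
        chunks: list[str] = []
        for line in fasta_lines:
            if line.startswith(">"):
                if sid is not None:
                    ref.add_sequence(sid, "".join(chunks))
                sid = line[1:].split()[0]
                chunks = []
            elif sid is not None:
                chunks.append(line.strip())
        if sid is not None:
            ref.add_sequence(sid, "".join(chunks))
    return feats


def load_reference(paths: list[str] | str,
                   extra_repeat_types: tuple[str, ...] = ()) -> ReferenceSet:
    """Load reference files (FASTA, GenBank, or GFF3 with embedded FASTA).

    Multiple files are merged into one :class:`ReferenceSet`; a sidecar FASTA
    may accompany a GFF3 that lacks an embedded ``##FASTA`` section.  Duplicate
    sequence ids and out-of-bounds features are hard errors.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    ref = ReferenceSet()
    pending: list[Feature] = []
    for path in paths:
        fmt = _sniff_format(str(path))
        if fmt == "fasta":
            for rec in SeqIO.parse(str(path), "fasta"):
                ref.add_sequence(rec.id, str(rec.seq))
        elif fmt == "genbank":
            for rec in SeqIO.parse(str(path), "genbank"):
                topo = rec.annotations.get("topology", "linear")
                ref.add_sequence(rec.id, str(rec.seq),
                                 "circular" if topo == "circular" else "linear")
                for bf in rec.features:
                    kind = _classify_feature_type(bf.type, extra_repeat_types)
                    if kind == "other" and bf.type not in ("gene", "CDS"):
                        continue
                    if kind == "other":
                        kind = "gene" if bf.type == "gene" else "other"
                    pending.append(
                        Feature(
                            seq_id=rec.id,
                            start=int(bf.location.start) + 1,
                            end=int(bf.location.end),
                            strand="-" if bf.location.strand == -1 else "+",
                            kind=kind,
                            family_name=_family_from_qualifiers(bf.qualifiers),
                        )
                    )
        else:  # gff3
            pending.extend(_load_gff3(str(path), ref, extra_repeat_types))
    for f in pending:
        ref.add_feature(f)
    return ref


# ---------------------------------------------------------------------------
# writers (FASTA for mutated genomes; GFF3 for lifted-over annotations)


def write_fasta(ref: ReferenceSet, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in ref:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(ref: ReferenceSet, path: str, embed_fasta: bool = True) -> None:
    type_of = {"repeat_region": "repeat_region", "mobile_element": "mobile_element",
               "gene": "gene", "other": "region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, seq in ref:
            fh.write(f"##sequence-region {sid} 1 {len(seq)}\n")
        for i, f in enumerate(sorted(ref.features,
                                     key=lambda f: (f.seq_id, f.start))):
            attrs = f"ID=feat{i + 1}"
            if f.family_name:
                attrs += f";Name={f.family_name}"
            fh.write(
                "\t".join(
                    [f.seq_id, "haplosv", type_of.get(f.kind, "region"),
                     str(f.start), str(f.end), ".", f.strand, ".", attrs]
                )
                + "\n"
            )
        if embed_fasta:
            fh.write("##FASTA\n")
            for sid, seq in ref:
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# exact repeat enumeration


def enumerate_exact_repeats(ref: ReferenceSet, min_len: int = 36,
                            include_revcomp: bool = True) -> list[RepeatInterval]:
    """Report every maximal exact repeat of length >= ``min_len``.

    An interval is reported when its sequence occurs at least twice in the
    reference (on either strand when ``include_revcomp``).  Windows containing
    N never match.  Output is sorted by ``(seq_id, start)``; each occurrence
    lists its mates.

    The implementation indexes all ``min_len``-mers and merges co-diagonal
    seed matches into maximal pairwise matches, so runtime is near-linear for
    genomes without massive low-complexity repeats.
    """
    k = min_len
    if k < 2:
        raise ValueError("min_len must be >= 2")

    # occurrences of each canonical k-mer: (seq_idx, pos0, orient)
    seq_ids = ref.seq_ids
    occ: dict[bytes, list[tuple[int, int, int]]] = {}
    for si, sid in enumerate(seq_ids):
        s = ref.sequence(sid)
        b = s.encode()
        rb = revcomp(s).encode()
        n = len(s)
        for i in range(n - k + 1):
            w = b[i : i + k]
            if b"N" in w:
                continue
            if include_revcomp:
                rw = rb[n - i - k : n - i]
                if w <= rw:
                    occ.setdefault(w, []).append((si, i, +1))
                if rw <= w:
                    occ.setdefault(rw, []).append((si, i, -1))
            else:
                occ.setdefault(w, []).append((si, i, +1))

    # pairwise seed matches grouped for run-merging
    fwd: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
    rc: dict[tuple[int, int, int], list[int]] = {}
    for hits in occ.values():
        if len(hits) < 2:
            continue
        for x in range(len(hits)):
            sa, pa, fa = hits[x]
            for y in range(x + 1, len(hits)):
                sb, pb, fb = hits[y]
                if (sa, pa) == (sb, pb):
                    continue  # palindromic self-match
                if (sb, pb) < (sa, pa):
                    (sa, pa, fa), (sb, pb, fb) = (sb, pb, fb), (sa, pa, fa)
                if fa == fb:
                    fwd.setdefault((sa, sb, pb - pa), []).append((pa, pb))
                else:
                    rc.setdefault((sa, sb, pa + pb), []).append(pa)

    # merge consecutive co-diagonal seeds into maximal matches
    matches: set[tuple[int, int, int, int, int, str]] = set()
    for (sa, sb, _d), pairs in fwd.items():
        pas = sorted({pa for pa, _ in pairs})
        off = pairs[0][1] - pairs[0][0]
        run_start = prev = pas[0]
        for pa in pas[1:] + [None]:
            if pa is not None and pa == prev + 1:
                prev = pa
                continue
            length = prev - run_start + k
            matches.add((sa, run_start, sb, run_start + off, length, "+"))
            if pa is not None:
                run_start = prev = pa
    for (sa, sb, ssum), pas_list in rc.items():
        pas = sorted(set(pas_list))
        run_start = prev = pas[0]
        for pa in pas[1:] + [None]:
            if pa is not None and pa == prev + 1:
                prev = pa
                continue
            length = prev - run_start + k
            # mate interval start: for pa in run, pb = ssum - pa is the RC
            # window start; over the run the mate interval spans
            # [ssum - prev, ssum - run_start + k - 1]
            matches.add((sa, run_start, sb, ssum - prev, length, "-"))
            if pa is not None:
                run_start = prev = pa

    # assemble intervals with mates
    by_interval: dict[tuple[int, int, int], list[tuple[str, int, str]]] = {}
    for sa, pa, sb, pb, length, strand in matches:
        by_interval.setdefault((sa, pa, length), []).append(
            (seq_ids[sb], pb + 1, strand)
        )
        by_interval.setdefault((sb, pb, length), []).append(
            (seq_ids[sa], pa + 1, strand)
        )
    out = []
    for (si, p, length), mates in sorted(by_interval.items()):
        out.append(
            RepeatInterval(
                seq_id=seq_ids[si],
                start=p + 1,
                end=p + length,
                mates=sorted(set(mates)),
            )
        )
    out.sort(key=lambda r: (r.seq_id, r.start, r.end))
    return out
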