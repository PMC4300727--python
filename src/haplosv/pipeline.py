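"""Single-call orchestration of the structural-variant pipeline.

Stages: map reads (stringent, then relaxed for unmapped reads) -> split
alignments at indels -> build, collapse and pre-select junction candidates
-> fit the coverage model -> re-map reads to candidates and statistically
evaluate junctions -> place breakpoints and split junction reads back onto
the reference -> detect missing coverage -> integrate evidence into
mutation calls, written as Genome Diff.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import calls as _calls
from .coverage import (CoverageModel, CoverageTable, find_missing_coverage,
                       fit_coverage_model, tabulate_coverage_batch)
from .gd import GenomeDiff, JCEntry, MCEntry, write_genome_diff
from .junction_eval import (JunctionTestResult, evaluate_all_junctions,
                            place_breakpoint, remap_and_resolve,
                            split_reads_onto_reference)
from .junctions import (JunctionCandidate, collapse_candidates, make_candidate,
                        pairs_for_read, prescore_and_select,
                        split_alignment_at_indels)
from .readmap import (GenomeIndex, ReadSet, map_reads_batch, materialize,
                      stage_mapping_params)
from .refio import ReferenceSet, load_reference

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "benchmark"]


@dataclass
class PipelineConfig:
    """Every tunable default of the pipeline; echoed into the run log."""

    min_indel_split: int = 3  # split alignments at indels this long
    span_fraction: float = 0.9  # reads with one alignment this long skip pairing
    side_fraction: float = 0.2  # each junction side must span 0.2 L
    end_tail_fraction: float = 0.1  # unaligned tail allowance past 50 bases
    overlap_base: int = 12  # V,|U| <= overlap_base + overlap_slope (L - 12)
    overlap_slope: float = 0.4
    max_candidates: int = 5000
    max_total_len_fraction: float = 0.10
    min_kept: int = 100
    min_evenness: int = 2
    skew_threshold: float = 3.0
    repeat_margin: int = 20
    mc_tail_probability: float = 0.05  # divided by sqrt(reference length)
    min_fit_positions: int = 1000
    seed: int = 0


@dataclass
class PipelineResult:
    gd: GenomeDiff
    accepted: list[JunctionTestResult]
    marginal: list[JunctionTestResult]
    mc: list
    model: CoverageModel
    table: CoverageTable
    candidates: list[JunctionCandidate]
    config: PipelineConfig
    mean_read_length: float
    max_read_length: int
    n_reads: int
    unassigned: list = field(default_factory=list)
    log: dict = field(default_factory=dict)
    # internals retained for benchmarking sweeps
    _resolution: object = None
    _ref: ReferenceSet | None = None

    def accepted_junction_sequences(self, flank: int | None = None) -> list[str]:
        """Junction sequences of accepted junctions (benchmark flank rule:
        mean read length - 5 unless overridden)."""
        if flank is None:
            flank = int(round(self.mean_read_length)) - 5
        from .junctions import build_junction_sequence

        out = []
        for r in self.accepted:
            c = r.candidate
            seq, _, _, _ = build_junction_sequence(
                self._ref, c.side1, c.side2, c.overlap, c.unique_seq, flank)
            out.append(seq)
        return out


def _redundant_key(aln):
    return (aln.read_start, aln.read_end, round(aln.score, 3))


def run_pipeline(reads, reference, config: PipelineConfig | None = None,
                 outdir: str | None = None) -> PipelineResult:
    """Run the full pipeline on a read set against a reference.

    ``reads`` may be a :class:`ReadSet`, a FASTQ path, or a sequence list;
    ``reference`` a :class:`ReferenceSet` or reference file path(s).
    When ``outdir`` is given, writes ``output.gd``, ``summary.tsv`` and
    ``run_log.json`` there.
    """
    config = config or PipelineConfig()
    ref = (reference if isinstance(reference, ReferenceSet)
           else load_reference(reference))
    if isinstance(reads, ReadSet):
        rs = reads
    elif isinstance(reads, (str, os.PathLike)):
        rs = ReadSet.from_fastq(str(reads))
    else:
        rs = ReadSet.from_sequences(list(reads))
    if len(rs) == 0:
        raise ValueError("no input reads")
    log: dict = {"config": asdict(config), "n_reads": len(rs),
                 "mean_read_length": rs.mean_length,
                 "max_read_length": rs.max_length}

    # 1. map
    gidx = GenomeIndex(ref, pad=max(512, rs.max_length + 1))
    batch = map_reads_batch(rs, gidx)
    best_ref = np.full(len(rs), -np.inf)
    if len(batch):
        np.maximum.at(best_ref, batch.read, batch.score)
    log["n_alignments"] = int(len(batch))
    log["n_reads_mapped"] = int(np.isfinite(best_ref).sum())

    # 2. junction candidates from relaxed-stage (split) reads
    relaxed_reads = np.unique(batch.read[batch.stage == 1]) if len(batch) else []
    idx = np.flatnonzero(np.isin(batch.read, relaxed_reads)) if len(batch) else []
    per_read = materialize(rs, gidx, batch, idx)
    raw_cands: list[JunctionCandidate] = []
    for read_i, alns in per_read.items():
        read_seq = rs.sequence(read_i)
        expanded = []
        for a in alns:
            if a.has_indel():
                expanded.extend(split_alignment_at_indels(
                    a, ref, read_seq, config.min_indel_split))
            else:
                expanded.append(a)
        groups: dict = {}
        for a in expanded:
            groups.setdefault(_redundant_key(a), []).append(a)
        red = {id(a) for g in groups.values() if len(g) > 1 for a in g}
        for pair in pairs_for_read(expanded, read_seq,
                                   max_span_fraction=config.span_fraction):
            cand = make_candidate(pair, ref, rs.max_length,
                                  side1_redundant=id(pair.side1) in red,
                                  side2_redundant=id(pair.side2) in red)
            if cand is not None:
                raw_cands.append(cand)
    log["n_candidate_raw"] = len(raw_cands)
    collapsed = collapse_candidates(raw_cands)
    total_ref_len = sum(ref.length(s) for s in ref.seq_ids)
    candidates = prescore_and_select(
        collapsed, total_ref_len,
        max_candidates=config.max_candidates,
        max_total_len_fraction=config.max_total_len_fraction,
        min_kept=config.min_kept, min_score=config.min_evenness)
    log["n_candidate_selected"] = len(candidates)

    # 3. coverage model from initial best mappings
    table0 = tabulate_coverage_batch(batch, rs, gidx)
    model = fit_coverage_model(table0, ref, config.min_fit_positions)
    log["coverage_model"] = {
        sid: {"mu": model.mu[sid], "alpha": model.alpha[sid],
              "p0": model.p0[sid], "threshold": model.threshold[sid]}
        for sid in model.mu
    }

    # 4. junction evaluation
    stringent = stage_mapping_params(rs.mean_length, rs.max_length, "stringent")
    resolution = remap_and_resolve(rs, candidates, best_ref, stringent)
    accepted, marginal = evaluate_all_junctions(
        candidates, resolution, model, rs.mean_length, ref,
        skew_threshold=config.skew_threshold)
    for r in accepted:
        place_breakpoint(r, ref.features, config.repeat_margin)
    log["n_junctions_accepted"] = len(accepted)
    log["n_junctions_marginal"] = len(marginal)

    # 5. final coverage (claimed reads replaced by their split pieces)
    claimed = np.zeros(len(rs), dtype=bool)
    for r in accepted:
        claimed[r.claimed_reads] = True
    final_batch = batch.select(~claimed[batch.read]) if len(batch) else batch
    table = tabulate_coverage_batch(final_batch, rs, gidx)
    for r in accepted:
        for piece in split_reads_onto_reference(r, resolution, rs,
                                                r.cand_index):
            table.add_interval(piece.seq_id, piece.ref_start, piece.ref_end,
                               unique=piece.unique)

    # 6. missing coverage
    mc = find_missing_coverage(table, model.threshold)
    log["n_mc"] = len(mc)

    # 7. evidence -> mutations
    jc_entries = []
    for r in accepted:
        s1 = r.side1_resolved or r.candidate.side1
        s2 = r.side2_resolved or r.candidate.side2
        # breakpoint placement has assigned all overlap bases to a side,
        # so resolved evidence carries overlap 0
        jc_entries.append(JCEntry(
            id="", side1_seq_id=s1.seq_id, side1_position=s1.pos,
            side1_strand=s1.strand, side2_seq_id=s2.seq_id,
            side2_position=s2.pos, side2_strand=s2.strand,
            overlap=0,
            unique_read_seq=r.candidate.unique_seq,
            score=r.S_obs, skew=r.skew, status="accepted",
            side1_redundant=s1.redundant, side2_redundant=s2.redundant))
    mc_entries = [
        MCEntry(id="", seq_id=m.seq_id, start=m.left_lo, end=m.right_hi,
                start_range=m.left_hi - m.left_lo,
                end_range=m.right_hi - m.right_lo,
                left_in_repeat=m.left_in_repeat,
                right_in_repeat=m.right_in_repeat)
        for m in mc
    ]
    gd, unassigned = _calls.call_structural_variants(
        jc_entries, mc_entries, ref, ref.features, rs.mean_length)
    gd.metadata.update({"program": "haplosv", "seed": config.seed})
    for r in marginal:
        c = r.candidate
        gd.add_evidence(JCEntry(
            id="", side1_seq_id=c.side1.seq_id, side1_position=c.side1.pos,
            side1_strand=c.side1.strand, side2_seq_id=c.side2.seq_id,
            side2_position=c.side2.pos, side2_strand=c.side2.strand,
            overlap=c.overlap, unique_read_seq=c.unique_seq,
            score=r.S_obs, skew=min(r.skew, 9999.0), status="marginal"))
    log["n_mutations"] = len(gd.mutations)
    log["mutation_types"] = sorted(m.type for m in gd.mutations)

    result = PipelineResult(
        gd=gd, accepted=accepted, marginal=marginal, mc=mc, model=model,
        table=table, candidates=candidates, config=config,
        mean_read_length=rs.mean_length, max_read_length=rs.max_length,
        n_reads=len(rs), unassigned=unassigned, log=log,
        _resolution=resolution, _ref=ref,
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_genome_diff(gd, os.path.join(outdir, "output.gd"))
        rows = [{"type": m.type, "seq_id": m.seq_id, "position": m.position,
                 "size": m.size, "new_seq": m.new_seq,
                 "repeat_name": m.repeat_name,
                 "duplication_size": m.duplication_size,
                 "evidence": ",".join(m.parent_ids)}
                for m in gd.mutations]
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "summary.tsv"),
                                  sep="\t", index=False)
        with open(os.path.join(outdir, "run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, default=str)
    return result


def benchmark(result: PipelineResult, truth_gd: GenomeDiff,
              thresholds=(0.5, 1.0, 2.0, 3.0, 5.0, 10.0)) -> pd.DataFrame:
    """Sensitivity/precision of junction prediction vs skew cutoff.

    Junctions are compared as sequences with mean-read-length - 5 flanking
    bases; a prediction matches a truth junction when either sequence is an
    exact subsequence of the other or of its reverse complement.
    """
    ref = result._ref
    flank = int(round(result.mean_read_length)) - 5
    truth_seqs = _calls.junction_sequences_for_truth(truth_gd, ref, flank)
    from .junctions import build_junction_sequence

    rows = []
    for cutoff in thresholds:
        accepted, _ = evaluate_all_junctions(
            result.candidates, result._resolution, result.model,
            result.mean_read_length, ref, skew_threshold=cutoff)
        pred = []
        for r in accepted:
            c = r.candidate
            seq, _, _, _ = build_junction_sequence(
                ref, c.side1, c.side2, c.overlap, c.unique_seq, flank)
            pred.append(seq)
        sens, prec, _ = _calls.compare_junction_sets(pred, truth_seqs)
        rows.append({"skew_cutoff": cutoff, "n_predicted": len(pred),
                     "sensitivity": sens, "precision": prec})
    return pd.DataFrame(rows)
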