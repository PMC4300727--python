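"""Simulate a mutated microbial genome and call its structural variants.

Builds a 200-kb synthetic genome with eight identical IS-element copies,
plants ten unique-junction deletions, sequences it to 40-fold coverage with
50-base reads, and runs the full pipeline.  Each printed line is one
predicted deletion: its position and size should match a planted event
(possibly shifted by breakpoint homology, which leaves the mutant sequence
identical).
"""

from haplosv import (PipelineConfig, ReadSimModel, SimPlan, random_genome,
                     run_pipeline, simulate_reads, simulate_sv_genome)

ref = random_genome(length=200_000, n_elements=8, seed=1)
mutant, truth = simulate_sv_genome(
    ref, SimPlan("unique-deletion", count=10, seed=2))
reads = simulate_reads(mutant, ReadSimModel(read_length=50, coverage=40,
                                            error_rate=0.001, seed=3))
print(f"simulated {len(reads)} reads from a "
      f"{mutant.length('chr1'):,}-bp mutant genome")

result = run_pipeline(reads, ref, PipelineConfig())

print(f"\naccepted junctions: {len(result.accepted)}   "
      f"missing-coverage intervals: {len(result.mc)}")
print("\ntruth -> calls")
for tm in sorted(truth.mutations, key=lambda m: m.position):
    hit = min(result.gd.mutations, key=lambda m: abs(m.position - tm.position))
    print(f"  DEL @{tm.position:>7} len {tm.size:>4}  ->  "
          f"{hit.type} @{hit.position:>7} len {hit.size:>4} "
          f"(evidence {','.join(hit.parent_ids)})")
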