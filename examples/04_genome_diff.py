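"""Genome Diff round trip, genome application, and rate arithmetic.

Writes a small Genome Diff with a deletion and a mobile-element insertion,
reads it back, applies it to a reference, and checks the resulting genome
lengths.  Finally reproduces the spontaneous structural-variation rate
arithmetic for a mutation-accumulation experiment: 53 events over 21
lineages of 6,000 generations each.
"""

import tempfile

from haplosv import (Feature, GenomeDiff, Mutation, ReferenceSet,
                     apply_mutations, mutation_rate_estimate,
                     read_genome_diff, write_genome_diff, random_genome)

ref = random_genome(length=50_000, n_elements=2, element_length=1443,
                    seed=5, family="ISdemo")

gd = GenomeDiff({"title": "demo"})
gd.add_mutation(Mutation("DEL", "", [], "chr1", 20_001, size=700))
gd.add_mutation(Mutation("MOB", "", [], "chr1", 30_000,
                         repeat_name="ISdemo", strand=1, duplication_size=6))

with tempfile.NamedTemporaryFile(suffix=".gd", mode="w", delete=False) as fh:
    path = fh.name
write_genome_diff(gd, path)
back = read_genome_diff(path)
print(f"round trip: {len(back.mutations)} mutations recovered")

mutant = apply_mutations(back, ref)
delta = mutant.length("chr1") - ref.length("chr1")
print(f"applied genome length change: {delta:+} "
      f"(expected -700 + 1443 + 6 = {-700 + 1443 + 6:+})")

rate, lo, hi = mutation_rate_estimate(53, 21, 6000)
print(f"SV rate: {rate:.2g} per genome per generation "
      f"(95% CI {lo:.2g} - {hi:.2g})")
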