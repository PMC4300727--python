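"""Fit the read-depth model that calibrates junction and deletion evidence.

Simulates uniform 30x coverage of an 80-kb genome, tabulates per-position
depth and read starts, and fits the censored negative binomial.  The fitted
mean should sit near 30; the size parameter is large because simulated
coverage is nearly Poisson; p0 (the chance that no read starts at a given
position and strand) should be close to exp(-cov / (2 * read_len)); and the
propagation threshold is the depth below which missing-coverage intervals
may extend.
"""

import numpy as np

from haplosv import ReadSimModel, random_genome, simulate_reads
from haplosv.coverage import (estimate_no_start_probability,
                              fit_censored_negbinom, propagation_threshold,
                              tabulate_coverage_batch)
from haplosv.readmap import GenomeIndex, map_reads_batch

ref = random_genome(length=80_000, n_elements=0, seed=11)
reads = simulate_reads(ref, ReadSimModel(read_length=50, coverage=30,
                                         error_rate=0.0, seed=12))
gidx = GenomeIndex(ref, pad=600)
table = tabulate_coverage_batch(map_reads_batch(reads, gidx), reads, gidx)

mu, alpha = fit_censored_negbinom(table, "chr1")
p0 = estimate_no_start_probability(table, "chr1")
t = propagation_threshold(mu, alpha, ref.length("chr1"))

print(f"fitted coverage mean mu_cov   = {mu:.2f}  (requested 30)")
print(f"fitted size alpha_cov         = {alpha:.1f}  (large => ~Poisson)")
print(f"no-start probability p0       = {p0:.4f}  "
      f"(theory {np.exp(-30 / 100):.4f})")
print(f"MC propagation threshold      = {t}  reads")
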