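"""The junction evenness statistic and its skew p-value.

For 50-base reads a junction with no overlap has S_max = 2*(50-1) = 98
start-position/strand slots that could hold a supporting read.  The skew
p-value asks how often a typical genome position would show an evenness
score at least as low as the one observed, integrating over the coverage
distribution.  Junctions whose skew (-log10 p) exceeds 3.0 are rejected:
real junctions at 40x coverage sit far below that, while a pile of reads
all sharing one start position is rejected no matter how deep it is.
"""

from haplosv.junction_eval import junction_skew_pvalue, max_evenness_score

mu, alpha, p0 = 40.0, 12.0, 0.55

print("overlap V -> S_max (50-base reads):")
for V in (0, 4, 12):
    print(f"  V={V:>2}  S_max={max_evenness_score(50, V, 0, 0)}")

smax = max_evenness_score(50, 0, 0, 0)
print(f"\nskew vs observed evenness score (S_max={smax}, "
      f"mu={mu}, alpha={alpha}, p0={p0}):")
for sobs in (55, 40, 25, 10, 1):
    p, skew = junction_skew_pvalue(sobs, smax, mu, alpha, p0)
    verdict = "accept" if skew <= 3.0 else "reject"
    print(f"  S={sobs:>2}  p={p:0.3e}  skew={skew:6.2f}  -> {verdict}")
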