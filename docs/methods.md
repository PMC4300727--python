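# Methods

`haplosv` predicts structural variation (SV) in clonal, haploid microbial
samples from single-end short reads mapped against a closely related
reference genome. Two evidence types drive every call: **new-junction (JC)
evidence** — candidate sequences joining two discontinuous reference
locations, supported by split-read alignments crossing the breakpoint — and
**missing-coverage (MC) evidence** — reference intervals without uniquely
mapped read depth. Both are combined with repeat/mobile-element annotations
into typed mutation calls (DEL, INS, SUB, MOB, AMP) written as Genome Diff.

## Read mapping

The built-in mapper is a hash-seeded, ungapped local aligner that reports
*every* placement of a read at or above the stage score threshold,
including all placements inside repeats — repeat placements are information
here, not noise. Scoring is +1 per matching base; a mismatch costs 1 at
base quality ≤ 2 rising linearly to 3 at quality ≥ 40 (the linear
interpolation is a calibration choice; the endpoints are the model);
gaps in externally supplied alignments cost 2 to open plus 3 per base.

Mapping is staged. The **stringent** stage uses seeds of 0.5·L̄ bases
(clamped to [9, 31], L̄ the mean read length), spaced every
⌊1 + 0.25·√L⌋ positions, and keeps alignments scoring ≥ 0.9·L. Reads left
unmapped are retried in a **relaxed** stage with seeds of ⌊5 + 0.1·L̄⌋
bases (same clamp and spacing) and threshold 6 + 0.2·L, which lets the two
sides of a breakpoint-crossing read surface as two local alignments.

A design deviation worth stating: the extension step is strictly ungapped
(a maximum-scoring run along each seed diagonal) rather than banded-gapped.
Reference indels of length ≥ 3 then appear directly as two local alignments
on different diagonals — which is the representation the junction machinery
needs anyway, since gapped alignments are split at indels ≥ 3 before
pairing (`split_alignment_at_indels` still handles gapped SAM input, and
rewrites insertions that duplicate adjacent reference bases by maximally
re-extending both pieces, reproducing what a split-read mapper would have
reported). Indels of 1–2 bases inside otherwise-good alignments are the
domain of point-mutation calling, which is out of scope here. The ungapped
core keeps the whole mapper vectorizable in numpy: ~1.5 M 50-base reads
against a 1-Mb reference map in well under two minutes on one core.
External aligners can be substituted through SAM ingest (`pysam`); scores
are recomputed with the scheme above so downstream behavior is identical.

## Junction candidates

For every read where no single alignment spans ≥ 90% of the read, all
ordered alignment pairs are screened by six guards: side 1 must start at
read base 1; side 2 must end at the final base (reads ≤ 50) or leave a tail
of at most 0.1·(L − 50) bases; each side must contribute ≥ 0.2·L bases
outside the overlap; the overlap V = s₁ − r₂ + 1 (when s₁ ≥ r₂) and any
read-only insert U (when r₂ > s₁ + 1) are bounded by 12 + 0.4·(L − 12);
and only pairs achieving the read's maximum spanned length survive.

A passing pair defines a junction by six parameters: two reference
positions, two continuation directions, the overlap count, and the
read-only bases. Overlaps containing mismatches or indels are trimmed back
until the remainder matches both reference locations perfectly. The
candidate sequence takes (max read length − 1) − V (or −|U|) reference
bases per side beyond the breakpoint core, so that any read crossing the
core aligns strictly better to the junction than to the reference.
Candidates are canonicalized (side 1 on the alphabetically first sequence,
or the lower coordinate; reverse-complementing as needed — the side
convention here is chosen so that sequence reversal swaps the sides but
preserves each side's strand label), merged when identical, then collapsed:
among sequence-equivalent candidates (subsequence or reverse-complement
subsequence) the shortest sequence survives, preferring same-fragment and
nearby-coordinate descriptions. Per-side "redundant" flags (the side
matches multiple reference placements equally well) are OR-ed across
merges — a detail that matters, because the surviving shortest description
can stem from a single placement with a lucky one-base extension while the
junction side is in fact repetitive, and mobile-element calling keys on
that flag.

Candidates are pre-scored by **coverage evenness** S — the number of
distinct (start position, strand) classes among supporting reads that span
the breakpoint core — and kept score-class by score-class until a class
would exceed 5,000 candidates or 10% of the reference length in cumulative
sequence, once at least 100 are in; candidates with S < 2 are dropped.

## Coverage model

Read depth at unique-only positions (not touched by any multiply-mapped
read) is fit by a negative binomial with mean μ_cov and size α_cov, by
maximum likelihood with the data left-censored below 0.5× and
right-censored above 1.5× the average (censored likelihood terms, not
truncation): deleted regions with stray residual coverage and spurious
pileups then pull on the tails, not the fit. The censoring bounds are
recomputed once from the first fit, stabilizing them when the raw mean is
itself biased by deletions. Method-of-moments is the fallback if the
optimizer fails. The same tabulation yields p̄₀, the zero-start fraction
over 2 × (unique-only positions) — the chance that a (position, strand)
slot holds no read start.

## Junction evaluation

All reads are re-mapped to the candidate sequences with the stringent
parameters. Reads the reference beats outright go back to the reference;
reads tying or beating it are held unresolved with every candidate they
tie. Candidates are then evaluated in descending order of recomputed S,
with unresolved reads counting toward the candidate under test; an
accepted candidate permanently claims its reads.

The expected maximum evenness score is

    S_max = 2 · (⌈L̄⌉ − 1 − overlap − C₁ − C₂)

(two strands, one slot per unambiguous start position). C₁/C₂ are
continuation lengths: at short tandem repeats a read must align several
bases past the breakpoint core before it supports the junction over the
reference; they are computed by running the junction sequence against each
side's reference continuation until first mismatch. The observed S is
tested against

    p = Σₓ NegBinom(x; μ_cov, α_cov) · BinomCDF(S; S_max, p_succ(x)),
    p_succ(x) = 1 − p̄₀^(x/μ_cov),

the per-slot success chance scaling with local coverage x (exact under
Poisson thinning; isolated in one function for substitution). The sum runs
to the NB 1 − 10⁻⁶ quantile and is evaluated in log space, so extreme skews
never collapse to p = 0. The skew is −log₁₀ p; candidates with skew > 3.0
are rejected, the best of them kept as *marginal* output. When the two
sides lie on different reference sequences, the least-significant side's
p-value is used. Mixed read lengths use the mean length L̄ for S_max;
observed S is clipped at S_max.

Accepted junctions get breakpoints placed by three ordered rules:
(1) snap to a repeat/mobile-element boundary within 20 bases (possibly
assigning overlap bases to both sides); (2) overlap to the unique side when
the other side is repeat-only; (3) overlap to the higher-priority side.
Claimed reads are split at the placed breakpoint into two reference
alignments; the final coverage table replaces the claimed reads' original
placements with these pieces, so true junctions leave no artificial
coverage dip. A piece belonging to a redundant (multi-mapping) side counts
as repeat depth, not unique depth — it was arbitrarily placed on one copy,
and counting it as unique would block missing-coverage propagation into
the adjacent element.

## Missing coverage

Seeds are positions with zero total (unique + repeat) depth. They
propagate outward and join through positions whose unique-only depth is at
or below a threshold: the largest depth whose NB CDF stays within
0.05/√(sequence length) — in particular straight through regions covered
only by repeat reads. A margin crossed through repeat coverage leaves that
boundary as an ambiguous range (flagged); boundaries reached without
repeat involvement are collapsed to the outer edge of the propagated run,
which keeps the invariant that a range wider than one position always
overlaps repeat coverage. Single above-threshold positions terminate
propagation; the inclusive comparison (≤ t) and the non-strict tail
inequality are each isolated in one function.

## Mutation calls

Five rules, in order, each consuming evidence once: (a) DEL from a
both-sides-unique JC whose breakpoints exactly match an MC interval's
boundary ranges; (b) DEL from an MC alone whose two ends fall in annotated
same-family, same-orientation repeat copies (spanning the intervening
region plus the second copy); (c) short DEL/INS/SUB from a both-sides-
unique JC with same-side orientation and breakpoints closer than L̄, and
AMP (tandem, copy number 2) for the opposite orientation — junctions wider
than L̄ stay unassigned; (d) MOB from two JCs whose unique endpoints lie
within 20 bp and whose redundant sides attach opposite ends of one repeat
family: the target-site duplication comes from the two unique coordinates,
element orientation from which end faces the left flank, and margin
deletions/insertions from breakpoint offsets into the element and read-only
bases — a candidate geometry is accepted only if applying it to the
reference reproduces both junction sequences (the apply-and-verify oracle
fixes every sign convention); (e) IS-mediated DEL from an MC with one
repeat-flagged end plus a JC joining the interval's unique side to the
proximal end of any copy of that family. Remaining evidence is reported
unassigned; marginal junctions are written as evidence with a `marginal`
status. Inversions and compound events are deliberately not auto-resolved.

Genome Diff is the lossless output dialect (field orders documented in the
writer); `apply_mutations` regenerates a mutated genome from a GD — used
both to build simulations and to define mutation equivalence: two calls are
the same mutation iff applying either yields the same genome, which
absorbs the breakpoint-placement ambiguity created by homology at
junctions.

## Simulation

The generator mirrors the evaluation protocol the pipeline is benchmarked
under. The default base genome is a seeded uniform-random sequence
(configurable GC) carrying 10 identical copies of a 1,443-bp synthetic
IS-like element annotated as `mobile_element` — a stand-in for the IS
complement of a real enterobacterial chromosome. One SV class per genome:
unique-junction deletions of 400–1000 bp; new IS insertions copying a
randomly chosen existing element with a uniform 1–10 bp target-site
duplication; or IS-mediated deletions of 400–1000 bp extending from the
left or right margin (equal probability) of a randomly chosen copy, each
copy used at most once. Every affected site must lie ≥ 1,000 bases from
every other site and from every exact repeat ≥ 36 bp (enumerated with the
package's own maximal-repeat finder, forward and reverse-complement). The
truth GD records every event and the seed, and the emitted genome is
`apply_mutations(truth, ref)` by construction.

Reads start uniformly on both strands; lengths are fixed (36/50/100/200
are the benchmarked values) or Gaussian with SD 10% of the mean, truncated
at 18; substitution errors are i.i.d. at a configurable rate (default
0.1%, a typical short-read figure) with phred qualities reflecting that
rate. What this does *not* emulate: platform-specific error profiles
(homopolymer indels, quality decay along the read), GC or origin-distance
coverage bias, chimeric library artifacts, or paired ends. Passing tests
therefore demonstrate the algorithmic pipeline — candidate construction,
statistics, evidence integration — under idealized sampling, not
robustness to every real-world artifact.

## Problem sizes and numerics

The benchmark reproduction uses a 1-Mb genome with 100 deletions at
80-fold 50-base coverage (≈1.6 M reads, ~2 minutes end to end); the
per-class inversion checks use 400-kb genomes with 20 events at 40-fold.
These sizes keep the whole suite comfortably on a laptop while preserving
every constraint of the protocol (spacing, repeat avoidance, coverage
regime). Other numerical choices: score-threshold comparisons use a 1e-9
slack; equal-score placements are all reported (no sampling); candidate
evaluation breaks score ties lexicographically on the canonical
description; seeds with more than 64 placements are skipped during seeding
(the extension stage still finds repeat placements through their other
seeds); per-seed hash indexes are cached per seed length. Genome ends of
linear sequences legitimately ramp to zero coverage and may seed edge MC
items; they are reported as evidence and consumed by no rule.

## Known limitations

Three-or-more-way split reads are not considered. Junctions with both
sides repetitive are never auto-resolved. Tandem amplifications longer
than the read length, inversions, and IS-insertion-plus-adjacent-deletion
compounds are left as unassigned evidence for manual review. Copy-number
segmentation, polymorphism frequencies in mixed samples, and paired-end
discordance are out of scope. MOB margin-insertion orientation is
recovered by the apply-and-verify search and can fail for exotic
combinations of margins and strand, in which case the junction pair is
reported unassigned rather than guessed.
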