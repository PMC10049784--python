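# Methods

## Model overview

`haplodrop` simulates the transmission of a single chromosomal segment of
physical length `bp_len` (bp) and sex-specific genetic lengths `L_m`,
`L_f` (Morgans) from the founders of a fixed pedigree down to its
probands. No alleles are simulated: a haplotype is a tiling of
`[0, bp_len)` by half-open segments, each labelled with the founder
chromosome it descends from (`<founder>.1` = that founder's paternal
chromosome, `<founder>.2` = maternal, `0` = descended from a founder the
user chose not to track). Untracked material merges into anonymous `0`
runs, which keeps output small when only a few founders are of interest.

The pedigree model is two-parents-or-none. Records with exactly one known
parent are rejected with an explicit error rather than silently patched:
imputing a dummy spouse changes kinship and contribution values, so the
choice is left to the user's preprocessing. Founders are assumed mutually
unrelated and non-inbred; all kinship and contribution oracles and the
IBD expectations inherit that assumption.

## Meiosis models

All three models describe chiasmata on the four-strand bundle at intensity
2 per Morgan, resolved to the single transmitted product by independent
1/2 thinning (no chromatid interference); the product-scale crossover
intensity is therefore 1 per Morgan in every model.

- **poisson**: sampled directly at the product level — count ~
  Poisson(L), positions i.i.d. Uniform(0, L). Exactly equivalent to the
  thinned bundle description.
- **count_location**: bundle count ~ zero-truncated Poisson with
  untruncated mean 2L, guaranteeing the obligate chiasma at the bundle
  level (the product may still receive none). Truncation at the bundle
  rather than the product level is the only form in which "obligate
  chiasma" is biologically meaningful. Mean product count is
  L/(1 − e^(−2L)), noticeably above L only for short maps. Requires
  L > 0.
- **gamma**: stationary renewal process with Gamma(shape ν, rate 2ν per
  Morgan) inter-arrivals. The first event is drawn from the equilibrium
  (stationary-excess) distribution, whose closed-form CDF
  F_e(x) = 2x(1 − F_ν(x)) + F_{ν+1}(x) (F_k = Gamma(k, 2ν) CDF) is
  inverted numerically by safeguarded Newton iteration to ~1e-13 —
  exact stationarity, no burn-in approximation. ν = 1 reduces to the
  Poisson model; larger ν spreads crossovers apart, reducing count
  variance while stationarity pins the mean at L for every ν. A single ν
  is shared by both sexes.

Defaults used in the examples and acceptance computations: segment of
250 Mb and 250 cM (a large-human-chromosome scale), Poisson model unless
interference is the object of study, ν = 2.6 as a realistic
human-autosome interference strength when the gamma model is exercised.

## Genetic-to-physical conversion

Crossover locations are generated in Morgans and converted to integer bp
breakpoints. With no user map the relation is linear
(`bp = round(g/L · bp_len)`); a user map is a strictly monotone table of
(cM, bp) anchors, interpolated linearly between anchors (no spline — the
conservative choice absent calibration data), optionally one table per
parental sex. Rounding is half-away-from-zero; results are clamped to
`[1, bp_len − 1]`. If two crossovers collapse onto one bp after rounding
they annihilate in pairs (odd multiplicity leaves one breakpoint),
preserving the parity semantics of recombination at coarse physical
resolution. Missing endpoint anchors `(0, 0)` / `(total cM, bp_len)` are
synthesized with a logged warning; anchors that disagree with the
simulated lengths are an error.

Segments are half-open `[start, end)` over `[0, bp_len)`; a breakpoint at
bp x starts a new segment at x. Slot 1 is paternal and slot 2 maternal,
uniformly from founders to probands.

## Engine and determinism

The genealogy is pruned to the probands' ancestor closure before
simulation; the tracked-founder set is intersected with the remaining
founders. All pruned individuals are simulated even when they cannot
carry tracked material — pruning already bounds the work, and uniformity
keeps the all-node output complete for traceback. One seeded
`numpy.random.Generator` drives a run and is consumed in a fixed order
(replicate → topological order → father's meiosis before mother's →
crossover draws before the strand-choice coin), so identical inputs and
seed give byte-identical output files. Replicates are generated and
flushed one at a time; memory is independent of the replicate count.

## Traceback and concatenation

Because transmission copies intervals at fixed genomic coordinates, a
proband segment with label ℓ can be traced upward by locating ℓ at the
same coordinates in each successive ancestor. At an ancestor carrying ℓ
on both chromosomes (homozygous by descent) the true route is not
recoverable from haplotype records alone; the tracer resolves minimally:
if a single chromosome covers the whole traced interval, one route is
reported (ties broken toward the paternal chromosome), and the interval
is split across both routes only when neither chromosome alone explains
it. A segment is flagged *concatenated* exactly when this forces more
than one distinct founder-to-proband path — the conservative reading of a
multi-path descent event, so concatenation counts are lower bounds on
route ambiguity. In pedigrees where the founder has a single descent
route to every individual, concatenation is impossible and the tracer
never reports it.

## IBD comparison

For probands a and b, each replicate yields (i) `mean_pairwise`: the mean
over the four ordered haplotype pairs of the fraction of bp with equal
non-zero labels — its expectation is the kinship coefficient φ(a, b),
which makes it the statistically clean summary — and (ii) `union`: the
fraction of bp where at least one pair matches, closer to "proportion of
the diploid chromosome shared". Both are emitted. If untracked (`0`)
material is present the fractions are lower bounds and the result is
flagged.

## Genotype conversion

`convert_genotypes` assigns to each proband haplotype, at each marker of
a founder genotype table (`bp` column plus one haploid allele column per
founder-chromosome label), the allele of the founder chromosome whose
segment contains the marker; label-`0` regions emit the missing code
`"0"`. Phase (paternal | maternal) is preserved. Marker positions are
taken from the table; an optional argument restricts to a subset.

## Synthetic pedigrees

The fixture generator grows pedigrees generation by generation: fathers
are pedigree-born males (new founders when none remain), and each
couple's mother is, with probability `consanguinity_rate`, drawn from the
pedigree-born females (excluding the father's mother, daughters, and
full/half sisters — loops stay cousin-like, matching real
founder-population consanguinity; remarriage is allowed), otherwise a new
founder enters. Offspring counts are Poisson(`offspring_mean`, default
2.5, a growing-founder-population value). Rate 0 provably yields
kinship-0 matings; rate 1 raises an error only when no eligible
in-pedigree mate exists at all.

What the synthetic data do **not** emulate: real marker maps (maps are
linear unless supplied), hotspots, gene conversion, sex chromosomes,
mutation, selection, overlapping generations and age structure.
Passing tests therefore validate the transmission machinery and its
statistics, not demographic realism.

## Problem sizes and numerical choices

The acceptance computations use 25,000 replicates for the loop-pedigree
traceback experiment, 10^5 draws per crossover-model calibration, 10^4
replicates for IBD/contribution recovery, and 10^6 draws for the
obligate-chiasma check — sizes at which the 3-standard-error bands used
throughout are a few parts per thousand. Statistical unit tests run at
2–3·10^4 draws for speed; the full sizes live in the acceptance suite.
Equal-label adjacent segments are always merged on construction, making
haplotype equality well-defined; crossover positions are kept strictly
inside the open interval at both genetic and physical scales; L = 0 is a
supported degenerate case (intact chromosomes transmitted, Poisson model
only — the obligate-chiasma and renewal models are undefined on an empty
map).

## Known limitations

- One chromosome (segment) per invocation; no multi-chromosome batching.
- Founders cannot be declared related or inbred.
- Single interference parameter ν for both sexes.
- Concatenation detection is minimal-explanation (see above): replicates
  where both routes cover a segment entirely are counted as single-path.
- The output dialect is this package's own documented format; it is not
  byte-compatible with other simulators' files.
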