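# haplodrop

Gene-dropping simulation of recombinant haplotypes through large, possibly
consanguineous genealogies — plus companion analyses for retracing
transmission paths, measuring pairwise identity-by-descent (IBD), and
converting simulated segments into phased genotypes.

## The problem

Founder populations with deep genealogical records (tens to hundreds of
thousands of linked individuals) are a powerful setting for studying rare
recessive disease variants: affected individuals often carry the causal
mutation on long haplotypes that are homozygous by recent descent. To ask
questions like *"how much of this chromosome do two distant cousins expect
to share IBD?"* or *"through which ancestors could this segment have
descended from founder F?"*, one simulates transmission down the **fixed,
known pedigree** ("gene dropping"). Tracking alleles at every marker is
hopeless at that scale; tracking only **crossover breakpoints and the
founder chromosome of origin of each segment** makes whole-chromosome
simulation through arbitrarily deep genealogies cheap.

That is what `haplodrop` does. Each founder's two chromosomes are labelled
`<id>.1` (paternal) and `<id>.2` (maternal). Every non-founder, visited in
topological order, receives one recombinant meiotic product from each
parent; a proband's haplotype is then an ordered tiling of the simulated
segment `[0, bp_len)` by founder-chromosome labels.

## Meiosis models

Crossover locations for one meiotic product are generated on the genetic
scale (Morgans, sex-specific lengths L_m, L_f) under one of:

- **poisson** — no interference: count ~ Poisson(L), locations i.i.d.
  Uniform(0, L);
- **count_location** — obligate chiasma: bundle chiasma count ~
  zero-truncated Poisson(2L), uniform locations, each chiasma passed to the
  product with probability 1/2 (mean product count L / (1 − e^(−2L)));
- **gamma** — crossover interference: chiasmata form a stationary renewal
  process with Gamma(shape ν, rate 2ν per Morgan) inter-arrivals, thinned
  by 1/2; ν = 1 is exactly the Poisson model, ν ≈ 2.6 is a
  human-autosome-like interference strength.

Genetic positions are converted to physical bp either linearly or through
a user-supplied piecewise-linear (cM, bp) map, optionally sex-specific.

## Post-simulation analyses

- `traceback` — walks every founder-labelled proband segment back up the
  pedigree and reports its transmission path(s). In consanguineous loops a
  segment can be assembled from **multiple** paths joining at an ancestor
  homozygous by descent (a *concatenation*); these are detected and
  flagged, and they are markedly longer than single-path segments.
- `compare_ibd` — per replicate, the proportion of the diploid chromosome
  two probands share IBD: the mean over the 4 ordered haplotype pairs of
  the matching-label fraction (expectation = the kinship coefficient φ),
  plus the union fraction.
- `convert_genotypes` — projects proband haplotypes onto user-provided
  haploid founder genotypes, yielding phased marker data (e.g. to contrast
  identity by descent with identity by state).

Pedigree oracles (recursive kinship, Wright path-counting kinship,
expected genetic contribution Σ_paths (1/2)^meioses, exhaustive path
enumeration) are part of the public API and anchor the test suite.

## Worked example

Simulate a 250 Mb / 250 cM segment through a first-cousin-mating pedigree
(founder couple 1·2, their children 3 and 4 marry out, the first cousins 7
and 8 marry, 9 is their inbred child), tracking founder 1 only:

```
$ haplodrop simulate --pedigree cousins.tsv --probands 9 --founders 1 \
    --n-sim 3 --model poisson --cm-len-male 250 --cm-len-female 250 \
    --bp-len 250000000 --all-nodes --seed 42 --out sim_out
$ head -4 sim_out/Proband_Haplotypes.txt
# haplodrop bp_len=250000000 model=poisson
1;9;1;{0,70345973,1.2,73398439,0}
1;9;2;{1.2,5678018,0}
2;9;1;{1.2,75378022,1.1,82892249,0,109727865,1.2,130168101,0}
```

Each line is `sim;individual;slot;{label,boundary,label,...}`: in
replicate 1 the proband's paternal chromosome (slot 1) carries founder 1's
maternal chromosome (`1.2`) on [70,345,973, 73,398,439) bp and untracked
material (`0`) elsewhere. Retracing those segments:

```
$ haplodrop traceback --pedigree cousins.tsv \
    --all-nodes-file sim_out/All_nodes_haplotypes.txt --proband 9 --founder 1
sim	start	end	label	concatenated	n_paths	paths
1	70345973	73398439	1.2	0	1	1-3-7-9
1	0	5678018	1.2	0	1	1-4-8-9
2	0	75378022	1.2	0	1	1-3-7-9
...
```

The first segment descended through child 3 and grandchild 7, the second
through the other branch (4, then 8) — the two possible inheritance paths
in this pedigree. `concatenated` turns 1 when a single segment required
more than one path (possible only below an ancestor homozygous by
descent). The same analyses are available in Python via
`haplodrop.simulate`, `haplodrop.traceback`, `haplodrop.compare_ibd` and
`haplodrop.convert_genotypes`.

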