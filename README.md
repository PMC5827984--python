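# epiregion

Window-based calling of differential epigenomic regions from pooled
enrichment-sequencing coverage — DMRs (differential DNA-methylation
regions, MeDIP-seq) and DHRs (differential histone-retention regions,
histone ChIP-seq) — with a permutation null for the region count and
integration across epimutation types (DMRs, differential ncRNAs, DHRs).

It is written for analysts working on environmentally induced epigenetic
inheritance designs: two breeding lineages (control vs exposed), a few
pooled sequencing libraries per lineage per generation, and the question
of which genomic regions differ reproducibly between the lineages.

## Method

The reference genome is tiled into 100-bp windows and each sample's
aligned fragments are assigned to the window containing the fragment
midpoint (single-end reads are first extended to the 300-bp sonication
length from their 5′ end). Windows with fewer than 40 reads summed across
all samples are removed.

Per window, counts are modelled as negative binomial with a common
dispersion φ (Var = μ + φμ²), estimated by a debiased median-of-moments
rule across windows. After scaling to a common library size, pool counts
are collapsed to group sums *Y*<sub>A</sub>, *Y*<sub>B</sub>, and the
two-sided exact conditional test evaluates, given the window total
*t* = *Y*<sub>A</sub> + *Y*<sub>B</sub>,

  p = Σ { P(a | t) : P(a | t) ≤ P(Y<sub>A</sub> | t) },

with NB(size = n/φ) group-sum components; at φ = 0 this degenerates to the
binomial split test. Windows at p < 10⁻⁶ seed regions; region edges extend
while any retained window with p < 0.1 lies within 1000 bp of the
boundary, absorbing intervening windows, iterated to closure; touching
closures merge. Called regions are annotated with CpG count and density
per 100 bp and kb-length bins.

Significance of the region *count* is assessed by re-running the whole
pipeline under every balanced relabeling of the pools (10 splits for a
3-vs-3 design, so the smallest achievable empirical p is 0.1). Integration
utilities provide interval Venn overlaps between region sets, name-based
ncRNA overlaps, gene association within 10 kb, 100-kb multi-mark
co-localization, a Poisson scan for chromosomal region clusters, the
retained-histone genome fraction, sncRNA class tallies and sample PCA.

## Worked example

`examples/01_call_differential_regions.py` builds the default synthetic
benchmark — 50,000 windows, 3 control vs 3 exposed pools, NB counts at
mean 50 and dispersion 0.1, 100 planted 3-window regions at 4-fold
change — and calls regions:

```
windows tested: 50000 (0 removed by 40-read filter)
estimated dispersion phi: 0.0983 (simulated 0.1)
regions called at p<1e-6: 85 (41 with >=2 significant windows)
planted regions recovered: 85/100

region counts across seed thresholds (all vs multiple-window):
      seed_p  all_window  multiple_window
1.000000e-04         103               93
1.000000e-05          99               71
1.000000e-06          85               41
1.000000e-07          62               20
1.000000e-08          42                9
```

The dispersion estimate recovers the simulated φ; nearly every call
overlaps a planted region (the threshold ladder shows how calls tighten as
the seed p-value drops), and recovery of ~85/100 reflects per-window power
at p < 10⁻⁶: a 4-fold change at these depths sits near the detection
boundary of a 3-vs-3 pooled design. `examples/02_permutation_null.py`
shows the permutation test reaching its design-minimum empirical p of 0.1,
and `examples/03_multi_epimutation_integration.py` walks through the
cross-set analyses.

The same stages are scriptable from the shell:

```sh
epiregion --run-dir run --seed 0 simulate
epiregion --run-dir run --seed 0 count   # then: test, regions, permute, ...
```

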