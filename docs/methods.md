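# Methods

## Coordinate and count model

All coordinates are 0-based, half-open. BED is written unchanged; GFF3/GTF
(1-based inclusive) is converted on ingest. The genome is tiled left to
right into `window_size` (default 100 bp) windows; the trailing window of
a chromosome may be shorter and is kept — its counts are used unchanged.

Each usable aligned fragment contributes exactly one count, to the window
containing its midpoint `floor((start+end)/2)`; a midpoint on a window
boundary belongs to the right-hand window. Properly paired reads use the
pair span; other reads are extended to `fragment_length` (default 300 bp,
the sonication target) from the 5′ end in the strand direction. Unmapped,
secondary, supplementary and duplicate-flagged records are skipped;
duplicate flags are honored but no deduplication is performed. The
alternative — counting a fragment into every window it overlaps — inflates
totals by fragment_length/window_size and makes column sums
uninterpretable; midpoint assignment keeps column sums equal to library
sizes, which is what the low-coverage filter acts on. Windows with a
count total across all samples strictly below `min_total_reads` (default
40) are removed; library sizes are deliberately not recomputed afterwards.

## Differential test

Counts are negative binomial with a single genome-wide dispersion φ,
parameterized everywhere (simulation, estimation, testing) as
Var = μ + φμ², i.e. NB size r = 1/φ. Two conventions for φ exist in the
wild; fixing one in a single place avoids the classic mismatch.

Library-size normalization divides each sample by a factor proportional
to its total assigned fragments, rescaled to geometric mean 1. Normalized
counts are rounded to integer pseudo-counts and summed within groups;
pool-level variability enters through φ, not through a per-pool model.

φ is estimated by a median-of-moments rule: within each group every
window yields the moment ratio (s² − m)/m² on normalized counts, and the
median over windows is robust to the minority of genuinely differential
windows. With n = 3 replicates the ratio's median is badly biased — the
sample variance is approximately (μ + φμ²)·χ²₍ₙ₋₁₎/(n−1) and the
chi-square median is 0.693 of its mean at two degrees of freedom — so the
median ratio ρ is inverted through ρ ≈ cφ + (c−1)/m with
c = median(χ²₍ₙ₋₁₎)/(n−1), evaluated at the median window mean. Without
this correction the estimate runs ~30% low at n = 3 and the exact test
loses type-I control (measured: 3 rather than 0 windows below 10⁻⁶ among
50,000 nulls). Group estimates are averaged and clamped at zero, so
under-dispersed data fall back to the Poisson/binomial limit.

The per-window test is exact and conditional: group sums of iid NB
samples with common φ are NB with size n/φ and a shared success
probability, so given the window total t the distribution of the group-A
sum is free of μ. The two-sided p is the sum of conditional probabilities
of all splits whose probability does not exceed the observed one (ties
included, relative tolerance 1e-12), capped at 1; a zero-total window has
p = 1 by convention. At φ = 0 the conditional distribution is binomial
with proportion equal to group A's size fraction. The conditional pmf
depends only on t for fixed group sizes and φ, so it is cached across
windows; a 50,000-window test runs in about a second. This is a
calibrated exact NB test in the edgeR-classic family; bit-equivalence
with any external tool is not a goal — a uniform null and controlled
type-I error are.

Because the test is discrete, its null p distribution carries an atom at
p = 1 equal to the probability that the observed split is the conditional
mode (~0.03 at 300-count totals). The CDF elsewhere tracks the uniform
from below to ~1e-4. Consumers of "approximately uniform" should read it
one-sidedly: small p-values are never inflated; the conservative mass
sits harmlessly at 1.

FDR is Benjamini–Hochberg (statsmodels), reported alongside raw-p
thresholds.

## Region calling

Windows at p < `seed_p` (default 10⁻⁶) seed regions. Edges extend while
any retained window with p < `extension_p` (default 0.1) lies within
`extension_gap` (default 1000 bp) of the boundary, measured edge-to-edge
(distance 0 when overlapping or adjacent; a window exactly at the gap
joins). Extension absorbs every intervening window regardless of its p,
iterates to closure, and merges touching closures, so the result is
independent of processing order. Because the boundary moves as windows
join, chaining is transitive; the final regions are exactly the
single-linkage chains (at the gap) of sub-threshold windows containing at
least one seed, which is how the caller computes them (the test suite
verifies interval-identity against a literal fixed-point re-scanner).
Filtered (low-coverage) windows are invisible to extension, but a
region's span is reported as one contiguous interval, so their genomic
footprint can be absorbed. A region is "multiple-window" when at least
two of its windows individually pass the seed threshold.

Features per region: CpG count (CG dinucleotides fully inside the span; N
never matches; counting is strand-symmetric because CpG is its own
reverse complement), density per 100 bp, and length bin ceil(length/1 kb).
Density histograms round half-up to integer bins.

## Permutation null

All C(2n, n)/2 distinct unordered balanced relabelings are enumerated
(10 at n = 3); the full pipeline — dispersion re-estimation, exact test,
region calling — is re-run per split. Re-estimating φ under each
relabeling is the honest null (signal windows inflate the permuted-null
dispersion, as they should); a `freeze_dispersion` flag reuses the
identity estimate instead. The empirical p is (1 + #{null ≥ observed}) /
(1 + #null), so a 3-vs-3 design bottoms out at 0.1. Beyond
`max_exhaustive` splits (default 200) a seeded Monte-Carlo subset is
used.

## Integration

- Interval Venn: two regions overlap iff they share ≥1 bp on the same
  chromosome. Every region is counted once, in the cell of its full
  overlap pattern; because overlaps can be many-to-one, each cell reports
  a count per member set and pairwise intersections are reported from
  both sets' perspectives.
- ncRNA overlaps are exact string matches on whitespace-trimmed names,
  case preserved; duplicates within a table are deduplicated with a
  warning. Rows with unknown location are kept for name operations and
  excluded from interval operations.
- Gene association: edge-to-edge distance between region and gene span ≤
  `gene_proximity` (default 10 kb), strand ignored; unassociated regions
  are reported as intergenic.
- Co-localization: feature midpoints on a chromosome are single-linkage
  clustered at `coloc_window` (default 100 kb); clusters drawing from ≥2
  distinct feature sets become sites. Single linkage can chain a cluster
  beyond one window span; sites report their actual span.
- Cluster scan: sliding windows (default 2 Mb, step 100 kb) scored by
  region-midpoint counts against a Poisson upper tail at the genome-wide
  rate; overlapping flagged windows merge. The scan method is this
  package's own construction — the underlying study design only displays
  clusters — and its parameters are configurable.
- Retention fraction: 100 × (union bp of the supplied intervals) /
  (genome bp). The interval source (called DHRs, a coverage-threshold
  track, external peak calls) is the caller's choice; the statistic is
  agnostic to it.
- Sample PCA: log2(CPM+1), windows centered, SVD; sample coordinates are
  the unit right-singular vectors (hence invariant to duplicating
  windows) with variance-explained ratios alongside; each component's
  sign makes its largest-magnitude coordinate positive.

## Synthetic data

The generator reproduces the study conditions the pipeline targets: a
3-vs-3 pooled design; per-window NB counts (default μ = 50, φ = 0.1)
with planted multi-window regions (default 100 regions × 3 windows at
fold change 4, placed non-overlapping with a 20-window buffer); a
CpG-desert genome (default 5 chromosomes × 1 Mb = 50,000 windows) built
as an A/T background with whole CG dinucleotides placed at Poisson rate
`cpg_rate` (default 1 per 100 bp) — placing whole dinucleotides on a
C/G-free background makes the realized rate exactly the planted one;
toy non-overlapping gene annotations; and ncRNA tables with named,
classed features, a signal fraction far below the 10⁻⁴ integration
threshold and a configurable unknown-location fraction. Counts can be
emitted as sorted fragment BED files whose midpoint counting reproduces
the count matrix exactly, so the counting stage is exercised end to end.
Everything is deterministic under its seed.

What the generator does not emulate — CpG-coupled enrichment bias,
mappability, GC effects, correlated windows, library-size imbalance
beyond sampling noise — bounds what green tests show: they certify the
statistics and interval algebra under the stated model, not robustness to
real MeDIP/ChIP artifacts.

At the default conditions the per-window power of the exact test at
p < 10⁻⁶ for a 4-fold change is ≈0.5, so a 3-window planted region is
recovered with probability ≈0.87 — an intrinsic property of the
conditions, not an implementation ceiling (a 5-fold change is recovered
≈99% of the time). Essentially all multiple-window calls overlap truth.

## Problem sizes and runtime

The benchmark grid is 50,000 windows (5 × 1 Mb); the permutation analyses
run on a 5,000-window grid (10 full pipeline re-runs); the end-to-end
fragment-level smoke chain uses 2 × 200 kb with ~1.2 M fragments. The
full test suite completes in well under a minute on one CPU; the
acceptance script in a few seconds.

## Known limitations

- One genome-wide dispersion; no tagwise shrinkage, GLM covariates or
  batch terms.
- Normalization is library-size only (no CpG-coupling or TMM-style
  composition correction).
- Exact-test p-values are discrete: conservative mass accumulates at
  p = 1 (see above); with 3 + 3 pools the permutation p cannot go below
  0.1.
- The cluster scan's Poisson null ignores region-length variation, and
  co-localization uses midpoints, so very long regions are represented by
  a point.
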