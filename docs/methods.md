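# Methods

This note records the models and procedures `seriesbin` implements, the
defaults that matter and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Feature construction

Each binnable scaffold (strictly longer than 8 kb, the conventional gate
below which composition signals are too noisy) is represented by two
concatenated blocks.

**Coverage block.** Raw fold coverages are first *size-normalized*: every
sample column is divided by its column sum and multiplied by the mean
column sum, equalizing per-sample totals while keeping values on a
fold-coverage-like scale. (This makes the normalized table unique only up
to a global factor — rescaling one sample's sequencing depth rescales the
equalization target — which is harmless because the downstream per-row
scaling removes the factor.) Each scaffold's normalized series is then
rescaled to unit sum, so the block encodes only the *shape* of the
abundance series, not its level.

**Tetra block.** Overlapping 4-mer frequencies counted on the given strand
only, 256 columns in lexicographic order (no reverse-complement collapsing,
which would give 136). Windows containing a non-ACGT symbol are skipped;
counts are divided by the number of valid windows, so the block also sums
to one per row.

**Block weights.** With both blocks on unit row sums their *signal-to-noise
ratios* are far from equal: per-scaffold coverage is overdispersed
(negative-binomial, coefficient of variation ≈ √dispersion ≈ 45 % at the
default dispersion 0.2), giving a per-row coverage noise magnitude (~0.14
in L2) roughly sixteen times the 4-mer sampling noise of a >8 kb scaffold
(~0.009). The feature builder's neutral default is `(1, 1)`, but the
binning pipeline defaults to `(0.1, 1)` — down-weighting coverage so the
two blocks contribute comparable *noise* — which measured decisive for
genome recovery (adjusted Rand index ~0 at `(1, 1)` versus 1.0 at
`(0.1, 1)` on 20-genome communities). Both weights are exposed in the
configuration; per-column z-scoring is available as a switch (off by
default).

## ESOM binning

**Training.** Batch SOM on a toroidal rows × cols grid: per epoch, every
row is assigned to its best matching unit (BMU), then each neuron is set to
the Gaussian-neighborhood-weighted mean of all rows,
`w_k = Σᵢ h(bmuᵢ,k) xᵢ / Σᵢ h`, with kernel `h = exp(−d²/2σ²)` on toroidal
Euclidean grid distance. σ decays linearly from half the larger grid
dimension to 1.0 over 20 epochs. Weights are initialized by seeded sampling
of training rows; training is fully deterministic given the seed. At σ = 0
the kernel degenerates to an indicator and one epoch is exactly one Lloyd
k-means step — the property the test suite uses to anchor the update
against an independent implementation.

**Grid sizing.** The emergent regime needs many more neurons than clusters:
each genome territory must span dozens of cells and be separated from its
neighbors by interpolation zones whose high U-matrix values form *closed*
ridges. The default is ≈2 neurons per training row (clamped to
[100, 4096]), aspect 1:1.6. The classical ≈5√n heuristic was tried first
and fails structurally here: with 216 neurons for ~1 860 scaffolds the 20
territories touch directly, no ridge separates them, and all valleys merge
into one component even when every neuron is pure. Measured territory
sizes suggest ≥50 neurons per expected genome as a practical floor when
overriding the grid.

**Delineation.** U-matrix cells below the 0.6 quantile of all U values are
valley cells; toroidal 8-connected components of valley cells are candidate
bins; every scaffold inherits its BMU's component; scaffolds whose BMU is a
ridge cell, or whose component attracts fewer than 5 scaffolds, stay
UNBINNED. The 0.6 quantile is deliberately conservative: raising it to 0.7
lowers the unbinned fraction (~0.20 vs ~0.34 at the 20-genome scale) but
proved fragile on mid-sized maps, where the thinner ridges leak and merge
territories; 0.8 collapses the partition entirely. Automated
valley-component delineation replaces interactive polygon curation of the
map; the consequence — a fifth to a third of scaffolds stranded on ridges —
is visible downstream as bins whose marker completeness undershoots the
fraction of the genome actually resolved. Misassignments that do occur are
left to the QC stage, which evicts outliers rather than redrawing bins.

**Quantization error.** The model records mean row-to-BMU distance before
and after training. With a vanishing final radius (σ_end ≲ 0.3) training
cannot worsen it and the suite asserts exactly that; with the default
σ_end = 1 batch SOM minimizes a neighborhood-smoothed energy instead, and
since sampled-row initialization starts at near-zero quantization error on
neuron-rich grids, the raw error may legitimately rise while the map
organizes.

## Bin quality control

Completeness = distinct single-copy markers present on member scaffolds /
marker-set size (51 bacterial, 38 archaeal; the shipped identifiers are
placeholders with the canonical cardinalities and can be swapped by
configuration). Duplication fraction = markers with ≥2 copies / set size.
Draft quality requires completeness ≥ 0.70 and duplication ≤ 0.10; the cap
is permissive because genes split across scaffold ends legitimately count
twice. If the domain is unspecified both sets are scored and the higher
completeness wins, ties to bacteria.

Contaminant flags: |value − bin median| > 3.5 × MAD (the conventional
robust-outlier fence) on GC or mean normalized coverage — dimensions with
zero MAD are skipped — plus taxon votes conflicting with a strict (>50 %)
majority. Bins with fewer than 4 members are never flagged (no robust
statistics at that size). Refinement moves flagged scaffolds to UNBINNED
and preserves the partition.

## rpS3 profiling

Greedy centroid clustering, longest sequence first; each query is globally
aligned to existing centroids in creation order with BLOSUM62 scoring,
affine gaps (open 11, extend 1) and free end gaps. Identity = matches /
aligned columns between the first and last column where both sequences are
present (internal gaps count against identity); span = those columns /
total alignment columns. A query joins the first centroid with identity
≥ 0.99 and span ≥ 0.60; queries that reach identity only over insufficient
span (short fragments) are excluded; everything else founds a centroid.
Thresholds follow the species-level convention for this marker; the
amino-acid alphabet is the default (nucleotide clustering would need its
own scoring and is not provided).

Cluster abundance in a sample is the summed normalized coverage of the
scaffolds carrying its member sequences, rescaled to percent per sample;
phylum rollups sum species within a phylum and preserve column totals.
Bray–Curtis is computed from the percent table; it is a semimetric
(triangle-inequality violations allowed), so PCoA may produce negative
eigenvalues, which are dropped and reported. PCoA is classical scaling:
eigendecomposition of −½·J·D²·J, coordinates = eigenvectors × √eigenvalue,
proportions relative to the positive-eigenvalue total.

## Group statistics

One-way ANOVA by the standard between/within decomposition. Degenerate
inputs are defined explicitly: no variance at all → F = 0, p = 1; zero
within-group variance with real between-group differences → p = 0 with a
degenerate flag. BH adjustment is the step-up rule
`q_(i) = min_{j≥i} p_(j)·m/j` clipped at 1, applied across all analytes'
ANOVA p-values. Tukey HSD uses the Tukey–Kramer statistic
`q = |m̄ᵢ−m̄ⱼ| / √(MSW(1/nᵢ+1/nⱼ)/2)` with p-values from
`scipy.stats.studentized_range`; pairwise comparisons are per analyte and
not further corrected across analytes by default (a switch applies BH to
them as well). The empirical-FDR simulation (1 000 analytes, 90 % null,
10 % with a 3-SD shift in one of three triplicate groups, 50 seeds) yields
very few discoveries per seed (~5–10), so the realized
false-discovery-proportion estimate carries visible sampling noise around
the theoretical 0.045 level; the suite allows 0.07.

## Synthetic community generator

What it emulates: genomes as order-3 Markov chains whose 64 × 4 transition
rows carry seeded Gaussian log-perturbations (scale 0.6), giving each
genome a separable tetranucleotide signature; every row is rescaled so its
G+C mass equals the genome's GC target exactly, pinning genome GC while
leaving the A/T and C/G splits genome-specific. Abundances: per genome a
base log-level (sd 0.6), a depth loading (standard normal) multiplied by
the depth effect (default 1.0 on the natural-log scale) and the sample's
depth sign, plus per-sample series variation of log-sd 0.8 — chosen to
mirror the order-of-magnitude abundance swings and rank changes organisms
show across a rain-perturbed sampling series, which is precisely the
signal series-coverage binning relies on. The default ten-sample layout is
six shallow + four deep samples across four sampling days with two plot
replicates. Coverage: negative-binomial read counts (dispersion 0.2,
variance m + 0.2 m²) converted to fold coverage; per-sample depth factors
lognormal (sd 0.15) emulate sequencing-yield differences, undone by the
normalization stage. Scaffolds: sequential log-normal fragments (median
12 kb, log-sd 0.45, minimum 1 kb; defaults give ≈90–100 scaffolds >8 kb
per 1.5 Mb genome). Markers: the full 51- or 38-member set planted once
each on uniformly random scaffolds (per scaffold, not per bp — so ~18 % of
markers land on sub-8 kb scaffolds and are invisible to binning, which
bounds attainable bin completeness below 1). rpS3: one locus per genome;
220-aa sequences mutated from a per-taxon base at divergence 0.05.

What it does not emulate: read-level artifacts, assembly chimeras and
gaps, strain-level microheterogeneity, GC-dependent coverage bias,
inter-sample batch structure beyond the depth factors. Passing recovery
tests therefore demonstrates the pipeline's correctness and its behavior
under realistic noise magnitudes, not performance on real assemblies,
where fragmented strain mixtures blur both signatures.

## Problem sizes used in tests and the reproduction script

Binning recovery runs 20 genomes × 1.5 Mb × 10 samples (≈1 850 binnable
scaffolds) over five seeds — the scale at which the emergent map regime is
exercised. Depth-structure recovery runs the full profiling chain on 50
seeded communities of 20 × 60 kb genomes (binning is uninvolved, so short
genomes suffice). The FDR study uses 50 seeds × 1 000 analytes. These sizes
keep a full run in the low minutes on one CPU while leaving every
statistical conclusion comfortably away from its threshold.

## Known limitations

* Bin delineation quality degrades when genome territories receive fewer
  than ~50 neurons; override the grid for unusually large communities.
* The coverage block weight is a fixed default, not estimated from the
  data; communities with weak compositional separation but strong series
  separation may warrant raising it.
* Marker identities are placeholders; real annotations should supply the
  project's single-copy gene catalogue with the same cardinalities.
* The rpS3 aligner scores amino acids only, and cluster membership depends
  on processing order in the rare case of chained near-threshold identity.
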