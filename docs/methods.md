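# Methods

`symbiopop` analyses strain-level population structure of horizontally
transmitted bacterial symbionts from pooled per-host metagenome allele
counts, and ships a synthetic generator that emulates a deep-sea mussel
hybrid-zone sampling design on a mid-ocean-ridge transect. This note
documents the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic data can and cannot show.

## Statistical model and procedures

### Pool-seq allele frequencies

Each sample is one host's symbiont population sequenced as a pool; the read
counts at a biallelic site estimate the within-host allele frequency, and
read depth plays the role of sample size. `variants.call_snps` keeps a site
when its pooled minor-allele frequency (over cells at depth ≥ `min_depth`)
is ≥ `min_maf` and at least `min_sample_fraction` of samples reach
`min_depth` there. Defaults `min_depth=5`, `min_maf=0.02`,
`min_sample_fraction=0.8` are conservative pool-seq practice; all three are
exposed in the run configuration. Computing the pooled MAF over qualifying
cells only makes filtering exactly idempotent. Cells below `min_depth` are
missing, never imputed, except in ordination (below).

### Hudson F_ST, ratio of averages

Per site, with frequencies p₁, p₂ at depths n₁, n₂ ≥ 2:

    N = (p₁ − p₂)² − p₁(1 − p₁)/(n₁ − 1) − p₂(1 − p₂)/(n₂ − 1)
    D = p₁(1 − p₂) + p₂(1 − p₁)

Gene and genome-wide estimates are ΣN/ΣD over usable sites — the ratio of
averages, which is far less biased than averaging per-site ratios when many
sites carry little diversity. The Hudson form was chosen because it is
robust to unequal (read-depth) sample sizes, the norm for metagenome-derived
frequencies. Sites with depth < 2 in either pool are excluded from that pair
(the correction divides by n − 1); sites with D = 0 are uninformative and
skipped. Genome-wide estimates can be slightly negative for near-identical
pools; the reported matrix floors them at 0 (display convention) while raw
values are kept for statistics.

### Consensus ANI

The per-host consensus is the majority allele at each called site (exact
ties call the reference). ANI between two hosts is computed over the whole
gene catalogue: invariant positions count as matches, positions uncalled in
either sample are removed from the denominator. This matches whole-genome
ANI semantics, where percentages like 99.7% refer to total aligned length,
not to SNP sites only.

### Host genetics

Hosts are genotyped at 18 species-diagnostic markers as dosages 0/1/2 of the
northern-species allele. Pairwise host distance is the allele-sharing
distance d = 1 − (shared alleles)/(2·jointly typed markers); it tolerates
missing data but is not guaranteed metric (no triangle inequality), which
nothing downstream requires. The hybrid index is Σdosage/(2·typed). The
sampling-year distance is binary because only two collection years exist in
the emulated design.

### Association tests

* **Mantel**: Pearson correlation of upper-triangle entries with joint
  row/column permutation of the second matrix, p with the +1 correction.
  Default 9999 permutations, one-tailed "greater" (positive association is
  the alternative of interest); two-sided is available.
* **Per-gene F_ST contrast**: per gene, pair values split into
  between-class (hybrid–parental) and within-class sets, two-sided
  Mann-Whitney U (normal approximation with tie correction), BH across
  genes. Pairwise values are not independent; the test is the conventional
  screen and is implemented literally, with this caveat.
* **CLR differential abundance**: per Monte-Carlo instance, per-sample gene
  proportions ~ Dirichlet(counts + 0.5), centred log-ratio transform,
  Kruskal-Wallis per gene; the reported p is the expectation over
  `n_mc=128` instances (prior and instance count follow the common
  compositional-analysis convention), then BH. For two groups the
  Kruskal-Wallis test is the two-group rank contrast, so no separate linear
  model branch is needed.
* **Presence/absence**: two-sided Fisher exact per gene; genes present or
  absent everywhere are non-testable and recorded as such.

### RDA and variation partitioning

RDA is multivariate least squares of the column-centred response (allele
frequencies, per-site mean-imputed for missing cells only here) on a centred
full-rank design; R² = SS(fitted)/SS(total), adjusted R² is Ezekiel's
1 − (1 − R²)(n − 1)/(n − m − 1), and significance comes from free row
permutation of the response using the pseudo-F statistic (1000 permutations
by default, p-resolution 1/1001). Rank-deficient designs are an error that
names the collinear columns; mere correlation never drops anything.

Variation partitioning fits all 15 non-empty subsets of the four blocks and
solves the inclusion–exclusion system for the 15 exclusive fractions plus
residual (they sum to 1 by construction; negative fractions are legitimate
by-products of the adjustment and reported as-is). Two summaries are
reported per block: the unique ("solely explained") fraction
adjR²(all) − adjR²(others), and the "with interactions" total, which equals
the block's marginal adjusted R². Per-block p-values test the unique
fraction with a partial pseudo-F under free response permutation.

Geography enters as a single along-ridge coordinate: cumulative great-circle
(haversine) distance along the latitude-ordered vent chain. The ridge is
essentially a north–south line, so one coordinate captures position;
distance-based eigenvector encodings were considered and rejected as the
default because they add free dimensions that absorb variance from the
other, low-dimensional blocks. Host class enters as indicator column(s),
vent type as basalt=0/ultramafic=1, depth in metres. Blocks that are
constant (e.g. geography with one vent) are flagged non-testable; blocks
fully aliased by earlier blocks (e.g. depth when only two vents are
sampled) are excluded from partitioning with a warning.

### NMDS

Kruskal stress-1 is minimised by SMACOF majorization: isotonic regression
of configuration distances on the dissimilarity ranks gives disparities
(rescaled to the configuration's sum of squares), followed by a Guttman
transform. The first restart starts from classical scaling, the rest from
seeded Gaussian noise; the best of `n_restarts=4` is returned. The recorded
stress path is non-increasing within a restart (a numerical guard rejects
any up-step and stops). Ties in the dissimilarities are handled by the
isotonic fit's pooling.

## Synthetic data generator

The generator emulates the study design the pipeline is built for: ~30
pooled host metagenomes, 13 parental and 17 hybrid hosts, up to 16 symbiont
strains per host, hundreds of orthologous genes, one to six vent fields on
a near-linear ridge transect with two collection years.

* **Pools**: vents are ordered by latitude as a 1-D stepping-stone chain.
  Each SNP site has a pool-major allele that flips between adjacent vents
  with probability `regional_divergence` (default 0.1). A shared set of
  per-strain deviations (probability `within_pool_maf=0.2` per site) is
  applied to every vent's majors, so zero divergence yields literally
  identical pools — the null of geographic structure. With
  `pool_structure="vent_type"` the pool is tied to rock type instead,
  decoupling community differences from distance.
* **Hosts**: strain proportions ~ Dirichlet(α·w), α = 1. Under the null,
  w is uniform. Hybrids with `host_effect` > 0 are tilted toward a fixed
  half of the strains by exp(host_effect · q), with q the host's admixture
  proportion — one scalar controls detectability, and hosts with similar
  admixture get similar symbionts, which is what a host-genetic driver
  would produce.
* **Reads**: per site per host, depth ~ Poisson(`mean_depth`=50), alt
  count ~ Binomial(depth, mixture frequency). Sites are independent (no
  within-gene linkage) because every downstream statistic used here is
  site-frequency-based. Gene coverage counts follow a class-independent
  compositional null (lognormal gene baselines, Poisson counts, 2% random
  dropout).
* **Host genotypes**: parentals are homozygous dosage 0 at all 18 markers;
  hybrids draw q ~ U(0.25, 0.75) (the F2–F4 range without explicit
  pedigrees) and dosage ~ Binomial(2, q).

The `paper_null` scenario distributes the 13 + 17 hosts across the six-vent
transect with classes balanced within vents, so the host-class contrasts
stay null while geography structures the pools — the same dataset then
exercises the null gene screens, the Mantel tests, and the variation
partitioning. `host_driven` places all 30 hosts at the hybrid-zone vent
with host_effect = 8 (a strong preference regime, chosen so the scenario is
unambiguously host-driven). Depth and SNP density of real symbiont
metagenomes are not published for this design; `mean_depth=50` and 10 SNP
sites per gene (2000 sites over 200 genes, scaled down from ~2500 genes)
are declared stand-ins, not calibrated values.

**What passing tests show — and not.** The generator reproduces the
statistical skeleton of the study (pool structure, mixture sampling noise,
class design); it does not simulate reads, assembly, binning, within-gene
linkage, multi-allelic sites, or the methane-oxidising co-symbiont.
Recovery of the null on synthetic data therefore certifies the inference
machinery, not the upstream bioinformatics.

## Numerical choices and degenerate inputs

* Permutation and Monte-Carlo p-values all use the +1 correction and
  explicit `numpy` generators seeded from the run seed; identical
  configuration + seed is byte-identical output.
* Exact consensus ties call the reference allele; pairs with no usable
  F_ST site, zero jointly covered ANI length, or no jointly typed marker
  raise errors naming the pair; genes with no usable site for a pair are
  absent rows, not zeros.
* Problem sizes in the test and acceptance runs (200 genes × 10 sites, 20
  replicate seeds, 999 permutations) were chosen so the whole suite
  completes in minutes on one core while keeping every check's Monte-Carlo
  error well inside its asserted margin.

## Known limitations

* The per-gene Mann-Whitney screen treats non-independent pairwise values
  as a sample; its p-values are calibrated only in the sense the original
  analysis used them (a conservative screen expected to find nothing under
  the null).
* The allele-sharing host distance and the binary year distance are
  declared substitutes; any distance can be plugged into the Mantel layer.
* ANI is consensus-based; alignment-based ANI on assembled genomes may
  differ where assemblies disagree on gene content.
* The along-ridge geography encoding is low-dimensional by design; with
  strongly non-linear spatial structure a distance-eigenvector encoding
  would be more appropriate.
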