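# symbiopop

Strain-level population structure of horizontally transmitted bacterial
symbionts, from pooled per-host metagenome allele counts.

Deep-sea *Bathymodiolus* mussels house sulphur-oxidising gammaproteobacterial
symbionts taken up from the environment, with many co-occurring strains per
host. Where two mussel species meet and hybridise, an obvious question is
what structures each host's symbiont strain community: the host's genotype,
geographic location along the ridge, or the vent environment. `symbiopop`
implements the statistical machinery to answer that question from
metagenome-derived SNP allele frequencies, for anyone working with pooled
host-associated microbial populations:

* **Differentiation** — Hudson F_ST between per-host symbiont populations,
  pooled as a ratio of averages, N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) −
  p₂(1−p₂)/(n₂−1), D = p₁(1−p₂) + p₂(1−p₁), F_ST = ΣN/ΣD, with read depth
  as sample size; plus consensus-based average nucleotide identity (ANI)
  over the whole gene catalogue.
* **Host association** — Mantel permutation tests of symbiont distance
  (F_ST or 100−ANI) against host genetic distance (allele-sharing over 18
  species-diagnostic markers) and sampling year; per-gene between- vs
  within-class Mann-Whitney F_ST contrasts; Dirichlet-CLR differential gene
  abundance; Fisher presence/absence tests; all BH-corrected.
* **Drivers** — redundancy analysis (RDA) of allele frequencies on
  geography, water depth, host class and vent rock type, with adjusted-R²
  variation partitioning over all 15 block combinations and permutation
  p-values; NMDS (Kruskal stress-1) for visual structure.
* **Synthetic data** — a generator of strain-structured symbiont
  metagenomes with known ground truth: stepping-stone strain pools along a
  vent chain, Dirichlet strain mixtures per host, binomial read sampling,
  and named scenarios (`paper_null`, `host_driven`, `environment_driven`).

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import numpy as np
from symbiopop import (scenario_library, simulate_dataset, call_snps,
                       consensus_alleles, pairwise_fst_matrix, pairwise_ani,
                       host_distance, mantel, fst_between_within_test,
                       varpart4, build_predictors)

cfg = scenario_library("paper_null")   # 30 hosts (13 parental, 17 hybrid),
cfg.mc_seed = 1                        # 6 vents, no host effect
ds = simulate_dataset(cfg)

freqs = call_snps(ds.counts, min_depth=5, min_maf=0.02, min_sample_fraction=0.8)
fst = pairwise_fst_matrix(freqs)
ani = pairwise_ani(consensus_alleles(freqs), ds.gene_catalogue)

iu = np.triu_indices(len(ds.metadata), 1)
print(f"median ANI: {np.median(ani.ani.to_numpy()[iu]):.2f}%")

m = mantel(fst.matrix, host_distance(ds.host_genotypes), n_perm=999, seed=7)
print(f"Mantel F_ST vs host distance: r = {m.r:+.3f}, p = {m.p:.3f}")

genes = fst_between_within_test(fst.gene_table, ds.metadata["host_class"])
print(f"genes with q < 0.05: {int(genes['significant'].sum())} of {int(genes['tested'].sum())}")

vp = varpart4(freqs, build_predictors(ds.metadata).blocks, n_perm=0)
print(f"unique variation, geography: {100 * vp.unique['geography']:.1f}%")
print(f"total explained (adj. R2):   {100 * vp.total_adj_r2:.1f}%")
```

prints

```
median ANI: 99.76%
Mantel F_ST vs host distance: r = -0.078, p = 0.959
genes with q < 0.05: 0 of 200
unique variation, geography: 22.0%
total explained (adj. R2):   60.7%
```

Read: symbiont genomes within and between hosts are nearly identical
(median ANI ≈ 99.8%), symbiont differentiation carries no signal of host
genotype (Mantel non-significant; no gene survives BH correction), and
geographic position along the ridge owns the largest uniquely attributable
share of allele-frequency variation — the expected outcome for this
scenario, where the free-living strain pool is geographically structured
and host genetics plays no role.

## Command line

The same pipeline is available as a CLI:

```sh
symbiopop simulate --scenario paper_null --seed 1 --outdir data/
symbiopop validate --input data/
symbiopop run-all --input data/ --seed 1 --outdir run/
```

`run-all` writes the full bundle (ANI and F_ST matrices, per-gene F_ST
table, four Mantel tests, gene test tables, NMDS coordinates, variation
partitioning, and a manifest with seeds and artifact digests; reruns are
byte-identical). Individual stages are exposed as `snps`, `fst`, `ani`,
`mantel`, `genetests`, `ordinate` and `varpart`.

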