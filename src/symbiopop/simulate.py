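"""Synthetic strain-structured symbiont metagenome datasets with known truth.

The generator emulates the sampling design of a deep-sea mussel hybrid-zone
study on the Mid-Atlantic Ridge: ~30 pooled host metagenomes from one to six
hydrothermal vent fields, each host carrying a mixture of up to 16
sulphur-oxidising symbiont strains drawn from a geographically structured
free-living pool.

Model
-----
* Vents are ordered by latitude (north to south) and form a 1-D
  stepping-stone chain.  Every SNP site has a pool-major allele; between
  adjacent vents the major allele flips with probability
  ``regional_divergence``.  With ``pool_structure="vent_type"`` the pool is
  instead shared by all vents of the same rock type (basalt vs ultramafic),
  decoupling divergence from distance.
* Each vent pool holds ``n_strains`` strains whose alleles deviate from the
  pool major independently per site with probability ``within_pool_maf``;
  the deviation pattern is shared across vents (a common ancestral strain
  set), so vents whose major alleles coincide carry identical pools.
* Each host receives strain proportions from Dirichlet(alpha * w).  Under
  the null (``host_effect = 0``) the tilt ``w`` is uniform; hybrids with
  ``host_effect > 0`` are exponentially tilted toward a fixed "preferred"
  half of the strains, with strength scaled by their admixture proportion.
* Observed data: per site per host, depth ~ Poisson(mean_depth) and the
  alternate-allele read count ~ Binomial(depth, mixture allele frequency).
  Sites are independent (no within-gene linkage).
* Host genotypes at 18 species-diagnostic markers: parentals are fixed
  homozygous (dosage 0); hybrids draw an admixture proportion q uniform on
  [0.25, 0.75] (mimicking F2-F4 classes) and marker dosage ~ Binomial(2, q).

Identical ``mc_seed`` and configuration give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .datatypes import (SITE_COLUMNS, AlleleCountMatrix, Dataset,
                        ValidationError, _check)

N_DIAGNOSTIC_MARKERS = 18
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Vent:
    """A hydrothermal vent field on the ridge transect."""

    name: str
    lat: float
    lon: float
    depth_m: float
    vent_type: str  # "basalt" | "ultramafic"


# Northern MAR transect, north to south.  Depth increases along the ridge
# (the southernmost vent breaks the trend), making the predictors collinear.
NORTHERN_MAR_VENTS = (
    Vent("MenezGwen", 37.84, -31.52, 850.0, "basalt"),
    Vent("LuckyStrike", 37.29, -32.28, 1700.0, "basalt"),
    Vent("Rainbow", 36.23, -33.90, 2300.0, "ultramafic"),
    Vent("BrokenSpur", 29.17, -43.17, 3050.0, "basalt"),
    Vent("Logatchev", 14.75, -44.98, 3050.0, "ultramafic"),
    Vent("Semenov", 13.51, -44.96, 2320.0, "ultramafic"),
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give the six-vent null scenario."""

    vents: tuple[Vent, ...] = NORTHERN_MAR_VENTS
    n_parental_per_vent: tuple[int, ...] = (2, 2, 2, 2, 2, 3)
    n_hybrid_per_vent: tuple[int, ...] = (3, 3, 3, 3, 3, 2)
    n_strains: int = 16
    n_genes: int = 200
    mean_gene_length: int = 900
    n_snp_sites: int = 2000
    regional_divergence: float = 0.1
    within_pool_maf: float = 0.2
    host_effect: float = 0.0
    dirichlet_alpha: float = 1.0
    mean_depth: float = 50.0
    gene_dropout: float = 0.02
    pool_structure: str = "distance"  # or "vent_type"
    years: tuple[int, ...] = (1997, 2001)
    fixed_proportions: np.ndarray | None = field(default=None, repr=False)
    mc_seed: int = 0

    @property
    def n_vents(self) -> int:
        return len(self.vents)

    @property
    def n_hosts(self) -> int:
        return int(sum(self.n_parental_per_vent) + sum(self.n_hybrid_per_vent))

    def validate(self) -> "SimulationConfig":
        _check(self.n_vents >= 1, "vents", "need at least one vent")
        _check(len(self.n_parental_per_vent) == self.n_vents,
               "n_parental_per_vent", "length must equal number of vents")
        _check(len(self.n_hybrid_per_vent) == self.n_vents,
               "n_hybrid_per_vent", "length must equal number of vents")
        _check(all(n >= 0 for n in self.n_parental_per_vent),
               "n_parental_per_vent", "counts must be >= 0")
        _check(all(n >= 0 for n in self.n_hybrid_per_vent),
               "n_hybrid_per_vent", "counts must be >= 0")
        _check(self.n_hosts >= 1, "n_hosts", "need at least one host")
        for name in ("n_strains", "n_genes", "mean_gene_length", "n_snp_sites"):
            _check(getattr(self, name) >= 1, name, "must be >= 1")
        _check(0.0 <= self.regional_divergence <= 1.0, "regional_divergence",
               "must be in [0, 1]")
        _check(0.0 <= self.within_pool_maf <= 1.0, "within_pool_maf",
               "must be in [0, 1]")
        _check(0.0 <= self.gene_dropout < 1.0, "gene_dropout", "must be in [0, 1)")
        _check(self.host_effect >= 0.0, "host_effect", "must be >= 0")
        _check(self.dirichlet_alpha > 0.0, "dirichlet_alpha", "must be > 0")
        _check(self.mean_depth > 0.0, "mean_depth", "must be > 0")
        _check(self.pool_structure in ("distance", "vent_type"),
               "pool_structure", "must be 'distance' or 'vent_type'")
        _check(self.n_snp_sites <= self.n_genes * self.mean_gene_length,
               "n_snp_sites", "exceeds total gene length")
        vt = {v.vent_type for v in self.vents}
        _check(vt <= {"basalt", "ultramafic"}, "vents",
               f"unknown vent_type in {sorted(vt)}")
        if self.fixed_proportions is not None:
            fp = np.asarray(self.fixed_proportions, dtype=float)
            _check(fp.shape == (self.n_hosts, self.n_strains),
                   "fixed_proportions",
                   f"shape {fp.shape} != {(self.n_hosts, self.n_strains)}")
            _check(np.allclose(fp.sum(axis=1), 1.0, atol=1e-9),
                   "fixed_proportions", "rows must sum to 1")
        return self


@dataclass
class SimulationTruth:
    """Ground truth used to generate a dataset (for parameter recovery)."""

    strain_genotypes: dict[str, np.ndarray]   # vent name -> (n_strains, n_sites) 0/1
    strain_proportions: pd.DataFrame          # samples x strains, rows sum to 1
    admixture: pd.Series                      # per-sample admixture proportion
    block_strength: dict[str, float]
    expected_freq: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> "SimulationTruth":
        props = self.strain_proportions.to_numpy(dtype=float)
        _check(np.allclose(props.sum(axis=1), 1.0, atol=1e-12),
               "strain_proportions", "rows must sum to 1 within 1e-12")
        for vent, geno in self.strain_genotypes.items():
            _check(np.isin(geno, (0, 1)).all(), "strain_genotypes",
                   f"non-binary alleles in pool {vent}")
        return self


def scenario_library(name: str) -> SimulationConfig:
    """Named study designs.

    ``paper_null``
        Six-vent northern-MAR transect, 13 parental + 17 hybrid hosts,
        geographically structured pools, no host effect.
    ``host_driven``
        Single hybrid-zone vent; hybrid hosts strongly tilted toward a
        preferred strain subset (host_effect = 4).
    ``environment_driven``
        Six vents, pool composition tied to vent rock type rather than
        distance along the ridge.
    """
    if name == "paper_null":
        return SimulationConfig().validate()
    if name == "host_driven":
        return SimulationConfig(
            vents=(NORTHERN_MAR_VENTS[3],),
            n_parental_per_vent=(13,),
            n_hybrid_per_vent=(17,),
            host_effect=8.0,
        ).validate()
    if name == "environment_driven":
        return SimulationConfig(pool_structure="vent_type").validate()
    raise ValidationError(f"scenario: unknown name {name!r}")


# ------------------------------------------------------------------ internals

def _gene_catalogue(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = rng.poisson(cfg.mean_gene_length, size=cfg.n_genes)
    sites_per_gene = _sites_per_gene(cfg)
    lengths = np.maximum(lengths, sites_per_gene + 1)
    width = len(str(cfg.n_genes))
    ids = [f"gene{g + 1:0{width}d}" for g in range(cfg.n_genes)]
    return pd.DataFrame({"gene_id": ids, "length": lengths.astype(np.int64)})


def _sites_per_gene(cfg: SimulationConfig) -> np.ndarray:
    base, extra = divmod(cfg.n_snp_sites, cfg.n_genes)
    counts = np.full(cfg.n_genes, base, dtype=np.int64)
    counts[:extra] += 1
    return counts


def _site_table(cfg: SimulationConfig, catalogue: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    counts = _sites_per_gene(cfg)
    rows = []
    for gid, length, k in zip(catalogue["gene_id"], catalogue["length"], counts):
        pos = np.sort(rng.choice(int(length), size=int(k), replace=False))
        for p in pos:
            rows.append((gid, int(p)))
    ref_idx = rng.integers(0, 4, size=len(rows))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(rows))) % 4
    width = len(str(len(rows)))
    df = pd.DataFrame(rows, columns=["gene_id", "pos"])
    df.insert(0, "site_id", [f"s{i + 1:0{width}d}" for i in range(len(rows))])
    df["ref"] = _BASES[ref_idx]
    df["alt"] = _BASES[alt_idx]
    return df[SITE_COLUMNS]


def _vent_pools(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Pool-major alt-allele indicator per vent (stepping stone or vent type)."""
    s = cfg.n_snp_sites
    base = rng.integers(0, 2, size=s)
    majors: dict[str, np.ndarray] = {}
    if cfg.pool_structure == "distance":
        order = sorted(cfg.vents, key=lambda v: -v.lat)
        current = base
        for i, vent in enumerate(order):
            if i > 0:
                flips = rng.random(s) < cfg.regional_divergence
                current = np.where(flips, 1 - current, current)
            majors[vent.name] = current.copy()
    else:  # vent_type: one pool per rock type
        flipped = np.where(rng.random(s) < cfg.regional_divergence, 1 - base, base)
        for vent in cfg.vents:
            majors[vent.name] = (base if vent.vent_type == "basalt" else flipped).copy()
    return majors


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Generate a complete dataset plus its :class:`SimulationTruth`."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.mc_seed)

    catalogue = _gene_catalogue(cfg, rng)
    sites = _site_table(cfg, catalogue, rng)
    majors = _vent_pools(cfg, rng)

    # strain genotypes per vent pool: one shared set of per-strain deviations
    # applied to each vent's major alleles, so vents with identical majors
    # (regional_divergence = 0) carry identical pools
    deviations = rng.random((cfg.n_strains, cfg.n_snp_sites)) < cfg.within_pool_maf
    genotypes: dict[str, np.ndarray] = {}
    for vent in cfg.vents:
        genotypes[vent.name] = np.where(deviations, 1 - majors[vent.name],
                                        majors[vent.name]).astype(np.int8)

    # hosts: metadata, admixture, marker genotypes
    n_hosts = cfg.n_hosts
    width = len(str(n_hosts))
    sample_ids, meta_rows = [], []
    classes, vent_of = [], []
    idx = 0
    for vi, vent in enumerate(cfg.vents):
        for cls, n in (("parental", cfg.n_parental_per_vent[vi]),
                       ("hybrid", cfg.n_hybrid_per_vent[vi])):
            for _ in range(n):
                idx += 1
                sid = f"S{idx:0{width}d}"
                sample_ids.append(sid)
                classes.append(cls)
                vent_of.append(vent.name)
                meta_rows.append((sid, cls, vent.name, vent.lat, vent.lon,
                                  vent.depth_m, vent.vent_type, 0))
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "host_class",
                                                "vent_field", "lat", "lon",
                                                "depth_m", "vent_type", "year"])
    metadata["year"] = rng.choice(np.asarray(cfg.years), size=n_hosts)
    metadata = metadata.set_index("sample_id")

    is_hybrid = np.array([c == "hybrid" for c in classes])
    admix = np.zeros(n_hosts)
    admix[is_hybrid] = rng.uniform(0.25, 0.75, size=int(is_hybrid.sum()))
    marker_cols = [f"m{m + 1:02d}" for m in range(N_DIAGNOSTIC_MARKERS)]
    dosages = rng.binomial(2, np.repeat(admix[:, None], N_DIAGNOSTIC_MARKERS, axis=1))
    dosages[~is_hybrid] = 0
    host_geno = pd.DataFrame(dosages.astype(np.int64), index=sample_ids,
                             columns=marker_cols).astype("Int64")
    host_geno.index.name = "sample_id"

    # strain proportions: Dirichlet(alpha * w); hybrids tilted when host_effect>0
    if cfg.fixed_proportions is not None:
        props = np.asarray(cfg.fixed_proportions, dtype=float).copy()
    else:
        preferred = np.zeros(cfg.n_strains)
        preferred[: cfg.n_strains // 2 or 1] = 1.0
        props = np.empty((n_hosts, cfg.n_strains))
        for i in range(n_hosts):
            w = np.exp(cfg.host_effect * admix[i] * preferred)
            w = w / w.mean()
            props[i] = rng.dirichlet(cfg.dirichlet_alpha * w)

    # pooled reads: depth ~ Poisson, alt count ~ Binomial(depth, mixture freq)
    expected = np.empty((n_hosts, cfg.n_snp_sites))
    for i in range(n_hosts):
        # clip: float summation of a simplex row can exceed 1 by one ulp
        expected[i] = np.clip(props[i] @ genotypes[vent_of[i]], 0.0, 1.0)
    depth = rng.poisson(cfg.mean_depth, size=expected.shape)
    alt = rng.binomial(depth, expected)
    counts = AlleleCountMatrix(samples=sample_ids, sites=sites,
                               ref=depth - alt, alt=alt)

    # per-gene coverage: compositional null (class-independent), rare dropout
    rel = rng.lognormal(0.0, 0.5, size=cfg.n_genes)
    rel /= rel.mean()
    size_f = rng.lognormal(0.0, 0.3, size=n_hosts)
    lam = np.outer(size_f, rel * cfg.mean_depth * 10.0)
    cov = rng.poisson(lam)
    if cfg.gene_dropout > 0:
        cov[rng.random(cov.shape) < cfg.gene_dropout] = 0
    coverage = pd.DataFrame(cov.astype(np.int64), index=sample_ids,
                            columns=list(catalogue["gene_id"]))
    coverage.index.name = "sample_id"

    truth = SimulationTruth(
        strain_genotypes=genotypes,
        strain_proportions=pd.DataFrame(
            props, index=sample_ids,
            columns=[f"strain{k + 1:02d}" for k in range(cfg.n_strains)]),
        admixture=pd.Series(admix, index=sample_ids, name="admixture"),
        block_strength={"regional_divergence": cfg.regional_divergence,
                        "host_effect": cfg.host_effect,
                        "pool_structure": cfg.pool_structure},
        expected_freq=expected,
    ).validate()
    return Dataset(counts=counts, gene_catalogue=catalogue, coverage=coverage,
                   metadata=metadata, host_genotypes=host_geno, truth=truth)


# ------------------------------------------------------------------ fixtures

FIXTURE_FILES = ("allele_counts.tsv", "allele_counts.vcf", "gene_catalogue.tsv",
                 "gene_coverage.tsv", "metadata.tsv", "host_genotypes.tsv",
                 "truth.yaml", "truth_strain_proportions.tsv",
                 "truth_strain_genotypes.tsv")


def write_fixture(dataset: Dataset, directory: str | Path,
                  sequences: dict[str, str] | None = None) -> list[Path]:
    """Write a dataset as the package's plain-text file set.

    Round-trips losslessly through :func:`read_fixture`; the optional gene
    FASTA is omitted when no sequences are supplied.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.write_allele_tsv(dataset.counts, d / "allele_counts.tsv")
    spio.write_allele_vcf(dataset.counts, d / "allele_counts.vcf")
    spio.write_gene_catalogue(dataset.gene_catalogue, d / "gene_catalogue.tsv",
                              sequences=sequences,
                              fasta_path=d / "genes.fasta" if sequences else None)
    spio.write_coverage(dataset.coverage, d / "gene_coverage.tsv")
    spio.write_metadata(dataset.metadata, d / "metadata.tsv")
    spio.write_host_genotypes(dataset.host_genotypes, d / "host_genotypes.tsv")
    paths = [d / f for f in FIXTURE_FILES[:6]]
    if dataset.truth is not None:
        truth: SimulationTruth = dataset.truth
        doc = {
            "admixture": {s: float(v) for s, v in truth.admixture.items()},
            "block_strength": {k: (v if isinstance(v, str) else float(v))
                               for k, v in truth.block_strength.items()},
        }
        with open(d / "truth.yaml", "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
        truth.strain_proportions.reset_index(names="sample_id").to_csv(
            d / "truth_strain_proportions.tsv", sep="\t", index=False,
            lineterminator="\n", float_format="%.17g")
        with open(d / "truth_strain_genotypes.tsv", "w") as fh:
            fh.write("vent\tstrain\talleles\n")
            for vent in sorted(truth.strain_genotypes):
                geno = truth.strain_genotypes[vent]
                for k in range(geno.shape[0]):
                    fh.write(f"{vent}\t{k}\t"
                             + "".join(map(str, geno[k].tolist())) + "\n")
        paths += [d / f for f in FIXTURE_FILES[6:]]
    return paths


def read_fixture(directory: str | Path) -> Dataset:
    """Read a fixture directory back into a :class:`Dataset`."""
    d = Path(directory)
    counts = spio.read_allele_tsv(d / "allele_counts.tsv")
    dataset = Dataset(
        counts=counts,
        gene_catalogue=spio.read_gene_catalogue(d / "gene_catalogue.tsv"),
        coverage=spio.read_coverage(d / "gene_coverage.tsv"),
        metadata=spio.read_metadata(d / "metadata.tsv"),
        host_genotypes=spio.read_host_genotypes(d / "host_genotypes.tsv"),
    )
    if (d / "truth.yaml").exists():
        with open(d / "truth.yaml") as fh:
            doc = yaml.safe_load(fh)
        props = pd.read_csv(d / "truth_strain_proportions.tsv", sep="\t",
                            float_precision="round_trip")
        props = props.set_index("sample_id")
        geno_df = pd.read_csv(d / "truth_strain_genotypes.tsv", sep="\t",
                              dtype={"alleles": str})
        genotypes = {
            vent: np.array([list(map(int, a)) for a in grp["alleles"]],
                           dtype=np.int8)
            for vent, grp in geno_df.groupby("vent", sort=True)
        }
        dataset.truth = SimulationTruth(
            strain_genotypes=genotypes,
            strain_proportions=props,
            admixture=pd.Series(doc["admixture"], name="admixture").reindex(props.index),
            block_strength=doc["block_strength"],
        )
    return dataset


def fixture_digest(directory: str | Path) -> dict[str, str]:
    """SHA-256 of every fixture file, for determinism checks."""
    d = Path(directory)
    out = {}
    for p in sorted(d.iterdir()):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
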