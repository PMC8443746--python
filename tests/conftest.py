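import numpy as np
import pandas as pd
import pytest

from symbiopop import SimulationConfig, Vent, simulate_dataset
from symbiopop.datatypes import SITE_COLUMNS, AlleleCountMatrix

TWO_VENTS = (
    Vent("NorthVent", 37.0, -32.0, 900.0, "basalt"),
    Vent("SouthVent", 29.0, -43.0, 3000.0, "ultramafic"),
)


def small_config(**kw) -> SimulationConfig:
    """A fast two-vent design for unit tests (8 hosts, 20 genes, 100 sites)."""
    base = dict(
        vents=TWO_VENTS,
        n_parental_per_vent=(2, 2),
        n_hybrid_per_vent=(2, 2),
        n_strains=6,
        n_genes=20,
        mean_gene_length=300,
        n_snp_sites=100,
        mean_depth=50.0,
        mc_seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base).validate()


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def paper_null_dataset():
    from symbiopop import scenario_library
    cfg = scenario_library("paper_null")
    cfg.mc_seed = 11
    return simulate_dataset(cfg)


def random_counts(rng: np.random.Generator, n_samples: int, n_genes: int,
                  sites_per_gene: int, depth_low: int = 0,
                  depth_high: int = 30) -> AlleleCountMatrix:
    """Random allele-count fixture with sites assigned to genes."""
    n_sites = n_genes * sites_per_gene
    sites = pd.DataFrame({
        "site_id": [f"s{i:04d}" for i in range(n_sites)],
        "gene_id": [f"g{i // sites_per_gene:03d}" for i in range(n_sites)],
        "pos": list(range(sites_per_gene)) * n_genes,
        "ref": ["A"] * n_sites,
        "alt": ["T"] * n_sites,
    })[SITE_COLUMNS]
    depth = rng.integers(depth_low, depth_high, size=(n_samples, n_sites))
    alt = rng.binomial(depth, rng.uniform(0, 1, size=n_sites)[None, :])
    samples = [f"h{i:02d}" for i in range(n_samples)]
    return AlleleCountMatrix(samples=samples, sites=sites,
                             ref=depth - alt, alt=alt)
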