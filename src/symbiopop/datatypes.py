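"""Core in-memory containers shared across the pipeline.

Sites are annotated with the gene they belong to; positions are 0-based
offsets within the gene (converted to 1-based only on VCF output).
Distance matrices throughout the package are ``skbio.DistanceMatrix``
instances (symmetric, hollow, labelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["site_id", "gene_id", "pos", "ref", "alt"]
_NUCLEOTIDES = frozenset("ACGT")


class ValidationError(ValueError):
    """Input violated a documented invariant; the message names the field."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {msg}")


def validate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate a SNP site annotation table (biallelic, unique ids)."""
    _check(list(sites.columns[:5]) == SITE_COLUMNS, "sites",
           f"expected columns {SITE_COLUMNS}, got {list(sites.columns)}")
    _check(sites["site_id"].is_unique, "site_id", "duplicated site_id")
    _check((sites["pos"] >= 0).all(), "pos", "negative position")
    for col in ("ref", "alt"):
        bad = ~sites[col].isin(list(_NUCLEOTIDES))
        _check(not bad.any(), col, f"non-nucleotide allele {sites.loc[bad, col].tolist()[:3]}")
    _check((sites["ref"] != sites["alt"]).all(), "alt", "ref == alt at some sites")
    return sites.reset_index(drop=True)


@dataclass
class AlleleCountMatrix:
    """Per-sample ref/alt read counts at biallelic SNP sites.

    ``ref`` and ``alt`` are ``(n_samples, n_sites)`` integer arrays aligned
    with ``samples`` (rows) and ``sites`` (columns).
    """

    samples: list[str]
    sites: pd.DataFrame
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.sites = validate_sites(self.sites)
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        shape = (len(self.samples), len(self.sites))
        _check(self.ref.shape == shape, "ref", f"shape {self.ref.shape} != {shape}")
        _check(self.alt.shape == shape, "alt", f"shape {self.alt.shape} != {shape}")
        _check((self.ref >= 0).all() and (self.alt >= 0).all(), "counts",
               "negative read counts")
        _check(len(set(self.samples)) == len(self.samples), "samples",
               "duplicated sample ids")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountMatrix):
            return NotImplemented
        return (self.samples == other.samples
                and self.sites.equals(other.sites)
                and np.array_equal(self.ref, other.ref)
                and np.array_equal(self.alt, other.alt))


@dataclass
class AlleleFrequencyMatrix:
    """Alternate-allele frequencies with parallel depths.

    ``freq[i, s]`` is alt/(ref+alt) where depth >= ``min_depth`` and NaN
    (missing) otherwise; ``depth`` keeps the raw coverage for every cell.
    """

    samples: list[str]
    sites: pd.DataFrame
    freq: np.ndarray
    depth: np.ndarray
    min_depth: int = 1

    def __post_init__(self) -> None:
        self.sites = validate_sites(self.sites)
        self.freq = np.asarray(self.freq, dtype=float)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        shape = (len(self.samples), len(self.sites))
        _check(self.freq.shape == shape, "freq", f"shape {self.freq.shape} != {shape}")
        _check(self.depth.shape == shape, "depth", f"shape {self.depth.shape} != {shape}")
        ok = np.isnan(self.freq) | ((self.freq >= 0) & (self.freq <= 1))
        _check(ok.all(), "freq", "frequencies outside [0, 1]")
        present = ~np.isnan(self.freq)
        _check((self.depth[present] >= self.min_depth).all(), "freq",
               "frequency present at a cell below min_depth")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def gene_ids(self) -> pd.Series:
        return self.sites["gene_id"]


@dataclass
class Dataset:
    """Bundle of the five tables the pipeline consumes."""

    counts: AlleleCountMatrix
    gene_catalogue: pd.DataFrame          # gene_id, length
    coverage: pd.DataFrame                # samples x genes, integer counts
    metadata: pd.DataFrame                # indexed by sample_id
    host_genotypes: pd.DataFrame          # samples x 18 markers, dosage 0/1/2
    truth: "object | None" = field(default=None, repr=False)

METADATA_COLUMNS = ["sample_id", "host_class", "vent_field", "lat", "lon",
                    "depth_m", "vent_type", "year"]
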