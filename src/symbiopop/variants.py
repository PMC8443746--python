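"""SNP filtering and per-sample allele frequencies / consensus alleles.

The pooled-metagenome convention applies throughout: each sample is a pool
of symbiont strains from one host, read counts estimate within-host allele
frequencies, and read depth plays the role of sample size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AlleleCountMatrix, AlleleFrequencyMatrix, ValidationError
from .io import (read_allele_tsv, read_allele_vcf, write_allele_tsv,
                 write_allele_vcf)

__all__ = [
    "call_snps", "consensus_alleles",
    "read_allele_tsv", "read_allele_vcf", "write_allele_tsv", "write_allele_vcf",
]

DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_MAF = 0.02
DEFAULT_MIN_SAMPLE_FRACTION = 0.8


def call_snps(counts: AlleleCountMatrix, min_depth: int = DEFAULT_MIN_DEPTH,
              min_maf: float = DEFAULT_MIN_MAF,
              min_sample_fraction: float = DEFAULT_MIN_SAMPLE_FRACTION,
              ) -> AlleleFrequencyMatrix:
    """Filter to usable variable sites and compute alt-allele frequencies.

    A site is kept when (a) its pooled minor-allele frequency — reads summed
    over the cells meeting ``min_depth``, so that low-coverage noise cannot
    rescue a site — is >= ``min_maf`` and (b) at least ``min_sample_fraction``
    of samples cover it at depth >= ``min_depth``.  Cells below ``min_depth``
    are set missing (NaN); surviving frequencies are exactly
    alt / (ref + alt).  Raises when no site survives.  Filtering is
    idempotent at equal thresholds.
    """
    if min_depth < 1:
        raise ValidationError("min_depth: must be >= 1")
    for name, val in (("min_maf", min_maf),
                      ("min_sample_fraction", min_sample_fraction)):
        if not 0.0 <= val <= 1.0:
            raise ValidationError(f"{name}: must be in [0, 1]")

    depth = counts.depth
    covered = depth >= min_depth
    pooled_alt = (counts.alt * covered).sum(axis=0)
    pooled_tot = (depth * covered).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(pooled_tot > 0, pooled_alt / np.maximum(pooled_tot, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    covered_frac = covered.mean(axis=0)
    keep = (maf >= min_maf) & (covered_frac >= min_sample_fraction) & (pooled_tot > 0)
    if not keep.any():
        raise ValidationError("call_snps: no variable sites survive the filters")

    sub_depth = depth[:, keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts.alt[:, keep] / np.maximum(sub_depth, 1)
    freq = np.where(sub_depth >= min_depth, freq, np.nan)
    return AlleleFrequencyMatrix(
        samples=list(counts.samples),
        sites=counts.sites.loc[keep].reset_index(drop=True),
        freq=freq, depth=sub_depth, min_depth=min_depth)


def refilter(freqs: AlleleFrequencyMatrix, min_depth: int, min_maf: float,
             min_sample_fraction: float) -> AlleleFrequencyMatrix:
    """Re-apply :func:`call_snps` thresholds to an already-filtered matrix.

    Used by the idempotence property tests; reconstructs counts from the
    stored depths and frequencies (exact because freq = alt/depth).
    """
    alt = np.where(np.isnan(freqs.freq), 0, np.rint(
        np.nan_to_num(freqs.freq) * freqs.depth)).astype(np.int64)
    # cells that were masked keep their raw depth as ref-only coverage
    counts = AlleleCountMatrix(samples=list(freqs.samples), sites=freqs.sites,
                               ref=freqs.depth - alt, alt=alt)
    return call_snps(counts, min_depth, min_maf, min_sample_fraction)


def consensus_alleles(freqs: AlleleFrequencyMatrix) -> pd.DataFrame:
    """Per-sample consensus allele at every site.

    The consensus is the majority allele of the within-host strain mixture:
    alt when frequency > 0.5, ref when < 0.5; an exact tie calls ref (the
    reference base is the deterministic tie-break).  Missing cells yield no
    call (NaN).  Returns a samples x sites DataFrame of 'A'/'C'/'G'/'T'/NaN.
    """
    if freqs.n_sites == 0:
        raise ValidationError("consensus_alleles: empty frequency matrix")
    ref = freqs.sites["ref"].to_numpy()
    alt = freqs.sites["alt"].to_numpy()
    use_alt = freqs.freq > 0.5
    called = ~np.isnan(freqs.freq)
    out = np.where(use_alt, alt[None, :], ref[None, :]).astype(object)
    out[~called] = np.nan
    return pd.DataFrame(out, index=list(freqs.samples),
                        columns=list(freqs.sites["site_id"]))
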