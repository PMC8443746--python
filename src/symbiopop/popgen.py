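"""Pairwise genetic differentiation between per-host symbiont populations.

F_ST uses the Hudson estimator with read depth in the role of sample size
(pool-seq convention).  Per site, with alt frequencies p1, p2 at depths
n1, n2 >= 2::

    N = (p1 - p2)^2 - p1(1 - p1)/(n1 - 1) - p2(1 - p2)/(n2 - 1)
    D = p1(1 - p2) + p2(1 - p1)

and multi-site estimates are the *ratio of averages* sum(N)/sum(D) — never
the average of per-site ratios, which is biased for low-diversity sites.
Sites with D = 0 (monomorphic in both pools) carry no information and are
skipped; sites with depth < 2 in either member of a pair are excluded from
that pair.

ANI between two hosts is computed on their strain-mixture consensus
sequences over the whole gene catalogue: invariant (non-SNP) positions
count as matches, so the denominator is the total catalogue length minus
positions uncalled in either sample, matching whole-genome ANI semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datatypes import AlleleFrequencyMatrix, ValidationError

__all__ = ["hudson_fst_site", "gene_fst", "pairwise_fst_matrix", "pairwise_ani",
           "FstResult", "AniResult"]


def hudson_fst_site(p1: float, p2: float, n1: float, n2: float,
                    ) -> tuple[float, float]:
    """Numerator/denominator pair of the Hudson F_ST estimator at one site.

    ``n1``/``n2`` are the read depths of the two pools.  The site-level
    F_ST is N/D when D > 0; callers pool (N, D) across sites before
    dividing.  Raises for depths < 2 (the finite-sample correction divides
    by n - 1).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("depth: hudson_fst_site requires n1, n2 >= 2")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValidationError("freq: p1, p2 must be in [0, 1]")
    num = ((p1 - p2) ** 2
           - p1 * (1.0 - p1) / (n1 - 1.0)
           - p2 * (1.0 - p2) / (n2 - 1.0))
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return num, den


def _pair_nd(freqs: AlleleFrequencyMatrix, i: np.ndarray, j: np.ndarray,
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (N, D, usable) for pair index arrays i, j over all sites."""
    p, n = freqs.freq, freqs.depth.astype(float)
    p1, p2 = p[i], p[j]
    n1, n2 = n[i], n[j]
    usable = (~np.isnan(p1)) & (~np.isnan(p2)) & (n1 >= 2) & (n2 >= 2)
    p1 = np.nan_to_num(p1)
    p2 = np.nan_to_num(p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1.0 - p1) / np.maximum(n1 - 1.0, 1e-300)
               - p2 * (1.0 - p2) / np.maximum(n2 - 1.0, 1e-300))
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    usable &= den > 0
    return num, den, usable


def gene_fst(freqs: AlleleFrequencyMatrix, gene_id: str, sample_i: str,
             sample_j: str) -> float:
    """Ratio-of-averages Hudson F_ST for one gene and one sample pair.

    Returns NaN when the gene has no usable site for the pair.
    """
    ii = freqs.samples.index(sample_i)
    jj = freqs.samples.index(sample_j)
    in_gene = (freqs.sites["gene_id"] == gene_id).to_numpy()
    if not in_gene.any():
        raise ValidationError(f"gene_id: {gene_id!r} not in site table")
    num, den, usable = _pair_nd(freqs, np.array([ii]), np.array([jj]))
    use = usable[0] & in_gene
    if not use.any():
        return float("nan")
    return float(num[0, use].sum() / den[0, use].sum())


@dataclass
class FstResult:
    """Per-gene table, raw genome-wide pair values, and the floored matrix."""

    gene_table: pd.DataFrame   # gene_id, sample_i, sample_j, fst, n_sites
    pairwise: pd.DataFrame     # sample_i, sample_j, fst (raw), n_sites
    matrix: DistanceMatrix     # genome-wide F_ST, negatives floored at 0


def pairwise_fst_matrix(freqs: AlleleFrequencyMatrix) -> FstResult:
    """All-pairs Hudson F_ST: per gene and genome-wide.

    The genome-wide value for a pair pools N and D over *all* usable sites
    (not the mean of per-gene values).  Negative pooled estimates — expected
    for near-identical pools at finite depth — are floored at 0 in the
    reported matrix only; the raw values stay in ``pairwise``.
    """
    samples = list(freqs.samples)
    if len(samples) < 2:
        raise ValidationError("samples: pairwise F_ST needs >= 2 samples")
    gene_ids, gene_idx = np.unique(freqs.sites["gene_id"].to_numpy(),
                                   return_inverse=True)
    n_genes = len(gene_ids)
    pairs = list(combinations(range(len(samples)), 2))
    i_idx = np.fromiter((p[0] for p in pairs), dtype=int)
    j_idx = np.fromiter((p[1] for p in pairs), dtype=int)
    num, den, usable = _pair_nd(freqs, i_idx, j_idx)

    mat = np.zeros((len(samples), len(samples)))
    gene_rows, pair_rows = [], []
    for k, (a, b) in enumerate(pairs):
        use = usable[k]
        if not use.any():
            raise ValidationError(
                f"pair: no usable sites for ({samples[a]}, {samples[b]})")
        raw = float(num[k, use].sum() / den[k, use].sum())
        pair_rows.append((samples[a], samples[b], raw, int(use.sum())))
        mat[a, b] = mat[b, a] = max(raw, 0.0)
        g_num = np.bincount(gene_idx[use], weights=num[k, use], minlength=n_genes)
        g_den = np.bincount(gene_idx[use], weights=den[k, use], minlength=n_genes)
        g_n = np.bincount(gene_idx[use], minlength=n_genes)
        ok = g_den > 0
        for g in np.nonzero(ok)[0]:
            gene_rows.append((gene_ids[g], samples[a], samples[b],
                              g_num[g] / g_den[g], int(g_n[g])))
    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "sample_i",
                                                  "sample_j", "fst", "n_sites"])
    pairwise = pd.DataFrame(pair_rows, columns=["sample_i", "sample_j",
                                                "fst", "n_sites"])
    return FstResult(gene_table=gene_table, pairwise=pairwise,
                     matrix=DistanceMatrix(mat, ids=samples))


@dataclass
class AniResult:
    """Average nucleotide identity between consensus sequences."""

    ani: pd.DataFrame             # square, percent identity (100 on diagonal)
    aligned_length: pd.DataFrame  # square, jointly called length in bp
    distance: DistanceMatrix      # 100 - ANI


def pairwise_ani(consensus: pd.DataFrame, gene_catalogue: pd.DataFrame,
                 ) -> AniResult:
    """Consensus-based ANI over the full gene catalogue.

    ``consensus`` is the samples x sites allele table from
    :func:`symbiopop.variants.consensus_alleles`; every catalogue position
    that is not a (called) SNP site counts as identical.  Positions uncalled
    in either sample are removed from the denominator.
    """
    samples = list(consensus.index)
    if len(samples) < 2:
        raise ValidationError("samples: pairwise ANI needs >= 2 samples")
    total_len = int(gene_catalogue["length"].sum())
    if consensus.shape[1] > total_len:
        raise ValidationError("gene catalogue: shorter than the SNP site count")
    # code alleles as ints, missing as -1
    alleles = consensus.to_numpy(dtype=object)
    called = ~pd.isna(alleles)
    codes = np.full(alleles.shape, -1, dtype=np.int8)
    for b, c in zip("ACGT", range(4)):
        codes[(alleles == b) & called] = c

    n = len(samples)
    ani = np.full((n, n), 100.0)
    aligned = np.full((n, n), float(total_len))
    for a in range(n):
        for b in range(a + 1, n):
            joint = (codes[a] >= 0) & (codes[b] >= 0)
            uncalled = int((~joint).sum())
            length = total_len - uncalled
            if length <= 0:
                raise ValidationError(
                    f"pair: zero jointly covered length for "
                    f"({samples[a]}, {samples[b]})")
            diffs = int((codes[a][joint] != codes[b][joint]).sum())
            ani[a, b] = ani[b, a] = 100.0 * (length - diffs) / length
            aligned[a, b] = aligned[b, a] = float(length)
    ids = samples
    return AniResult(
        ani=pd.DataFrame(ani, index=ids, columns=ids),
        aligned_length=pd.DataFrame(aligned, index=ids, columns=ids),
        distance=DistanceMatrix(100.0 - ani, ids=ids))
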