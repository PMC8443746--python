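"""Host-side quantities from the 18 species-diagnostic SNP markers.

Genotypes are stored as dosages in {0, 1, 2} — the number of alleles
diagnostic for the northern parental species — with missing values allowed.
The pairwise distance is the allele-sharing distance

    d(i, j) = 1 - (1 / (2 M_ij)) * sum_m s_m,   s_m = 2 - |g_im - g_jm|

over the M_ij markers typed in both individuals: s_m counts the alleles two
genotypes share at a marker (identical homozygotes share 2, opposite
homozygotes 0, a het shares 1 with anything).  Allele-sharing distance is
missing-data tolerant but need not satisfy the triangle inequality; nothing
downstream (Mantel tests) requires metricity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datatypes import ValidationError

__all__ = ["host_distance", "hybrid_index", "year_distance"]


def _dosage_array(genotypes: pd.DataFrame) -> np.ndarray:
    arr = genotypes.to_numpy(dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValidationError("genotypes: dosages must be 0/1/2 or missing")
    if arr.shape[1] > 18:
        raise ValidationError("genotypes: more than 18 marker columns")
    return arr


def host_distance(genotypes: pd.DataFrame) -> DistanceMatrix:
    """Pairwise allele-sharing distance between hosts."""
    arr = _dosage_array(genotypes)
    n = arr.shape[0]
    if n < 2:
        raise ValidationError("genotypes: need >= 2 individuals")
    typed = ~np.isnan(arr)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = typed[i] & typed[j]
            m = int(joint.sum())
            if m == 0:
                raise ValidationError(
                    f"genotypes: no jointly typed marker for pair "
                    f"({genotypes.index[i]}, {genotypes.index[j]})")
            shared = (2.0 - np.abs(arr[i, joint] - arr[j, joint])).sum()
            d[i, j] = d[j, i] = 1.0 - shared / (2.0 * m)
    return DistanceMatrix(d, ids=list(genotypes.index))


def hybrid_index(genotypes: pd.DataFrame) -> pd.Series:
    """Fraction of diagnostic alleles per individual: sum(dosage)/(2 * typed)."""
    arr = _dosage_array(genotypes)
    typed = (~np.isnan(arr)).sum(axis=1)
    if (typed == 0).any():
        bad = genotypes.index[typed == 0].tolist()
        raise ValidationError(f"genotypes: all markers missing for {bad}")
    idx = np.nansum(arr, axis=1) / (2.0 * typed)
    return pd.Series(idx, index=genotypes.index, name="hybrid_index")


def year_distance(metadata: pd.DataFrame) -> DistanceMatrix:
    """Binary sampling-year dissimilarity: 0 same year, 1 different."""
    if "year" not in metadata.columns:
        raise ValidationError("metadata: missing year column")
    years = metadata["year"]
    if years.isna().any():
        bad = metadata.index[years.isna()].tolist()
        raise ValidationError(f"metadata: missing year for {bad}")
    y = years.to_numpy()
    d = (y[:, None] != y[None, :]).astype(float)
    return DistanceMatrix(d, ids=list(metadata.index))
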