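"""Hypothesis tests for host–symbiont association.

Four procedures, all seeded and deterministic:

* :func:`mantel` — permutation test of the Pearson correlation between two
  distance matrices (rows/columns of the second matrix permuted jointly).
* :func:`fst_between_within_test` — per-gene Mann-Whitney U contrast of
  pairwise F_ST values between hybrid–parental pairs versus within-class
  pairs, BH-corrected across genes.  Pairwise values are not independent;
  the test is the field's conventional screen and is interpreted as such.
* :func:`clr_diff_abundance` — compositional differential abundance:
  Dirichlet resampling of per-sample gene proportions (prior 0.5), centred
  log-ratio transform, Kruskal-Wallis per gene, expected p over Monte-Carlo
  instances, then BH.
* :func:`presence_absence_test` — per-gene two-sided Fisher exact test of
  gene presence against host class.

Benjamini-Hochberg correction is delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError

__all__ = ["mantel", "MantelResult", "fst_between_within_test",
           "clr_diff_abundance", "presence_absence_test", "benjamini_hochberg"]


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up q-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------- Mantel

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    n: int

    def as_dict(self) -> dict:
        return {"r": float(self.r), "p": float(self.p),
                "n_perm": int(self.n_perm), "tail": self.tail, "n": int(self.n)}


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9999,
           seed: int | None = None, tail: str = "greater") -> MantelResult:
    """Mantel permutation test between two labelled distance matrices.

    The observed statistic is the Pearson correlation over the n(n-1)/2
    upper-triangle entries after aligning ``d2`` to ``d1``'s ids.  The null
    distribution permutes rows and columns of ``d2`` jointly; the p-value
    uses the +1 correction and so is never exactly 0.  ``tail`` is
    ``"greater"`` (positive association) or ``"two-sided"``.
    """
    if tail not in ("greater", "two-sided"):
        raise ValidationError(f"tail: unknown tail {tail!r}")
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("ids: distance matrices have different labels")
    n = len(d1.ids)
    if n < 3:
        raise ValidationError("ids: Mantel test needs >= 3 samples")
    if n_perm < 1:
        raise ValidationError("n_perm: must be >= 1")
    m1 = d1.data
    m2 = d2.filter(d1.ids).data
    iu = np.triu_indices(n, k=1)
    x, y = m1[iu], m2[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("matrix: constant distances, correlation undefined")
    x = (x - x.mean()) / x.std()
    y0 = y - y.mean()
    denom = np.sqrt((y0 ** 2).sum() * len(x))
    r_obs = float((x * y0).sum() / denom)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = m2[np.ix_(perm, perm)][iu]
        yp = yp - yp.mean()
        r_p = (x * yp).sum() / np.sqrt((yp ** 2).sum() * len(x))
        if tail == "greater":
            hits += r_p >= r_obs - 1e-12
        else:
            hits += abs(r_p) >= abs(r_obs) - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, tail=tail, n=n)


# ----------------------------------------------------- per-gene F_ST contrast

def _class_series(classes, samples: list[str]) -> pd.Series:
    s = pd.Series(classes)
    missing = [x for x in samples if x not in s.index]
    if missing:
        raise ValidationError(f"classes: no class for samples {missing[:5]}")
    s = s.loc[samples]
    levels = sorted(s.unique())
    if len(levels) != 2:
        raise ValidationError(f"classes: need exactly 2 classes, got {levels}")
    return s


def fst_between_within_test(gene_table: pd.DataFrame, classes,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene between- vs within-class contrast of pairwise F_ST.

    ``gene_table`` is the per-gene table from
    :func:`symbiopop.popgen.pairwise_fst_matrix` (raw, unfloored values);
    ``classes`` maps sample id to one of two host classes.  Each gene's
    pair values are split into between-class and within-class sets and
    compared with a two-sided Mann-Whitney U test (normal approximation
    with tie correction); genes with fewer than 2 values on either side are
    recorded as non-testable.  q-values are BH across testable genes;
    ``significant`` is q < ``alpha``.
    """
    samples = sorted(set(gene_table["sample_i"]) | set(gene_table["sample_j"]))
    cls = _class_series(classes, samples)
    between = (cls.loc[gene_table["sample_i"]].to_numpy()
               != cls.loc[gene_table["sample_j"]].to_numpy())
    rows = []
    for gene, grp in gene_table.groupby("gene_id", sort=True):
        b = grp.loc[between[grp.index], "fst"].to_numpy(dtype=float)
        w = grp.loc[~between[grp.index], "fst"].to_numpy(dtype=float)
        if len(b) < 2 or len(w) < 2:
            rows.append((gene, np.nan, np.nan, len(b), len(w), "none", False))
            continue
        res = sps.mannwhitneyu(b, w, alternative="two-sided",
                               method="asymptotic")
        direction = ("between_higher" if res.statistic > len(b) * len(w) / 2
                     else "within_higher")
        rows.append((gene, float(res.statistic), float(res.pvalue),
                     len(b), len(w), direction, True))
    table = pd.DataFrame(rows, columns=["gene_id", "statistic", "p",
                                        "n_between", "n_within", "direction",
                                        "tested"])
    return _attach_q(table, alpha)


def _attach_q(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    table["q"] = np.nan
    tested = table["tested"].to_numpy()
    if tested.any():
        table.loc[tested, "q"] = benjamini_hochberg(
            table.loc[tested, "p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table


# --------------------------------------------------- CLR differential tests

def clr_transform(proportions: np.ndarray) -> np.ndarray:
    """Centred log-ratio per row: log p minus the row mean of log p."""
    logp = np.log(proportions)
    return logp - logp.mean(axis=1, keepdims=True)


def clr_diff_abundance(coverage: pd.DataFrame, classes, n_mc: int = 128,
                       seed: int | None = None, prior: float = 0.5,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Dirichlet-CLR differential gene abundance between two host classes.

    For each of ``n_mc`` Monte-Carlo instances, per-sample gene proportions
    are drawn from Dirichlet(counts + ``prior``), CLR-transformed, and each
    gene is tested with Kruskal-Wallis across the two classes.  The
    reported per-gene p is the expectation over instances; q is BH.
    """
    counts = coverage.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValidationError("coverage: negative counts")
    if (counts.sum(axis=1) == 0).any():
        bad = coverage.index[counts.sum(axis=1) == 0].tolist()
        raise ValidationError(f"coverage: all-zero sample rows {bad}")
    cls = _class_series(classes, list(coverage.index))
    levels = sorted(cls.unique())
    g1 = (cls == levels[0]).to_numpy()
    g2 = ~g1
    rng = np.random.default_rng(seed)
    n_genes = counts.shape[1]
    p_sum = np.zeros(n_genes)
    h_sum = np.zeros(n_genes)
    effect = np.zeros(n_genes)
    for _ in range(n_mc):
        gam = rng.standard_gamma(counts + prior)
        prop = gam / gam.sum(axis=1, keepdims=True)
        clr = clr_transform(prop)
        res = sps.kruskal(clr[g1], clr[g2], axis=0)
        p_sum += res.pvalue
        h_sum += res.statistic
        effect += clr[g1].mean(axis=0) - clr[g2].mean(axis=0)
    p = p_sum / n_mc
    direction = np.where(effect > 0, f"higher_in_{levels[0]}",
                         f"higher_in_{levels[1]}")
    table = pd.DataFrame({
        "gene_id": list(coverage.columns),
        "statistic": h_sum / n_mc,
        "p": p,
        "n_between": int(g1.sum()),
        "n_within": int(g2.sum()),
        "direction": direction,
        "tested": True,
    })
    return _attach_q(table, alpha)


def presence_absence_test(presence: pd.DataFrame, classes,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Fisher exact test of gene presence against host class.

    Genes present in all samples or absent from all samples carry no
    contrast and are recorded as non-testable.
    """
    pres = presence.to_numpy(dtype=bool)
    cls = _class_series(classes, list(presence.index))
    levels = sorted(cls.unique())
    g1 = (cls == levels[0]).to_numpy()
    if g1.all() or not g1.any():
        raise ValidationError("classes: a class has zero samples")
    rows = []
    for g, gene in enumerate(presence.columns):
        col = pres[:, g]
        if col.all() or not col.any():
            rows.append((gene, np.nan, np.nan, int(g1.sum()),
                         int((~g1).sum()), "none", False))
            continue
        a, b = int(col[g1].sum()), int((~col[g1]).sum())
        c, d = int(col[~g1].sum()), int((~col[~g1]).sum())
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = (f"present_in_{levels[0]}" if a * d > b * c
                     else f"present_in_{levels[1]}")
        rows.append((gene, float(odds), float(p), int(g1.sum()),
                     int((~g1).sum()), direction, True))
    table = pd.DataFrame(rows, columns=["gene_id", "statistic", "p",
                                        "n_between", "n_within", "direction",
                                        "tested"])
    return _attach_q(table, alpha)
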