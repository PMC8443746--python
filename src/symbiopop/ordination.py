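"""Constrained and unconstrained ordination of symbiont allele frequencies.

* :func:`rda` — redundancy analysis: multivariate least squares of a
  (centred) response matrix on a predictor design, summarised by the
  fraction of total sum-of-squares explained, Ezekiel-adjusted R², and a
  permutation test of the pseudo-F statistic (free row permutation of the
  response).
* :func:`varpart4` — variation partitioning of adjusted R² across up to
  four predictor blocks: all 2^4 - 1 subset models are fitted and the 15
  exclusive (unique + shared) fractions are solved from the subset R²
  values; fractions may be negative and are reported as-is.
* :func:`nmds` — non-metric multidimensional scaling by SMACOF
  majorization with monotone (isotonic) regression of disparities,
  minimising Kruskal stress-1; best of several restarts, the first
  initialised from classical scaling.
* :func:`build_predictors` — turns sample metadata into the four blocks
  used in the ridge-transect analysis: along-ridge geographic position
  (cumulative great-circle distance down the latitude-ordered vent chain),
  water depth, host class, and vent rock type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from .datatypes import AlleleFrequencyMatrix, ValidationError

__all__ = ["rda", "varpart4", "nmds", "build_predictors",
           "impute_frequencies", "haversine_km",
           "RdaResult", "VarpartResult", "NmdsResult", "PredictorBlocks"]

EARTH_RADIUS_KM = 6371.0088
COLLINEARITY_FLAG = 0.8


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres."""
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    a = (math.sin((la2 - la1) / 2) ** 2
         + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def impute_frequencies(freqs: AlleleFrequencyMatrix) -> np.ndarray:
    """Fill missing cells with the per-site mean (ordination input only).

    Complete columns are returned untouched; F_ST never sees imputed
    values.  A site missing in every sample is filled with 0.
    """
    x = freqs.freq.copy()
    mean = np.nanmean(np.where(np.isnan(x).all(axis=0), 0.0, x), axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mean, idx[1])
    return x


def _as_matrix(y) -> np.ndarray:
    if isinstance(y, AlleleFrequencyMatrix):
        return impute_frequencies(y)
    arr = np.asarray(y, dtype=float) if not isinstance(y, pd.DataFrame) \
        else y.to_numpy(dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _design_array(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{k}" for k in range(arr.shape[1])]


def _check_rank(xc: np.ndarray, names: list[str]) -> int:
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        # name a minimal set of columns that complete the collinearity
        kept: list[int] = []
        collinear: list[str] = []
        for k in range(xc.shape[1]):
            trial = xc[:, kept + [k]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(k)
            else:
                collinear.append(names[k])
        raise ValidationError(
            f"design: rank-deficient predictor matrix; collinear columns "
            f"{collinear}")
    return rank


@dataclass
class RdaResult:
    r2: float
    adj_r2: float
    f_stat: float
    perm_p: float | None
    site_scores: np.ndarray
    eigenvalues: np.ndarray
    n: int
    m: int

    def as_dict(self) -> dict:
        return {"r2": float(self.r2), "adj_r2": float(self.adj_r2),
                "f_stat": float(self.f_stat),
                "perm_p": None if self.perm_p is None else float(self.perm_p),
                "n": int(self.n), "m": int(self.m)}


def _fit_ss(q: np.ndarray, yc: np.ndarray) -> float:
    return float(((q.T @ yc) ** 2).sum())


def rda(response, predictors, n_perm: int = 1000, seed: int | None = None,
        ) -> RdaResult:
    """Redundancy analysis of a multivariate response on a predictor design.

    The response is centred column-wise (an
    :class:`~symbiopop.datatypes.AlleleFrequencyMatrix` is mean-imputed
    first); predictors are centred and must be of full column rank.  The
    permutation p-value uses free row permutation of the response with the
    +1 correction; ``n_perm=0`` skips the test.
    """
    y = _as_matrix(response)
    x, names = _design_array(predictors)
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValidationError("design: response and predictors disagree on n")
    xc = x - x.mean(axis=0)
    m = _check_rank(xc, names)
    if n <= m + 1:
        raise ValidationError(f"design: need n > m + 1 (n={n}, m={m})")
    yc = y - y.mean(axis=0)
    ss_tot = float((yc ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("response: zero total variance")
    q, _ = np.linalg.qr(xc)
    ss_fit = _fit_ss(q, yc)
    ss_res = ss_tot - ss_fit
    r2 = ss_fit / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    f_stat = (ss_fit / m) / (ss_res / (n - m - 1)) if ss_res > 0 else np.inf

    perm_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            ss_f = _fit_ss(q, yp)
            ss_r = ss_tot - ss_f
            f_p = (ss_f / m) / (ss_r / (n - m - 1)) if ss_r > 0 else np.inf
            hits += f_p >= f_stat - 1e-12
        perm_p = (1 + hits) / (1 + n_perm)

    fitted = q @ (q.T @ yc)
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    k = min(m, len(s))
    return RdaResult(r2=r2, adj_r2=adj_r2, f_stat=f_stat, perm_p=perm_p,
                     site_scores=u[:, :k] * s[:k],
                     eigenvalues=(s[:k] ** 2) / (n - 1), n=n, m=m)


# ---------------------------------------------------------------- varpart

@dataclass
class VarpartResult:
    """Adjusted-R² decomposition over up to 4 predictor blocks.

    ``fractions`` maps each exclusive fraction label ("geography",
    "geography&host_class", ...) to its adjusted R²; together with
    ``residual`` they sum to 1.  ``unique`` are the singleton ("solely
    explained") fractions, ``with_interactions`` the marginal adjusted R²
    of each block alone (the block plus every interaction involving it).
    """

    fractions: dict[str, float]
    residual: float
    unique: dict[str, float]
    with_interactions: dict[str, float]
    subset_adj_r2: dict[str, float]
    unique_p: dict[str, float] = field(default_factory=dict)
    total_adj_r2: float = 0.0

    def as_dict(self) -> dict:
        return {
            "fractions": {k: float(v) for k, v in self.fractions.items()},
            "residual": float(self.residual),
            "unique": {k: float(v) for k, v in self.unique.items()},
            "with_interactions": {k: float(v)
                                  for k, v in self.with_interactions.items()},
            "unique_p": {k: float(v) for k, v in self.unique_p.items()},
            "total_adj_r2": float(self.total_adj_r2),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [(label, val, self.unique_p.get(label, np.nan))
                for label, val in self.fractions.items()]
        rows.append(("residual", self.residual, np.nan))
        return pd.DataFrame(rows, columns=["fraction", "adj_r2", "perm_p"])


def _adj(r2: float, n: int, m: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def varpart4(response, blocks: dict[str, "pd.DataFrame | np.ndarray"],
             n_perm: int = 1000, seed: int | None = None) -> VarpartResult:
    """Variation partitioning of adjusted R² across 2-4 predictor blocks.

    Fits every non-empty subset of blocks, converts each subset R² to an
    Ezekiel-adjusted R², and solves the inclusion-exclusion system for the
    exclusive fractions (negative values are legitimate and reported
    as-is).  ``unique_p`` holds permutation p-values for each block's
    unique fraction (partial pseudo-F with the other blocks as
    conditioning set, free row permutation of the response).
    """
    names = list(blocks)
    if not 2 <= len(names) <= 4:
        raise ValidationError("blocks: varpart needs 2-4 blocks")
    y = _as_matrix(response)
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    ss_tot = float((yc ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("response: zero total variance")

    mats, col_names = {}, {}
    for name in names:
        arr, cols = _design_array(blocks[name])
        if arr.shape[0] != n:
            raise ValidationError(f"blocks: block {name!r} disagrees on n")
        mats[name] = arr - arr.mean(axis=0)
        col_names[name] = [f"{name}:{c}" for c in cols]

    subsets = [frozenset(c) for k in range(1, len(names) + 1)
               for c in combinations(names, k)]

    def label(s: frozenset) -> str:
        return "&".join(sorted(s, key=names.index))

    adj_r2: dict[frozenset, float] = {}
    qs: dict[frozenset, tuple[np.ndarray, int]] = {}
    for s in subsets:
        xc = np.hstack([mats[b] for b in names if b in s])
        cn = sum((col_names[b] for b in names if b in s), [])
        m = _check_rank(xc, cn)
        if n <= m + 1:
            raise ValidationError(
                f"blocks: subset {label(s)} leaves no residual df")
        q, _ = np.linalg.qr(xc)
        r2 = _fit_ss(q, yc) / ss_tot
        adj_r2[s] = _adj(r2, n, m)
        qs[s] = (q, m)

    # exclusive fractions f_S solve  adjR2(U) = sum_{S: S ∩ U != ∅} f_S
    mat = np.array([[1.0 if s & u else 0.0 for s in subsets] for u in subsets])
    f = np.linalg.solve(mat, np.array([adj_r2[u] for u in subsets]))
    fractions = {label(s): float(v) for s, v in zip(subsets, f)}
    full = frozenset(names)
    residual = 1.0 - adj_r2[full]
    unique = {b: fractions[b] for b in names}
    with_inter = {b: adj_r2[frozenset([b])] for b in names}

    unique_p: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        q_full, m_full = qs[full]
        df_res = n - m_full - 1
        for b in names:
            others = full - {b}
            q_oth, m_oth = qs[others] if others else (np.zeros((n, 0)), 0)
            df_b = m_full - m_oth

            def partial_f(ymat: np.ndarray) -> float:
                ss_full = _fit_ss(q_full, ymat)
                ss_oth = _fit_ss(q_oth, ymat)
                ss_res = ss_tot - ss_full
                if ss_res <= 0:
                    return np.inf
                return ((ss_full - ss_oth) / df_b) / (ss_res / df_res)

            f_obs = partial_f(yc)
            hits = 0
            for _ in range(n_perm):
                hits += partial_f(yc[rng.permutation(n)]) >= f_obs - 1e-12
            unique_p[b] = (1 + hits) / (1 + n_perm)

    return VarpartResult(fractions=fractions, residual=float(residual),
                         unique=unique, with_interactions=with_inter,
                         subset_adj_r2={label(s): float(adj_r2[s])
                                        for s in subsets},
                         unique_p=unique_p,
                         total_adj_r2=float(adj_r2[full]))


def drop_aliased_blocks(blocks: dict[str, "pd.DataFrame | np.ndarray"],
                        ) -> tuple[dict, list[str]]:
    """Split blocks into a full-rank subset and fully aliased leftovers.

    Blocks are admitted in the given order; a block whose centred columns
    add no rank to the design built so far (e.g. depth when only two vents
    are sampled and depth is a function of vent) is reported as aliased.
    Correlation short of exact collinearity never drops a block.
    """
    kept: dict = {}
    aliased: list[str] = []
    design: np.ndarray | None = None
    for name, block in blocks.items():
        arr, _ = _design_array(block)
        arr = arr - arr.mean(axis=0)
        trial = arr if design is None else np.hstack([design, arr])
        base_rank = 0 if design is None else np.linalg.matrix_rank(design)
        if np.linalg.matrix_rank(trial) == base_rank + np.linalg.matrix_rank(arr):
            kept[name] = block
            design = trial
        else:
            aliased.append(name)
    return kept, aliased


# ------------------------------------------------------------------- NMDS

@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    stress_path: list[float]
    all_final_stress: list[float]
    best_restart: int
    converged: bool


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def nmds(distances: DistanceMatrix, k: int = 2, n_restarts: int = 4,
         max_iter: int = 300, tol: float = 1e-7, seed: int | None = None,
         ) -> NmdsResult:
    """Kruskal non-metric MDS via SMACOF with isotonic disparities.

    Minimises stress-1 = sqrt(sum (d - dhat)^2 / sum d^2) where the
    disparities ``dhat`` are a monotone regression of the configuration
    distances on the input dissimilarities (disparities rescaled to the
    configuration's sum of squares).  The first restart starts from the
    classical-scaling solution, the rest from seeded Gaussian noise; the
    recorded stress path of every restart is non-increasing.
    """
    n = distances.shape[0]
    if not 1 <= k < n - 1:
        raise ValidationError(f"k: need 1 <= k < n - 1 (k={k}, n={n})")
    dvec = distances.condensed_form()
    if np.ptp(dvec) == 0:
        raise ValidationError("distances: all pairwise values equal")
    order = np.argsort(dvec, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best: tuple[float, np.ndarray, list[float], int, bool] | None = None
    finals = []
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            x = _classical_scaling(distances.data, k)
            if np.allclose(x, 0):
                x = rng.normal(size=(n, k))
        else:
            x = rng.normal(size=(n, k))
        path: list[float] = []
        converged = False
        prev = np.inf
        x_prev = x
        for _ in range(max_iter):
            d = pdist(x)
            dsum2 = float((d ** 2).sum())
            if dsum2 == 0:
                break
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            dhat *= np.sqrt(dsum2 / max((dhat ** 2).sum(), 1e-300))
            stress = math.sqrt(max(((d - dhat) ** 2).sum(), 0.0) / dsum2)
            if stress > prev + 1e-12:   # majorization guard
                x = x_prev
                break
            path.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            x_prev = x
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            bmat = -squareform(ratio)
            np.fill_diagonal(bmat, -bmat.sum(axis=1))
            x = (bmat @ x) / n
        final = path[-1] if path else np.inf
        finals.append(final)
        if best is None or final < best[0]:
            best = (final, x, path, restart, converged)

    assert best is not None
    stress, x, path, restart, converged = best
    coords = pd.DataFrame(x, index=list(distances.ids),
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return NmdsResult(coordinates=coords, stress=float(stress),
                      stress_path=path, all_final_stress=finals,
                      best_restart=restart, converged=converged)


# ------------------------------------------------------------- predictors

@dataclass
class PredictorBlocks:
    """The four explanatory blocks of the ridge-transect RDA."""

    blocks: dict[str, pd.DataFrame]
    correlations: pd.DataFrame
    collinear_pairs: list[tuple[str, str, float]]
    non_testable: list[str]

    def design(self, names: list[str] | None = None) -> pd.DataFrame:
        use = names or [n for n in self.blocks if n not in self.non_testable]
        return pd.concat([self.blocks[n] for n in use], axis=1)

    def testable_blocks(self) -> dict[str, pd.DataFrame]:
        return {n: b for n, b in self.blocks.items()
                if n not in self.non_testable}


def build_predictors(metadata: pd.DataFrame) -> PredictorBlocks:
    """Construct geography / depth / host-class / vent-type blocks.

    Geography is a single along-ridge coordinate: vents are ordered by
    latitude (north first) and each sample gets the cumulative great-circle
    distance from the northernmost vent to its vent.  Host class becomes
    0/1 indicator column(s) (one per non-reference level); vent type is
    0 = basalt, 1 = ultramafic.  Constant blocks (e.g. geography with a
    single vent) are flagged non-testable rather than dropped silently.
    """
    required = ["host_class", "vent_field", "lat", "lon", "depth_m", "vent_type"]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise ValidationError(f"metadata: missing columns {missing}")
    if metadata[["lat", "lon"]].isna().any().any():
        raise ValidationError("metadata: missing coordinates")

    vents = (metadata[["vent_field", "lat", "lon"]]
             .drop_duplicates("vent_field")
             .sort_values("lat", ascending=False)
             .reset_index(drop=True))
    along = {vents.loc[0, "vent_field"]: 0.0}
    total = 0.0
    for i in range(1, len(vents)):
        total += haversine_km(vents.loc[i - 1, "lat"], vents.loc[i - 1, "lon"],
                              vents.loc[i, "lat"], vents.loc[i, "lon"])
        along[vents.loc[i, "vent_field"]] = total

    idx = metadata.index
    geo = pd.DataFrame({"along_ridge_km":
                        metadata["vent_field"].map(along).astype(float)},
                       index=idx)
    depth = pd.DataFrame({"depth_m": metadata["depth_m"].astype(float)},
                         index=idx)
    vt = pd.DataFrame({"ultramafic":
                       (metadata["vent_type"] == "ultramafic").astype(float)},
                      index=idx)
    levels = sorted(metadata["host_class"].unique())
    host = pd.DataFrame({f"host_{lv}":
                         (metadata["host_class"] == lv).astype(float)
                         for lv in levels[1:]}, index=idx)
    if host.shape[1] == 0:
        host = pd.DataFrame({"host_constant": np.zeros(len(idx))}, index=idx)

    blocks = {"geography": geo, "depth": depth, "host_class": host,
              "vent_type": vt}
    non_testable = [name for name, b in blocks.items()
                    if np.all(np.ptp(b.to_numpy(dtype=float), axis=0) == 0)]

    reps = pd.DataFrame({
        "geography": geo.iloc[:, 0],
        "depth": depth.iloc[:, 0],
        "host_class": host.iloc[:, 0],
        "vent_type": vt.iloc[:, 0],
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = reps.corr()
    collinear = [(a, b, float(corr.loc[a, b]))
                 for a, b in combinations(corr.columns, 2)
                 if abs(corr.loc[a, b]) > COLLINEARITY_FLAG]
    return PredictorBlocks(blocks=blocks, correlations=corr,
                           collinear_pairs=collinear,
                           non_testable=non_testable)
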