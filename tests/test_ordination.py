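"""RDA, variation partitioning, NMDS, and predictor construction."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_score

from symbiopop import (ValidationError, build_predictors, call_snps,
                       haversine_km, impute_frequencies, nmds, rda,
                       simulate_dataset, varpart4)
from symbiopop.datatypes import AlleleFrequencyMatrix

from conftest import small_config


def rng_xy(seed=0, n=20, p=3, q=5):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    beta = rng.normal(size=(p, q))
    y = x @ beta + rng.normal(scale=2.0, size=(n, q))
    return x, y


# --------------------------------------------------------------------- RDA

def test_univariate_rda_r2_equals_closed_form_regression():
    rng = np.random.default_rng(1)
    n = 25
    x = rng.normal(size=(n, 3))
    y = x @ [1.0, -2.0, 0.5] + rng.normal(size=n)
    res = rda(y, x, n_perm=0)
    xc = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
    fitted = xc @ beta
    r2_closed = 1 - ((y - fitted) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    assert res.r2 == pytest.approx(r2_closed, abs=1e-10)
    adj_closed = 1 - (1 - r2_closed) * (n - 1) / (n - 3 - 1)
    assert res.adj_r2 == pytest.approx(adj_closed, abs=1e-10)


def test_rda_invariant_under_invertible_reparameterization():
    x, y = rng_xy(2)
    rng = np.random.default_rng(3)
    a = rng.normal(size=(3, 3))
    while abs(np.linalg.det(a)) < 1e-3:
        a = rng.normal(size=(3, 3))
    r1 = rda(y, x, n_perm=0)
    r2 = rda(y, x @ a, n_perm=0)
    assert r2.r2 == pytest.approx(r1.r2, abs=1e-10)
    assert r2.adj_r2 == pytest.approx(r1.adj_r2, abs=1e-10)


def test_orthogonal_predictors_explain_nothing():
    rng = np.random.default_rng(4)
    n = 30
    y = rng.normal(size=(n, 4))
    yc = y - y.mean(axis=0)
    # build predictors in the orthogonal complement of the response columns
    q, _ = np.linalg.qr(yc)
    proj = np.eye(n) - q @ q.T
    x = proj @ rng.normal(size=(n, 2))
    res = rda(y, x, n_perm=0)
    assert res.r2 == pytest.approx(0.0, abs=1e-10)
    assert res.adj_r2 <= 0


def test_rda_permutation_resolution_and_determinism():
    x, y = rng_xy(5, n=15)
    r1 = rda(y, x, n_perm=1000, seed=9)
    r2 = rda(y, x, n_perm=1000, seed=9)
    assert r1.perm_p == r2.perm_p
    assert round(r1.perm_p * 1001) == pytest.approx(r1.perm_p * 1001)
    assert 1 / 1001 <= r1.perm_p <= 1.0


def test_rank_deficient_design_names_collinear_columns():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(20, 2))
    bad = pd.DataFrame(np.column_stack([x, x[:, 0] + x[:, 1]]),
                       columns=["a", "b", "c"])
    with pytest.raises(ValidationError, match="c"):
        rda(rng.normal(size=(20, 3)), bad, n_perm=0)


# ----------------------------------------------------------------- varpart

def blocks_from(seed=7, n=30):
    rng = np.random.default_rng(seed)
    return {f"b{k}": rng.normal(size=(n, dims))
            for k, dims in enumerate((1, 2, 1, 1))}


def test_varpart_fractions_sum_to_one():
    blocks = blocks_from()
    rng = np.random.default_rng(8)
    y = rng.normal(size=(30, 6))
    res = varpart4(y, blocks, n_perm=0)
    assert len(res.fractions) == 15
    total = sum(res.fractions.values()) + res.residual
    assert total == pytest.approx(1.0, abs=1e-9)


def test_varpart_recovers_single_generating_block():
    rng = np.random.default_rng(9)
    n = 150
    blocks = {name: rng.normal(size=(n, 1))
              for name in ("geography", "depth", "host", "vent")}
    noise = rng.normal(scale=1.0, size=(n, 5))
    y = blocks["geography"] @ rng.normal(size=(1, 5)) * 2.0 + noise
    res = varpart4(y, blocks, n_perm=0)
    generating = rda(y, blocks["geography"], n_perm=0).adj_r2
    assert res.unique["geography"] == pytest.approx(generating, abs=0.05)
    for other in ("depth", "host", "vent"):
        assert abs(res.unique[other]) < 0.05


def test_duplicated_blocks_share_their_variance():
    rng = np.random.default_rng(10)
    n = 50
    g = rng.normal(size=(n, 1))
    y = g @ rng.normal(size=(1, 4)) + rng.normal(scale=0.5, size=(n, 4))
    jitter = g + rng.normal(scale=1e-6, size=(n, 1))  # near-duplicate block
    blocks = {"g1": g, "g2": jitter, "noise": rng.normal(size=(n, 1))}
    res = varpart4(y, blocks, n_perm=0)
    assert abs(res.unique["g1"]) < 0.02
    assert abs(res.unique["g2"]) < 0.02
    assert res.fractions["g1&g2"] > 0.5


def test_varpart_consistent_under_block_merging():
    rng = np.random.default_rng(11)
    n = 40
    blocks = {"a": rng.normal(size=(n, 2)), "b": rng.normal(size=(n, 1)),
              "c": rng.normal(size=(n, 1))}
    y = rng.normal(size=(n, 3))
    three = varpart4(y, blocks, n_perm=0)
    merged = {"ab": np.hstack([blocks["a"], blocks["b"]]), "c": blocks["c"]}
    two = varpart4(y, merged, n_perm=0)
    assert two.unique["c"] == pytest.approx(three.unique["c"], abs=1e-10)
    assert two.total_adj_r2 == pytest.approx(three.total_adj_r2, abs=1e-10)


def test_varpart_matches_r_vegan_on_small_fixture(tmp_path):
    """Independent oracle: vegan::varpart / RsquareAdj on the same data."""
    rng = np.random.default_rng(12)
    n = 18
    x1 = rng.normal(size=(n, 2))
    x2 = rng.normal(size=(n, 1))
    y = (x1 @ rng.normal(size=(2, 4)) + x2 @ rng.normal(size=(1, 4))
         + rng.normal(size=(n, 4)))
    for name, arr in (("y.csv", y), ("x1.csv", x1), ("x2.csv", x2)):
        pd.DataFrame(arr).to_csv(tmp_path / name, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(vegan))
        Y <- as.matrix(read.csv("{tmp_path}/y.csv"))
        X1 <- as.matrix(read.csv("{tmp_path}/x1.csv"))
        X2 <- as.matrix(read.csv("{tmp_path}/x2.csv"))
        m <- rda(Y, cbind(X1, X2))
        adj <- RsquareAdj(m)
        v <- varpart(Y, X1, X2)
        fr <- v$part$indfract$Adj.R.square
        cat(sprintf("%.12f\\n", c(adj$r.squared, adj$adj.r.squared, fr)))
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    # vegan indfract rows: [a] = X1|X2, [b] = X2|X1, [c] = shared, [d] = resid
    r2_ref, adj_ref, fa, fb, fc, fd = map(float, out.stdout.split())
    ours = varpart4(y, {"x1": x1, "x2": x2}, n_perm=0)
    full = rda(y, np.hstack([x1, x2]), n_perm=0)
    assert full.r2 == pytest.approx(r2_ref, abs=1e-9)
    assert full.adj_r2 == pytest.approx(adj_ref, abs=1e-9)
    assert ours.fractions["x1"] == pytest.approx(fa, abs=1e-9)
    assert ours.fractions["x2"] == pytest.approx(fb, abs=1e-9)
    assert ours.fractions["x1&x2"] == pytest.approx(fc, abs=1e-9)
    assert ours.residual == pytest.approx(fd, abs=1e-9)


# -------------------------------------------------------------------- NMDS

def test_nmds_recovers_exact_two_dimensional_configuration():
    rng = np.random.default_rng(13)
    pts = rng.normal(size=(12, 2))
    dm = DistanceMatrix(squareform(pdist(pts)),
                        ids=[f"s{k}" for k in range(12)])
    res = nmds(dm, k=2, n_restarts=3, seed=0)
    assert res.stress < 0.01
    _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
    assert disparity < 1e-3
    assert res.converged


def test_nmds_stress_non_increasing_within_restart():
    rng = np.random.default_rng(14)
    dm = DistanceMatrix(squareform(pdist(rng.normal(size=(10, 5)))),
                        ids=[f"s{k}" for k in range(10)])
    res = nmds(dm, k=2, n_restarts=4, seed=1)
    path = np.asarray(res.stress_path)
    assert (np.diff(path) <= 1e-12).all()


def test_nmds_input_validation():
    rng = np.random.default_rng(15)
    dm = DistanceMatrix(squareform(pdist(rng.normal(size=(5, 2)))),
                        ids=list("abcde"))
    with pytest.raises(ValidationError, match="k"):
        nmds(dm, k=4)
    degenerate = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
    with pytest.raises(ValidationError, match="equal"):
        nmds(degenerate, k=2)


def test_samples_cluster_by_vent_not_host_class():
    ds = simulate_dataset(small_config(mc_seed=17))
    freqs = call_snps(ds.counts, 5, 0.02, 0.8)
    dm = DistanceMatrix(squareform(pdist(impute_frequencies(freqs))),
                        ids=list(freqs.samples))
    res = nmds(dm, k=2, seed=2)
    coords = res.coordinates.to_numpy()
    by_vent = silhouette_score(coords, ds.metadata["vent_field"])
    by_class = silhouette_score(coords, ds.metadata["host_class"])
    assert by_vent > by_class


# -------------------------------------------------------------- predictors

def meta_frame(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "host_class", "vent_field",
                                     "lat", "lon", "depth_m", "vent_type",
                                     "year"])
    return df.set_index("sample_id")


def test_single_vent_geography_flagged_non_testable():
    meta = meta_frame([("a", "parental", "V", 29.0, -43.0, 3000, "basalt", 1997),
                       ("b", "hybrid", "V", 29.0, -43.0, 3000, "basalt", 2001)])
    blocks = build_predictors(meta)
    assert "geography" in blocks.non_testable
    assert "depth" in blocks.non_testable
    assert "host_class" not in blocks.non_testable


def test_one_degree_latitude_is_111_km():
    assert haversine_km(30.0, -43.0, 31.0, -43.0) == pytest.approx(111.195,
                                                                   abs=0.05)
    meta = meta_frame([("a", "parental", "N", 31.0, -43.0, 1000, "basalt", 1997),
                       ("b", "hybrid", "S", 30.0, -43.0, 2000, "basalt", 1997)])
    blocks = build_predictors(meta)
    geo = blocks.blocks["geography"]["along_ridge_km"]
    assert geo["a"] == 0.0
    assert geo["b"] == pytest.approx(111.2, abs=0.1)


def test_monotone_depth_latitude_fixture_triggers_collinearity_flag():
    rows = [(f"s{k}", "parental", f"V{k}", 38.0 - k, -33.0, 800 + 300 * k,
             "basalt", 1997) for k in range(6)]
    blocks = build_predictors(meta_frame(rows))
    flagged = {frozenset(p[:2]) for p in blocks.collinear_pairs}
    assert frozenset(("geography", "depth")) in flagged
    assert abs(blocks.correlations.loc["geography", "depth"]) > 0.8


def test_imputation_preserves_complete_columns():
    sites = pd.DataFrame({"site_id": ["s1", "s2"], "gene_id": ["g", "g"],
                          "pos": [0, 1], "ref": ["A", "A"], "alt": ["T", "T"]})
    freq = np.array([[0.2, 0.5], [np.nan, 0.7]])
    depth = np.array([[10, 10], [1, 10]])
    fm = AlleleFrequencyMatrix(samples=["a", "b"], sites=sites, freq=freq,
                               depth=depth, min_depth=5)
    imputed = impute_frequencies(fm)
    assert imputed.shape == freq.shape
    np.testing.assert_allclose(imputed[:, 1], [0.5, 0.7])  # untouched
    assert imputed[1, 0] == pytest.approx(0.2)  # per-site mean
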