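"""Mantel, per-gene contrasts, CLR abundance, Fisher presence, and BH."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from symbiopop import (ValidationError, benjamini_hochberg,
                       clr_diff_abundance, fst_between_within_test, mantel,
                       presence_absence_test)
from symbiopop.stats import clr_transform


def random_dm(rng, n, ids=None):
    m = rng.uniform(0, 1, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(m, ids=ids or [f"s{k}" for k in range(n)])


# ------------------------------------------------------------------- Mantel

def test_mantel_identity_and_affine_transform_give_r_one():
    rng = np.random.default_rng(0)
    d1 = random_dm(rng, 8)
    assert mantel(d1, d1, n_perm=99, seed=1).r == pytest.approx(1.0)
    affine = DistanceMatrix(2.5 * d1.data + 1.0 * (1 - np.eye(8)),
                            ids=d1.ids)
    assert mantel(d1, affine, n_perm=99, seed=1).r == pytest.approx(1.0)


def test_mantel_r_matches_skbio_oracle():
    rng = np.random.default_rng(2)
    d1, d2 = random_dm(rng, 10), random_dm(rng, 10)
    ours = mantel(d1, d2, n_perm=99, seed=0)
    r_ref, _, n_ref = skbio_mantel(d1, d2, method="pearson", permutations=0)
    assert ours.r == pytest.approx(float(r_ref), abs=1e-12)
    assert ours.n == n_ref


def test_mantel_seeded_determinism_and_plus_one_correction():
    rng = np.random.default_rng(3)
    d1, d2 = random_dm(rng, 9), random_dm(rng, 9)
    a = mantel(d1, d2, n_perm=199, seed=42)
    b = mantel(d1, d2, n_perm=199, seed=42)
    assert (a.r, a.p) == (b.r, b.p)
    assert a.p >= 1 / 200  # +1 correction: never exactly 0
    # perfect self-correlation: only ties can reach r = 1
    assert mantel(d1, d1, n_perm=199, seed=0).p <= 0.05


def test_mantel_invariant_to_joint_relabelling():
    rng = np.random.default_rng(4)
    d1, d2 = random_dm(rng, 8), random_dm(rng, 8)
    perm = rng.permutation(8)
    ids = [d1.ids[k] for k in perm]
    d1p = DistanceMatrix(d1.data[np.ix_(perm, perm)], ids=ids)
    d2p = DistanceMatrix(d2.data[np.ix_(perm, perm)], ids=ids)
    a = mantel(d1, d2, n_perm=299, seed=5)
    b = mantel(d1p, d2p, n_perm=299, seed=5)
    assert b.r == pytest.approx(a.r, abs=1e-12)
    assert abs(a.p - b.p) < 0.06  # same null distribution, resampled


def test_mantel_errors():
    rng = np.random.default_rng(6)
    d1 = random_dm(rng, 5)
    d2 = random_dm(rng, 5, ids=list("vwxyz"))
    with pytest.raises(ValidationError, match="labels"):
        mantel(d1, d2)
    const = DistanceMatrix(1 - np.eye(5), ids=d1.ids)
    with pytest.raises(ValidationError, match="constant"):
        mantel(d1, const, n_perm=9)


# -------------------------------------------------- Mann-Whitney per gene

def brute_force_u(x, y):
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def make_gene_table(values_by_pair):
    rows = [(g, i, j, v, 1) for (g, i, j), v in values_by_pair.items()]
    return pd.DataFrame(rows, columns=["gene_id", "sample_i", "sample_j",
                                       "fst", "n_sites"])


def test_u_statistic_equals_exhaustive_rank_oracle():
    rng = np.random.default_rng(7)
    samples = [f"h{k}" for k in range(4)]
    classes = pd.Series({"h0": "parental", "h1": "parental",
                         "h2": "hybrid", "h3": "hybrid"})
    vals = {("g1", a, b): float(rng.normal())
            for a, b in itertools.combinations(samples, 2)}
    table = make_gene_table(vals)
    res = fst_between_within_test(table, classes)
    between = [v for (g, a, b), v in vals.items()
               if classes[a] != classes[b]]
    within = [v for (g, a, b), v in vals.items()
              if classes[a] == classes[b]]
    assert res["statistic"].iloc[0] == pytest.approx(
        brute_force_u(between, within))


def test_identical_between_within_sets_are_null():
    samples = [f"h{k}" for k in range(6)]
    classes = pd.Series({s: ("parental" if k < 3 else "hybrid")
                         for k, s in enumerate(samples)})
    vals = {("g1", a, b): 0.25
            for a, b in itertools.combinations(samples, 2)}
    res = fst_between_within_test(make_gene_table(vals), classes)
    assert res["p"].iloc[0] > 0.99
    n_b, n_w = res["n_between"].iloc[0], res["n_within"].iloc[0]
    assert res["statistic"].iloc[0] == pytest.approx(n_b * n_w / 2)


def test_single_class_input_rejected():
    vals = {("g1", "a", "b"): 0.1}
    with pytest.raises(ValidationError, match="2 classes"):
        fst_between_within_test(make_gene_table(vals),
                                pd.Series({"a": "x", "b": "x"}))


def test_undersized_genes_marked_non_testable():
    classes = pd.Series({"a": "p", "b": "p", "c": "h", "d": "h"})
    vals = {("g1", "a", "b"): 0.1, ("g1", "a", "c"): 0.2}
    res = fst_between_within_test(make_gene_table(vals), classes)
    assert not res["tested"].iloc[0]
    assert np.isnan(res["q"].iloc[0])


# --------------------------------------------------------------------- BH

def brute_force_bh(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = running
    return q


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
def test_bh_equals_step_up_oracle(p):
    p = np.asarray(p)
    np.testing.assert_allclose(benjamini_hochberg(p), brute_force_bh(p),
                               atol=1e-12)


# ------------------------------------------------------------------ Fisher

def exhaustive_fisher(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize("table", [(10, 0, 0, 10), (3, 5, 6, 2),
                                   (1, 11, 7, 4), (6, 6, 6, 6), (0, 4, 9, 3)])
def test_fisher_p_matches_hypergeometric_enumeration(table):
    a, b, c, d = table
    pres = [True] * a + [False] * b + [True] * c + [False] * d
    classes = pd.Series(["x"] * (a + b) + ["y"] * (c + d),
                        index=[f"s{k}" for k in range(a + b + c + d)])
    frame = pd.DataFrame({"gene": pres}, index=classes.index)
    res = presence_absence_test(frame, classes)
    assert res["p"].iloc[0] == pytest.approx(exhaustive_fisher(a, b, c, d),
                                             rel=1e-9)


def test_fisher_label_swap_symmetry_and_skip_rules():
    rng = np.random.default_rng(8)
    pres = pd.DataFrame(rng.random((12, 6)) < 0.5,
                        index=[f"s{k}" for k in range(12)],
                        columns=[f"g{k}" for k in range(6)])
    pres["g0"] = True   # present everywhere -> skipped
    classes = pd.Series(["x"] * 6 + ["y"] * 6, index=pres.index)
    res = presence_absence_test(pres, classes)
    assert not res.set_index("gene_id").loc["g0", "tested"]
    swapped = classes.map({"x": "y", "y": "x"})
    res2 = presence_absence_test(pres, swapped)
    np.testing.assert_allclose(res["p"].to_numpy(dtype=float),
                               res2["p"].to_numpy(dtype=float), atol=1e-12)


# --------------------------------------------------------------------- CLR

def test_clr_rows_sum_to_zero():
    rng = np.random.default_rng(9)
    gam = rng.standard_gamma(1.0, size=(10, 30))
    prop = gam / gam.sum(axis=1, keepdims=True)
    assert np.abs(clr_transform(prop).sum(axis=1)).max() < 1e-9


def test_identical_count_rows_yield_no_discoveries():
    counts = pd.DataFrame(np.tile([100, 50, 25, 200, 10], (12, 1)),
                          index=[f"s{k}" for k in range(12)],
                          columns=[f"g{k}" for k in range(5)])
    classes = pd.Series(["x"] * 6 + ["y"] * 6, index=counts.index)
    res = clr_diff_abundance(counts, classes, n_mc=64, seed=0)
    assert int(res["significant"].sum()) == 0
    assert (res["q"] > 0.3).all()


def test_spiked_gene_detected_with_high_power():
    """An 8-fold abundance shift of one gene (10 vs 10 samples, depth 1e4)
    is detected at q < 0.05 in >= 90% of seeded runs."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        base = np.ones(50)
        spiked = base.copy()
        spiked[0] *= 8
        rows = [rng.multinomial(10_000, base / base.sum()) for _ in range(10)]
        rows += [rng.multinomial(10_000, spiked / spiked.sum())
                 for _ in range(10)]
        counts = pd.DataFrame(rows, index=[f"s{k}" for k in range(20)],
                              columns=[f"g{k}" for k in range(50)])
        classes = pd.Series(["x"] * 10 + ["y"] * 10, index=counts.index)
        res = clr_diff_abundance(counts, classes, n_mc=64, seed=seed)
        row = res.set_index("gene_id").loc["g0"]
        hits += bool(row["significant"]) and row["direction"] == "higher_in_y"
    assert hits >= 0.9 * n_seeds


def test_all_zero_sample_row_rejected():
    counts = pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"],
                          columns=["g0", "g1"])
    with pytest.raises(ValidationError, match="all-zero"):
        clr_diff_abundance(counts, pd.Series({"a": "x", "b": "y"}))
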