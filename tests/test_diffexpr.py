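"""Tests of nested model fits, permutation/chi-squared nulls, BH adjustment,
XDE classification and DE-pattern clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

import trajdiff as td
from trajdiff.diffexpr import classify_xde, fit_nested_models, fit_tde_models


def _sim_obs(rng, S=8, C=150, K=3, B0=None, Bv=None, sigma=0.5, omega_sd=0.0):
    basis = td.make_basis(K)
    x = np.c_[np.ones(S), (np.arange(S) % 2).astype(float)]
    B0 = rng.normal(0, 1, K + 1) if B0 is None else np.asarray(B0, float)
    Bv = np.zeros(K + 1) if Bv is None else np.asarray(Bv, float)
    ys, ts = [], []
    for s in range(S):
        t = rng.uniform(0, 1, C)
        u = rng.normal(0, omega_sd, K + 1)
        ys.append(basis(t) @ (B0 + x[s, 1] * Bv + u)
                  + rng.normal(0, sigma, C))
        ts.append(t)
    return td.GeneObservations(ys, ts, [f"s{j}" for j in range(S)]), x


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_hand_example():
    np.testing.assert_allclose(td.bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])
    assert td.bh_adjust([0.4])[0] == 0.4


def test_bh_matches_reference_implementation(rng):
    p = rng.uniform(0, 1, 1000)
    ours = td.bh_adjust(p)
    _, ref, *_ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(ours, ref, rtol=0, atol=1e-14)


def test_bh_passes_nans_through():
    q = td.bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(q[1]) and np.isfinite(q[0])


# ---------------------------------------------------------------------------
# Chi-squared reference
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("df", [1, 2, 3, 5, 10])
def test_chisq_pvalue_matches_survival_oracle(df):
    llr = df / 2.0  # so 2*LLR == df
    assert td.chisq_pvalue(llr, df) == pytest.approx(chi2.sf(df, df),
                                                     abs=1e-10)
    assert td.chisq_pvalue(0.0, df) == 1.0


def test_nested_df_counts(rng):
    obs, x = _sim_obs(rng, K=4)
    nf = fit_nested_models(obs, x, 1, 4, tol=1e-3, max_iter=60)
    assert nf.df("overall") == 5
    assert nf.df("mean") == 1
    assert nf.df("trend") == 4


# ---------------------------------------------------------------------------
# Nested fits
# ---------------------------------------------------------------------------

def test_loglik_ordering_on_random_fixtures():
    for rep in range(10):
        rng = np.random.default_rng(rep)
        obs, x = _sim_obs(rng, K=int(rng.integers(1, 4)),
                          omega_sd=0.2, C=80)
        nf = fit_nested_models(obs, x, 1, obs_K := len(obs.y[0]) * 0 + 2,
                               tol=1e-4, max_iter=100)
        assert nf.logliks["m0"] <= nf.logliks["m1"] + 1e-4
        assert nf.logliks["m1"] <= nf.logliks["m2"] + 1e-4
        assert all(v >= 0 for v in nf.llr.values())


def test_null_llr_matches_chisq_scale():
    """Under M0 (no covariate effect, no random effects), the median of
    2*LLR(M2:M0) sits near the chi-squared median with K+1 df."""
    K = 3
    llrs = []
    for rep in range(80):
        rng = np.random.default_rng(rep)
        obs, x = _sim_obs(rng, K=K, omega_sd=0.0)
        nf = fit_nested_models(obs, x, 1, K, tol=1e-4, max_iter=150)
        llrs.append(nf.llr["overall"])
    med = np.median(2 * np.array(llrs))
    assert 0.5 * chi2.median(K + 1) <= med <= 1.4 * chi2.median(K + 1)


def test_pure_shift_loads_on_mean_not_trend(rng):
    K = 3
    obs, x = _sim_obs(rng, K=K, Bv=np.full(K + 1, 2.0), sigma=0.4)
    nf = fit_nested_models(obs, x, 1, K, tol=1e-4, max_iter=150)
    assert nf.llr["mean"] > 20
    assert td.chisq_pvalue(nf.llr["mean"], 1) < 1e-6
    # trend component stays at null scale
    assert 2 * nf.llr["trend"] < chi2.ppf(0.999, K)


def test_covariate_constant_rejected(rng):
    obs, _ = _sim_obs(rng)
    x_const = np.c_[np.ones(8), np.ones(8)]
    with pytest.raises(ValueError):
        fit_nested_models(obs, x_const, 1, 2)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def test_kde_tail_extremes(rng):
    null = rng.normal(0, 1, 100)
    assert td.kde_tail_pvalue(50.0, null) < 0.01
    assert td.kde_tail_pvalue(float(np.median(null)), null) == pytest.approx(
        0.5, abs=0.1)
    assert td.kde_tail_pvalue(1e9, null) >= 1e-300


def test_permutation_engine_calibrated():
    """When observed and permuted statistics share a distribution, the
    permutation p-values are uniform (KS check)."""
    pvals = []
    for rep in range(400):
        rng0 = np.random.default_rng(rep)
        obs_stat = rng0.normal()
        p = td.permutation_null_pvalue(
            obs_stat, lambda rng: rng.normal(), scheme="xde",
            n_perm=50, seed=rep + 1)
        pvals.append(p)
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_permutation_engine_guards():
    with pytest.raises(ValueError):
        td.permutation_null_pvalue(1.0, lambda rng: 0.0, n_perm=5)
    with pytest.raises(ValueError):
        td.permutation_null_pvalue(1.0, lambda rng: 0.0, scheme="bogus")

    def flaky(rng):
        raise RuntimeError("boom")

    with pytest.raises(RuntimeError):
        td.permutation_null_pvalue(1.0, flaky, n_perm=20, seed=0)


# ---------------------------------------------------------------------------
# XDE pipeline
# ---------------------------------------------------------------------------

def _dataset_with_signals(seed=0, G=30, shift=None, trend=None):
    """Small generative dataset; gene 0 optionally carries a covariate
    signal (constant shift and/or zero-mean trend contrast)."""
    cfg = td.SimConfig(S=8, G=G, cells_per_sample=(120, 160), K_true=3)
    Bv = np.zeros((G, 4))
    if shift is not None:
        Bv[0] += shift
    if trend is not None:
        Bv[0] += np.array([1.0, -1.0, 1.0, -1.0]) * trend
    ds, truth = td.simulate_femm_data(cfg, seed=seed, B_covariate=Bv)
    return ds, truth


def test_xde_category_shift_gene():
    """A pure constant shift loads on the mean test, not the trend test
    (chi-squared route: free of the S=8 permutation-granularity floor)."""
    hits = 0
    for seed in range(8):
        ds, truth = _dataset_with_signals(seed=seed, shift=1.5)
        res = td.xde_test(ds, truth["pseudotime"], "group", mode="chisq")
        cat = res.loc[res["gene"] == "g0", "category"].iloc[0]
        if cat in ("meanSig", "bothSig"):
            hits += 1
        assert res.loc[res["gene"] == "g0", "mean_shift"].abs().iloc[0] > 0.5
    assert hits >= 6


def test_xde_category_trend_gene():
    """A zero-mean trend contrast loads on the trend test, not the mean test
    (chi-squared route: free of the S=8 permutation-granularity floor)."""
    hits = 0
    for seed in range(8):
        ds, truth = _dataset_with_signals(seed=101 + seed, trend=2.0)
        res = td.xde_test(ds, truth["pseudotime"], "group", mode="chisq")
        row = res.loc[res["gene"] == "g0"].iloc[0]
        if row["category"] in ("trendSig", "bothSig"):
            hits += 1
        assert row["p_trend"] < 0.05 or row["p_overall"] > 0.001
    assert hits >= 6


def test_xde_category_consistency_invariant():
    ds, truth = _dataset_with_signals(seed=3, shift=1.0)
    res = td.xde_test(ds, truth["pseudotime"], "group", mode="chisq")
    for _, row in res.iterrows():
        expected = classify_xde(row["fdr_overall"], row["fdr_mean"],
                                row["fdr_trend"], 0.05)
        assert row["category"] == expected
        if row["category"] == "nonXDE":
            assert not (row["fdr_overall"] <= 0.05)


def test_xde_zero_variance_gene_is_na():
    ds, truth = _dataset_with_signals(seed=4, G=10)
    expr = np.asarray(ds.expression).copy()
    expr[5] = 1.0
    ds2 = td.MultiSampleDataset(expr, ds.gene_ids, ds.cell_ids,
                                ds.sample_of_cell, ds.embedding,
                                ds.sample_design)
    res = td.xde_test(ds2, truth["pseudotime"], "group", mode="chisq")
    assert np.isnan(res.loc[res["gene"] == "g5", "p_overall"].iloc[0])


def test_chisq_and_pm_pvalues_correlate():
    ds, truth = _dataset_with_signals(seed=5, G=40, shift=1.0)
    r_chi = td.xde_test(ds, truth["pseudotime"], "group", mode="chisq")
    r_pm = td.xde_test(ds, truth["pseudotime"], "group", mode="pm",
                       n_perm=40, seed=2, screen_p=1.0)
    rho = pd.Series(r_chi["p_overall"].to_numpy()).corr(
        pd.Series(r_pm["p_overall"].to_numpy()), method="spearman")
    assert rho >= 0.9


# ---------------------------------------------------------------------------
# TDE pipeline
# ---------------------------------------------------------------------------

def test_tde_monotone_genes_have_power(rng):
    cfg = td.SimConfig(S=6, G=12, cells_per_sample=(100, 140), K_true=1,
                       B_intercept_sd=2.0)
    ds, truth = td.simulate_femm_data(cfg, seed=9)
    res = td.tde_test(ds, truth["pseudotime"], mode="pm", n_perm=30, seed=1)
    # genes whose true basis coefficients differ strongly must be detected
    spread = np.ptp(truth["B_intercept"], axis=1)
    strong = spread > 1.5
    assert (res.loc[strong, "fdr"] <= 0.05).mean() >= 0.9


def test_tde_llr_location_invariant():
    rng = np.random.default_rng(2)
    K = 2
    obs, x = _sim_obs(rng, S=6, C=100, K=K, B0=[0.0, 1.0, 2.0])
    nf1 = fit_tde_models(obs, design=None, K=K, tol=1e-8, max_iter=2000)
    obs2 = td.GeneObservations([y + 7.3 for y in obs.y], obs.t, obs.samples)
    nf2 = fit_tde_models(obs2, design=None, K=K, tol=1e-8, max_iter=2000)
    assert nf1.llr["tde"] == pytest.approx(nf2.llr["tde"], abs=1e-2)


def test_tde_constant_genes_not_rejected():
    cfg = td.SimConfig(S=6, G=30, cells_per_sample=(80, 120), K_true=0,
                       B_intercept_sd=1.0)
    ds, truth = td.simulate_femm_data(cfg, seed=10)
    res = td.tde_test(ds, truth["pseudotime"], mode="pm", n_perm=25, seed=1)
    assert (res["fdr"] <= 0.05).mean() <= 0.05


# ---------------------------------------------------------------------------
# Pattern clustering
# ---------------------------------------------------------------------------

def test_cluster_patterns_planted_archetypes(rng):
    grid = np.linspace(0, 1, 100)
    rising = grid[None, :] + rng.normal(0, 0.02, (100, 100))
    falling = 1 - grid[None, :] + rng.normal(0, 0.02, (100, 100))
    X = np.vstack([rising, falling])
    planted = np.r_[np.zeros(100), np.ones(100)]
    for method in ("kmeans", "gmm", "louvain"):
        labels = td.cluster_patterns(X, method=method, k=2, seed=1)
        assert adjusted_rand_score(planted, labels) == 1.0


def test_cluster_patterns_identical_rows_single_cluster():
    X = np.tile(np.linspace(0, 1, 50), (20, 1))
    labels = td.cluster_patterns(X, seed=1)
    assert len(np.unique(labels)) == 1


def test_cluster_patterns_elbow_recovers_two(rng):
    grid = np.linspace(0, 1, 100)
    X = np.vstack([grid + rng.normal(0, 0.01, (50, 100)),
                   -grid + rng.normal(0, 0.01, (50, 100))])
    labels = td.cluster_patterns(X, method="kmeans", k=None, seed=1)
    assert len(np.unique(labels)) == 2
    with pytest.raises(ValueError):
        td.cluster_patterns(X[:3], k=5)
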