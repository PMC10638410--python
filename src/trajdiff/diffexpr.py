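"""Differential expression tests along and across pseudotime.

Two families of tests are built on the functional mixed-effects model:

* **XDE** — does a sample covariate X_v change a gene's pseudotemporal curve?
  Nested models: M0 (beta_.v = 0), M1 (beta_.v = c 1, a pure mean shift, which
  is a single extra column in the fixed-effect design because the B-spline
  basis sums to one), M2 (unconstrained).  The *overall* test compares M2 with
  M0, the *mean* test M1 with M0, and the *trend* test M2 with M1.
* **TDE** — does the curve change along pseudotime at all?  H0 constrains each
  column of B to a constant (flat curves); H1 is unconstrained.

The test statistic is the log-likelihood ratio (LLR).  Its null distribution
is obtained by permutation: each permutation bootstraps cells within samples
(to absorb pseudotime variability) and then shuffles the tested covariate
across samples (XDE) or the pseudotime within samples (TDE); a Gaussian
kernel density estimate over the permuted LLRs gives the tail p-value.  A
faster chi-squared reference on 2*LLR is available as ``mode="chisq"`` and is
also used to pre-screen genes before permutations in ``mode="pm"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .femm import (
    FemmFit,
    FemmParams,
    GeneObservations,
    _SuffStats,
    _fit_em_core,
    _kron_design,
    make_basis,
    scalar_omega_required,
    select_K_batch,
)

logger = logging.getLogger("trajdiff")

P_FLOOR = 1e-300
_LLR_SLACK = 1e-4

XDE_CATEGORIES = ("meanSig", "trendSig", "bothSig", "otherSig", "nonXDE")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    n = ps.size
    if n == 0:
        return q
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# Null references
# ---------------------------------------------------------------------------

def chisq_pvalue(llr: float, df: int) -> float:
    """Upper-tail chi-squared p-value of 2*LLR.

    The stored statistic is the raw log-likelihood ratio; the asymptotic
    reference applies to twice that value.
    """
    if df < 1:
        return 1.0
    stat = 2.0 * max(float(llr), 0.0)
    return float(chi2.sf(stat, df))


def kde_tail_pvalue(observed: float, null_draws) -> float:
    """Tail mass above ``observed`` of a Gaussian KDE of the null draws.

    Rule-of-thumb (Silverman) bandwidth; the tail is the analytic mixture of
    kernel survival functions.  Floored at 1e-300.
    """
    draws = np.asarray(null_draws, dtype=float)
    sd = draws.std(ddof=1) if draws.size > 1 else 0.0
    iqr = np.subtract(*np.percentile(draws, [75, 25]))
    bw = 0.9 * min(sd, iqr / 1.34 if iqr > 0 else np.inf) * draws.size ** -0.2
    if not np.isfinite(bw) or bw <= 0:
        bw = max(sd, 1e-8)
    p = float(norm.sf((observed - draws) / bw).mean())
    return max(p, P_FLOOR)


def permutation_null_pvalue(
    observed_llr: float,
    refit_callable,
    scheme: str = "xde",
    n_perm: int = 100,
    seed: int = 0,
) -> float:
    """Permutation p-value for an observed LLR.

    ``refit_callable(rng)`` must perform one permutation under the given
    scheme ("xde": covariate shuffle; "tde": within-sample pseudotime
    shuffle) and return the permuted LLR.  A failing permutation is redrawn,
    up to three times the permutation budget.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if scheme not in ("xde", "tde"):
        raise ValueError("scheme must be xde|tde")
    rng = np.random.default_rng(seed)
    draws = []
    attempts = 0
    while len(draws) < n_perm and attempts < 3 * n_perm:
        attempts += 1
        try:
            draws.append(float(refit_callable(rng)))
        except Exception as exc:  # noqa: BLE001 - redraw on refit failure
            logger.warning("permutation refit failed (%s); redrawn", exc)
    if len(draws) < n_perm:
        raise RuntimeError("too many permutation refit failures")
    return kde_tail_pvalue(observed_llr, draws)


# ---------------------------------------------------------------------------
# Nested model machinery
# ---------------------------------------------------------------------------

@dataclass
class NestedFits:
    """Log-likelihoods and parameter counts of a nested model sequence."""

    logliks: dict
    n_params: dict
    llr: dict
    K: int
    fits: dict = None

    def df(self, test: str) -> int:
        pairs = {"overall": ("m2", "m0"), "mean": ("m1", "m0"),
                 "trend": ("m2", "m1"), "tde": ("h1", "h0")}
        a, b = pairs[test]
        return self.n_params[a] - self.n_params[b]


def _xde_designs(phi_list, design, v):
    """Per-sample fixed-effect designs and warm-start embeddings for M0/M1/M2."""
    S, Vp1 = design.shape
    K1 = phi_list[0].shape[1]
    keep = [j for j in range(Vp1) if j != v]
    xr = design[:, keep]
    F0 = [_kron_design(phi, xr[s]) for s, phi in enumerate(phi_list)]
    F1 = [np.hstack([F0[s], design[s, v] * np.ones((phi.shape[0], 1))])
          for s, phi in enumerate(phi_list)]
    F2 = [_kron_design(phi, design[s]) for s, phi in enumerate(phi_list)]
    p0 = K1 * (Vp1 - 1)

    def embed01(theta0):
        return np.r_[theta0, 0.0]

    def embed12(theta1):
        theta2 = np.zeros(K1 * Vp1)
        for k in range(K1):
            for j, vv in enumerate(keep):
                theta2[k * Vp1 + vv] = theta1[k * (Vp1 - 1) + j]
            theta2[k * Vp1 + v] = theta1[p0]
        return theta2

    return [F0, F1, F2], [embed01, embed12]


def _tde_designs(phi_list, design):
    """Designs/embedding for the TDE pair: H0 flat-in-t, H1 unconstrained."""
    S, Vp1 = design.shape
    K1 = phi_list[0].shape[1]
    F0 = [np.ones((phi.shape[0], 1)) * design[s][None, :]
          for s, phi in enumerate(phi_list)]
    F1 = [_kron_design(phi, design[s]) for s, phi in enumerate(phi_list)]

    def embed01(theta0):
        return np.tile(theta0, K1)

    return [F0, F1], [embed01]


def _fit_sequence(y_list, phi_list, F_lists, embeds, scalar,
                  tol=1e-4, max_iter=150, init0=None):
    """Fit nested models poorest-first, warm-starting each richer model from
    the previous fit so log-likelihoods are ordered by EM monotonicity.

    ``init0`` optionally warm-starts the first (most restricted) model, e.g.
    permutation refits start from the observed null-model fit."""
    fits = []
    for i, F_list in enumerate(F_lists):
        st = _SuffStats(y_list, phi_list, F_list)
        res = _fit_em_core(st, scalar, tol=tol, max_iter=max_iter,
                           init=init0 if i == 0 else None)
        if i > 0 and res["loglik"] < fits[-1]["loglik"]:
            # restricted fit beat the cold start: refit from its embedding,
            # which restores the nesting order by EM monotonicity
            warm = dict(theta=embeds[i - 1](fits[-1]["theta"]),
                        Omega=fits[-1]["Omega"], alpha=fits[-1]["alpha"],
                        eta=fits[-1]["eta"])
            res2 = _fit_em_core(st, scalar, tol=tol, max_iter=max_iter,
                                init=warm)
            if res2["loglik"] > res["loglik"]:
                res = res2
        fits.append(res)
    return fits


def fit_nested_models(
    gene_obs: GeneObservations,
    design,
    v: int,
    K: int,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> NestedFits:
    """Fit M0/M1/M2 for covariate ``v`` (a non-intercept column index).

    Other covariate columns (e.g. batch dummies) remain free in all three
    models.  K is chosen once (under the richest model) and shared so LLRs
    compare like with like.
    """
    design = np.asarray(design, dtype=float)
    if v <= 0 or v >= design.shape[1]:
        raise ValueError("v must index a non-intercept covariate column")
    if np.ptp(design[:, v]) == 0:
        raise ValueError("covariate is constant across samples")
    V = design.shape[1] - 1
    scalar = scalar_omega_required(gene_obs.S, V, K)
    basis = make_basis(K)
    phi_list = [basis(t) for t in gene_obs.t]
    F_lists, embeds = _xde_designs(phi_list, design, v)
    f0, f1, f2 = _fit_sequence(gene_obs.y, phi_list, F_lists, embeds, scalar,
                               tol=tol, max_iter=max_iter)
    K1 = K + 1
    logliks = {"m0": f0["loglik"], "m1": f1["loglik"], "m2": f2["loglik"]}
    n_params = {"m0": K1 * V, "m1": K1 * V + 1, "m2": K1 * (V + 1)}
    llr = {
        "overall": max(logliks["m2"] - logliks["m0"], 0.0),
        "mean": max(logliks["m1"] - logliks["m0"], 0.0),
        "trend": max(logliks["m2"] - logliks["m1"], 0.0),
    }
    return NestedFits(logliks=logliks, n_params=n_params, llr=llr, K=K,
                      fits={"m0": f0, "m1": f1, "m2": f2})


def fit_tde_models(
    gene_obs: GeneObservations,
    design=None,
    K: int = 3,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> NestedFits:
    """Fit the TDE pair H0 (flat curves) vs H1 (free B)."""
    if design is None:
        design = np.ones((gene_obs.S, 1))
    design = np.asarray(design, dtype=float)
    V = design.shape[1] - 1
    scalar = scalar_omega_required(gene_obs.S, V, K)
    basis = make_basis(K)
    phi_list = [basis(t) for t in gene_obs.t]
    F_lists, embeds = _tde_designs(phi_list, design)
    f0, f1 = _fit_sequence(gene_obs.y, phi_list, F_lists, embeds, scalar,
                           tol=tol, max_iter=max_iter)
    K1 = K + 1
    logliks = {"h0": f0["loglik"], "h1": f1["loglik"]}
    n_params = {"h0": V + 1, "h1": K1 * (V + 1)}
    llr = {"tde": max(logliks["h1"] - logliks["h0"], 0.0)}
    return NestedFits(logliks=logliks, n_params=n_params, llr=llr, K=K,
                      fits={"h0": f0, "h1": f1})


# ---------------------------------------------------------------------------
# Gene observation extraction
# ---------------------------------------------------------------------------

def _resolve_branch(dataset, branch):
    """Return (cell indices into dataset, scaled pseudotime) for a branch.

    ``branch`` is either a trajectory Branch (with ``member_cells`` and
    ``scaled_pseudotime``) or a pandas Series mapping cell id -> pseudotime in
    [0, 1].
    """
    if hasattr(branch, "scaled_pseudotime"):
        pt = pd.Series(branch.scaled_pseudotime)
    else:
        pt = pd.Series(branch, dtype=float)
    pos = pd.Series(np.arange(dataset.n_cells), index=dataset.cell_ids)
    cells = pt.index.intersection(pos.index)
    idx = pos.loc[cells].to_numpy()
    return idx, pt.loc[cells].to_numpy(dtype=float)


def _split_by_sample(dataset, idx, t):
    samples = [s for s in dataset.samples
               if np.any(dataset.sample_of_cell[idx] == s)]
    idx_by, t_by = [], []
    for s in samples:
        mask = dataset.sample_of_cell[idx] == s
        idx_by.append(idx[mask])
        t_by.append(t[mask])
    return samples, idx_by, t_by


def gene_observations(dataset, branch, gene) -> GeneObservations:
    """Extract one gene's per-sample (expression, pseudotime) observations."""
    idx, t = _resolve_branch(dataset, branch)
    samples, idx_by, t_by = _split_by_sample(dataset, idx, t)
    vals = dataset.gene_values(gene)
    return GeneObservations([vals[i] for i in idx_by], t_by, samples)


# ---------------------------------------------------------------------------
# Test pipelines
# ---------------------------------------------------------------------------

def _xde_llrs_once(y_list, phi_list, design, v, scalar, tol, max_iter,
                   init0=None):
    F_lists, embeds = _xde_designs(phi_list, design, v)
    f0, f1, f2 = _fit_sequence(y_list, phi_list, F_lists, embeds, scalar,
                               tol=tol, max_iter=max_iter, init0=init0)
    llrs = (max(f2["loglik"] - f0["loglik"], 0.0),
            max(f1["loglik"] - f0["loglik"], 0.0),
            max(f2["loglik"] - f1["loglik"], 0.0))
    return llrs + ((f0, f1, f2),)


def _tde_llr_once(y_list, phi_list, design, scalar, tol, max_iter,
                  init0=None):
    F_lists, embeds = _tde_designs(phi_list, design)
    f0, f1 = _fit_sequence(y_list, phi_list, F_lists, embeds, scalar,
                           tol=tol, max_iter=max_iter, init0=init0)
    return max(f1["loglik"] - f0["loglik"], 0.0), (f0, f1)


def _as_init(fit: dict) -> dict:
    return dict(theta=fit["theta"], Omega=fit["Omega"], alpha=fit["alpha"],
                eta=fit["eta"])


def classify_xde(fdr_overall, fdr_mean, fdr_trend, cutoff=0.05) -> str:
    if not np.isfinite(fdr_overall) or fdr_overall > cutoff:
        return "nonXDE"
    mean_sig = np.isfinite(fdr_mean) and fdr_mean <= cutoff
    trend_sig = np.isfinite(fdr_trend) and fdr_trend <= cutoff
    if mean_sig and trend_sig:
        return "bothSig"
    if mean_sig:
        return "meanSig"
    if trend_sig:
        return "trendSig"
    return "otherSig"


def _branch_matrices(dataset, branch, genes):
    """Per-sample (cells x genes) expression and pseudotime blocks."""
    idx, t = _resolve_branch(dataset, branch)
    samples, idx_by, t_by = _split_by_sample(dataset, idx, t)
    gidx = np.array([dataset.gene_index(g) for g in genes])
    expr = np.asarray(dataset.expression[...], dtype=float)[gidx]
    Y_by = [expr[:, i].T for i in idx_by]  # C_s x G
    return samples, Y_by, t_by


def xde_test(
    dataset,
    branch,
    covariate,
    mode: str = "pm",
    n_perm: int = 100,
    fdr_cutoff: float = 0.05,
    seed: int = 1,
    K_max: int = 20,
    screen_p: float = 0.1,
    genes=None,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Covariate-associated differential expression along one branch.

    Returns a per-gene table with the three LLRs, p-values, BH FDRs, the XDE
    category at ``fdr_cutoff``, and the estimated mean shift.  In ``pm`` mode
    genes are first screened with the (cheap, anticonservative) chi-squared
    p-values; only genes with any screened p <= ``screen_p`` are sent to
    permutations, the rest keep their chi-squared p-values, which are already
    far from significance.
    """
    if mode not in ("pm", "chisq"):
        raise ValueError("mode must be pm|chisq")
    genes = list(dataset.gene_ids if genes is None else genes)
    design_df = dataset.sample_design
    v = (list(design_df.columns).index(covariate)
         if isinstance(covariate, str) else int(covariate))
    samples, Y_by, t_by = _branch_matrices(dataset, branch, genes)
    design = design_df.loc[samples].to_numpy(dtype=float)
    S, Vp1 = design.shape
    for level in np.unique(design[:, v]):
        if (design[:, v] == level).sum() < 2:
            logger.warning("covariate level %s has < 2 samples", level)

    K_per_gene = select_K_batch(Y_by, t_by, K_max=K_max)
    rng_root = np.random.default_rng(seed)
    gene_seeds = rng_root.integers(0, 2**31 - 1, size=len(genes))

    basis_cache: dict = {}

    def phis_for(K):
        if K not in basis_cache:
            b = make_basis(K)
            basis_cache[K] = [b(t) for t in t_by]
        return basis_cache[K]

    rows = []
    for gi, gene in enumerate(genes):
        yg = [Y[:, gi] for Y in Y_by]
        if all(np.ptp(y) == 0 for y in yg):
            rows.append(dict(gene=gene, K=np.nan, llr_overall=np.nan,
                             p_overall=np.nan, llr_mean=np.nan, p_mean=np.nan,
                             llr_trend=np.nan, p_trend=np.nan,
                             mean_shift=np.nan, screened=False))
            continue
        K = int(K_per_gene[gi])
        scalar = scalar_omega_required(S, Vp1 - 1, K)
        phi_list = phis_for(K)
        F_lists, embeds = _xde_designs(phi_list, design, v)
        f0, f1, f2 = _fit_sequence(yg, phi_list, F_lists, embeds, scalar,
                                   tol=tol, max_iter=max_iter)
        llr_o = max(f2["loglik"] - f0["loglik"], 0.0)
        llr_m = max(f1["loglik"] - f0["loglik"], 0.0)
        llr_t = max(f2["loglik"] - f1["loglik"], 0.0)
        p_o = chisq_pvalue(llr_o, K + 1)
        p_m = chisq_pvalue(llr_m, 1)
        p_t = chisq_pvalue(llr_t, K) if K >= 1 else 1.0
        screened = False
        if mode == "pm" and min(p_o, p_m, p_t) <= screen_p:
            screened = True
            rng = np.random.default_rng(gene_seeds[gi])
            init0 = _as_init(f0)
            null_o, null_m, null_t = [], [], []
            for _ in range(n_perm):
                boot = [rng.integers(0, len(y), len(y)) for y in yg]
                y_b = [y[i] for y, i in zip(yg, boot)]
                phi_b = [phi[i] for phi, i in zip(phi_list, boot)]
                design_b = design.copy()
                design_b[:, v] = design[rng.permutation(S), v]
                lo, lm, lt, _ = _xde_llrs_once(y_b, phi_b, design_b, v,
                                               scalar, tol, max_iter,
                                               init0=init0)
                null_o.append(lo)
                null_m.append(lm)
                null_t.append(lt)
            p_o = kde_tail_pvalue(llr_o, null_o)
            p_m = kde_tail_pvalue(llr_m, null_m)
            p_t = kde_tail_pvalue(llr_t, null_t) if K >= 1 else 1.0
        # mean shift per unit covariate: average population-curve difference
        Bhat = f2["theta"].reshape(K + 1, Vp1)
        grid = np.linspace(0, 1, 100)
        diff = make_basis(K)(grid) @ Bhat[:, v]
        rows.append(dict(gene=gene, K=K, llr_overall=llr_o, p_overall=p_o,
                         llr_mean=llr_m, p_mean=p_m, llr_trend=llr_t,
                         p_trend=p_t, mean_shift=float(diff.mean()),
                         screened=screened))
    res = pd.DataFrame(rows)
    res["fdr_overall"] = bh_adjust(res["p_overall"])
    res["fdr_mean"] = bh_adjust(res["p_mean"])
    res["fdr_trend"] = bh_adjust(res["p_trend"])
    res["category"] = [
        classify_xde(o, m, t, fdr_cutoff)
        for o, m, t in zip(res["fdr_overall"], res["fdr_mean"], res["fdr_trend"])
    ]
    res.attrs["mode"] = mode
    res.attrs["n_permutations"] = n_perm if mode == "pm" else 0
    return res[["gene", "K", "llr_overall", "p_overall", "fdr_overall",
                "llr_mean", "p_mean", "fdr_mean", "llr_trend", "p_trend",
                "fdr_trend", "category", "mean_shift", "screened"]]


def tde_test(
    dataset,
    branch,
    mode: str = "pm",
    n_perm: int = 100,
    fdr_cutoff: float = 0.05,
    seed: int = 1,
    K_max: int = 20,
    screen_p: float = 0.1,
    genes=None,
    use_covariates: bool = False,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Differential expression along pseudotime for one branch."""
    if mode not in ("pm", "chisq"):
        raise ValueError("mode must be pm|chisq")
    genes = list(dataset.gene_ids if genes is None else genes)
    samples, Y_by, t_by = _branch_matrices(dataset, branch, genes)
    if use_covariates:
        design = dataset.sample_design.loc[samples].to_numpy(dtype=float)
    else:
        design = np.ones((len(samples), 1))
    S, Vp1 = design.shape

    K_per_gene = select_K_batch(Y_by, t_by, K_max=K_max)
    rng_root = np.random.default_rng(seed)
    gene_seeds = rng_root.integers(0, 2**31 - 1, size=len(genes))
    basis_cache: dict = {}

    def phis_for(K):
        if K not in basis_cache:
            b = make_basis(K)
            basis_cache[K] = [b(t) for t in t_by]
        return basis_cache[K]

    rows = []
    for gi, gene in enumerate(genes):
        yg = [Y[:, gi] for Y in Y_by]
        if all(np.ptp(y) == 0 for y in yg):
            rows.append(dict(gene=gene, K=np.nan, llr=np.nan, p_value=np.nan,
                             screened=False))
            continue
        K = int(K_per_gene[gi])
        if K == 0:
            rows.append(dict(gene=gene, K=0, llr=0.0, p_value=1.0,
                             screened=False))
            continue
        scalar = scalar_omega_required(S, Vp1 - 1, K)
        phi_list = phis_for(K)
        llr, (h0, _) = _tde_llr_once(yg, phi_list, design, scalar, tol,
                                     max_iter)
        df = K * Vp1
        p = chisq_pvalue(llr, df)
        screened = False
        if mode == "pm" and p <= screen_p:
            screened = True
            rng = np.random.default_rng(gene_seeds[gi])
            init0 = _as_init(h0)
            null = []
            for _ in range(n_perm):
                boot = [rng.integers(0, len(y), len(y)) for y in yg]
                y_b = [y[i] for y, i in zip(yg, boot)]
                # permute pseudotime within each sample
                phi_b = [phi[i][rng.permutation(len(i))]
                         for phi, i in zip(phi_list, boot)]
                null.append(_tde_llr_once(y_b, phi_b, design, scalar,
                                          tol, max_iter, init0=init0)[0])
            p = kde_tail_pvalue(llr, null)
        rows.append(dict(gene=gene, K=K, llr=llr, p_value=p, screened=screened))
    res = pd.DataFrame(rows)
    res["fdr"] = bh_adjust(res["p_value"])
    res.attrs["mode"] = mode
    res.attrs["n_permutations"] = n_perm if mode == "pm" else 0
    return res[["gene", "K", "llr", "p_value", "fdr", "screened"]]


# ---------------------------------------------------------------------------
# Pattern clustering of DE genes
# ---------------------------------------------------------------------------

def _standardize_rows(X):
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def cluster_patterns(
    curves,
    what: str = "tde_curves",
    method: str = "kmeans",
    k: int | None = None,
    seed: int = 1,
    mean_shift_sign=None,
) -> np.ndarray:
    """Cluster DE genes by fitted-pattern shape.

    ``curves`` is a genes x grid matrix of fitted curves (TDE) or
    trend-difference curves (XDE); rows are standardized before clustering.
    For XDE the sign of the mean shift may be appended as one extra feature.
    k is chosen by an elbow on within-cluster dispersion when absent.
    """
    X = _standardize_rows(np.asarray(curves, dtype=float))
    if what == "xde_difference" and mean_shift_sign is not None:
        X = np.hstack([X, np.sign(np.asarray(mean_shift_sign))[:, None]])
    n = X.shape[0]
    if k is not None and n < k:
        raise ValueError("fewer genes than requested clusters")
    if np.allclose(X, X[0][None, :]):
        return np.zeros(n, dtype=int)

    from sklearn.cluster import KMeans

    if k is None:
        kmax = min(10, n - 1)
        wss = []
        for kk in range(1, kmax + 1):
            km = KMeans(n_clusters=kk, n_init=5, random_state=seed).fit(X)
            wss.append(km.inertia_)
        k = kmax
        for kk in range(1, kmax):
            if wss[kk - 1] <= 0 or (wss[kk - 1] - wss[kk]) / wss[kk - 1] < 0.10:
                k = kk
                break
    if method == "kmeans":
        return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    if method == "gmm":
        from sklearn.mixture import GaussianMixture

        return GaussianMixture(n_components=k, random_state=seed,
                               n_init=3).fit_predict(X)
    if method == "louvain":
        import networkx as nx
        from sklearn.neighbors import kneighbors_graph

        adj = kneighbors_graph(X, n_neighbors=min(15, n - 1), mode="connectivity")
        graph = nx.from_scipy_sparse_array(adj)
        comms = nx.community.louvain_communities(graph, seed=seed)
        labels = np.empty(n, dtype=int)
        for ci, comm in enumerate(comms):
            labels[list(comm)] = ci
        return labels
    raise ValueError("method must be kmeans|gmm|louvain")
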