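"""Functional mixed-effects model for gene expression along pseudotime.

A gene's expression in sample ``s`` is modeled as a B-spline curve whose
coefficients decompose into fixed covariate effects and a sample-level random
effect:

    y_s = Phi_s (X_s beta + u_s) + eps_s,
    eps_sc ~ N(0, sigma_s^2),   u_s ~ N(0, sigma_s^2 Omega),
    sigma_s^2 ~ InvGamma(alpha, eta).

``Phi_s`` stacks K+1 B-spline basis evaluations at the (branch-rescaled,
[0,1]) pseudotimes of sample ``s``; ``X_s = I_{K+1} (x) x_s^T`` encodes the
sample's covariate vector.  Integrating the conjugate normal-inverse-gamma
latents out gives a closed-form marginal likelihood per sample (a multivariate
t), which the EM algorithm here maximizes over Theta = {beta, Omega, alpha,
eta}.  All per-iteration work happens in (K+1)-dimensional sufficient
statistics, so fits cost the same whether a sample has 100 or 100,000 cells.

When the number of samples S does not exceed V + K + 2 there are not enough
degrees of freedom to estimate an unconstrained Omega, and the model falls
back to Omega = omega^2 I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import digamma, gammaln, polygamma

logger = logging.getLogger("trajdiff")

_RIDGE = 1e-8
_OMEGA_EIG_FLOOR = 1e-10
_ALPHA_FLOOR = 1.01


# ---------------------------------------------------------------------------
# B-spline basis
# ---------------------------------------------------------------------------

class SplineBasis:
    """K+1 B-spline basis functions on [0, 1].

    ``K`` counts equidistant knots: K = 0 yields the single constant basis;
    1 <= K <= 3 a degree-K Bernstein basis (no interior knots); K >= 4 a cubic
    basis with K-3 equidistant interior knots.  Every choice yields exactly
    K+1 functions that are nonnegative and sum to one (partition of unity).
    """

    def __init__(self, K: int):
        if K < 0:
            raise ValueError("K must be >= 0")
        self.K = int(K)
        self.n_bases = self.K + 1
        if K == 0:
            self.degree = 0
            self.knots = np.array([0.0, 1.0])
            self._spl = None
        else:
            self.degree = min(3, K)
            n_interior = K - self.degree
            interior = np.linspace(0, 1, n_interior + 2)[1:-1]
            self.knots = np.r_[
                np.zeros(self.degree + 1), interior, np.ones(self.degree + 1)
            ]
            self._spl = BSpline(
                self.knots, np.eye(self.n_bases), self.degree, extrapolate=True
            )

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the basis: returns an array of shape (len(t), K+1)."""
        t = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), 0.0, 1.0)
        if self.K == 0:
            return np.ones((t.size, 1))
        return self._spl(t)


def make_basis(K: int) -> SplineBasis:
    return SplineBasis(K)


# ---------------------------------------------------------------------------
# Observations and parameters
# ---------------------------------------------------------------------------

@dataclass
class GeneObservations:
    """Per-sample expression and pseudotime of one gene.

    ``y[i]`` and ``t[i]`` are aligned vectors for sample ``samples[i]``;
    pseudotimes must lie in [0, 1].
    """

    y: list
    t: list
    samples: list

    def __post_init__(self):
        self.y = [np.asarray(v, dtype=float).ravel() for v in self.y]
        self.t = [np.asarray(v, dtype=float).ravel() for v in self.t]
        if len(self.y) != len(self.t) or len(self.y) != len(self.samples):
            raise ValueError("y, t, samples must have equal lengths")
        for ys, ts in zip(self.y, self.t):
            if ys.shape != ts.shape:
                raise ValueError("y and t lengths differ within a sample")
            if ts.size and (ts.min() < 0 or ts.max() > 1):
                raise ValueError("pseudotime must be rescaled to [0, 1]")

    @property
    def S(self) -> int:
        return len(self.samples)

    @property
    def cells_per_sample(self) -> np.ndarray:
        return np.array([len(v) for v in self.y])

    @property
    def total_cells(self) -> int:
        return int(self.cells_per_sample.sum())


@dataclass
class FemmParams:
    """Estimated parameters Theta = {B, Omega, alpha, eta}."""

    B: np.ndarray          # (K+1) x (V+1) fixed effects
    Omega: np.ndarray      # (K+1) x (K+1) random-effect covariance (PD)
    alpha: float
    eta: float
    omega_constrained: bool = False

    @property
    def beta(self) -> np.ndarray:
        """Row-major vectorization (beta_0.^T, beta_1.^T, ...)."""
        return self.B.ravel()


@dataclass
class FemmFit:
    params: FemmParams
    K: int
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    posterior_mean_u: np.ndarray      # S x (K+1), E[u_s]
    posterior_uut: np.ndarray         # S x (K+1) x (K+1), E[u_s u_s^T]
    posterior_inv_sigma2: np.ndarray  # S, E[1/sigma_s^2]
    gene_obs: GeneObservations = field(repr=False, default=None)
    design: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

def _kron_design(phi: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Fixed-effect design Phi_s X_s: columns ordered (k, v)."""
    return (phi[:, :, None] * x[None, None, :]).reshape(phi.shape[0], -1)


class _SuffStats:
    """Per-sample Gram statistics of (y_s, Phi_s, F_s).

    Everything EM needs: A = Phi^T Phi, H = Phi^T F, G = F^T F, a = Phi^T y,
    g = F^T y, yy = y^T y, C = cell counts.  Stacked over samples.
    """

    def __init__(self, y_list, phi_list, F_list):
        S = len(y_list)
        K1 = phi_list[0].shape[1]
        p = F_list[0].shape[1]
        self.S, self.K1, self.p = S, K1, p
        self.A = np.empty((S, K1, K1))
        self.H = np.empty((S, K1, p))
        self.G = np.empty((S, p, p))
        self.a = np.empty((S, K1))
        self.g = np.empty((S, p))
        self.yy = np.empty(S)
        self.C = np.empty(S)
        for s, (y, phi, F) in enumerate(zip(y_list, phi_list, F_list)):
            self.A[s] = phi.T @ phi
            self.H[s] = phi.T @ F
            self.G[s] = F.T @ F
            self.a[s] = phi.T @ y
            self.g[s] = F.T @ y
            self.yy[s] = y @ y
            self.C[s] = y.size


def _estep(st: _SuffStats, theta, Omega, alpha, eta):
    """Closed-form normal-inverse-gamma posterior moments per sample."""
    phi_r = st.a - st.H @ theta                       # (S, K1)
    rr = st.yy - 2 * st.g @ theta + np.einsum("i,sij,j->s", theta, st.G, theta)
    Oinv = np.linalg.inv(Omega + _OMEGA_EIG_FLOOR * np.eye(st.K1))
    V = np.linalg.inv(Oinv[None] + st.A)              # (S, K1, K1)
    m = np.einsum("sij,sj->si", V, phi_r)
    q = np.maximum(rr - np.einsum("si,si->s", phi_r, m), 0.0)
    ahat = alpha + st.C / 2.0
    bhat = eta + q / 2.0
    w = ahat / bhat                                   # E[1/sigma_s^2]
    elog = np.log(bhat) - digamma(ahat)               # E[log sigma_s^2]
    return phi_r, V, m, q, w, elog


def _marginal_ll(st: _SuffStats, Omega, alpha, eta, q) -> float:
    """Sum over samples of the log marginal of y_s.

    Integrating (u_s, sigma_s^2) out of the model gives
    p(y_s) = eta^alpha Gamma(alpha + C/2) / ((2 pi)^{C/2} |M|^{1/2}
             Gamma(alpha)) * (eta + q/2)^{-(alpha + C/2)},
    with M = Phi Omega Phi^T + I and q = r^T M^{-1} r, evaluated via the
    Woodbury identity in (K+1)-space.
    """
    sign, logdetM = np.linalg.slogdet(
        np.eye(st.K1)[None] + Omega[None] @ st.A
    )
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("non-PD marginal scale matrix")
    ahat = alpha + st.C / 2.0
    ll = (
        alpha * np.log(eta) - gammaln(alpha) + gammaln(ahat)
        - 0.5 * st.C * np.log(2 * np.pi) - 0.5 * logdetM
        - ahat * np.log(eta + q / 2.0)
    )
    return float(ll.sum())


def _update_alpha_eta(w, elog, alpha0):
    """Joint maximizer of the inverse-gamma prior term of the EM objective.

    Profiling eta = S * alpha / sum(w) leaves a 1-D concave problem in alpha;
    solved by safeguarded Newton on the (strictly decreasing) derivative
    g(alpha) = S [log(S alpha / sum w) - digamma(alpha)] - sum(elog).
    """
    S = w.size
    Tw = max(float(w.sum()), 1e-300)
    Tl = float(elog.sum())

    def grad(a):
        return S * (np.log(S * a / Tw) - digamma(a)) - Tl

    def profile_obj(a):
        # expected complete-data contribution of the inverse-gamma block,
        # with eta profiled out at S*a/Tw
        return S * a * np.log(S * a / Tw) - S * gammaln(a) - (a + 1) * Tl - S * a

    lo, hi = _ALPHA_FLOOR, 1e6
    if grad(lo) <= 0:
        alpha = lo
    elif grad(hi) >= 0:
        alpha = hi
    else:
        alpha = float(np.clip(alpha0, lo, hi))
        for _ in range(15):
            g = grad(alpha)
            gp = S * (1.0 / alpha - polygamma(1, alpha))
            step = g / gp
            new = alpha - step
            if not (lo < new < hi):  # bisection fallback
                if g < 0:
                    hi = alpha
                else:
                    lo = alpha
                new = 0.5 * (lo + hi)
            if abs(new - alpha) < 1e-10 * max(1.0, alpha):
                alpha = new
                break
            alpha = new
    # monotonicity safeguard: never accept a worse block objective than the
    # previous alpha (profiled eta is optimal given alpha either way)
    a_prev = float(np.clip(alpha0, lo, 1e6))
    if profile_obj(a_prev) > profile_obj(alpha):
        alpha = a_prev
    eta = max(S * alpha / Tw, 1e-12)
    return float(alpha), float(eta)


def _regularize_omega(Omega):
    Omega = 0.5 * (Omega + Omega.T)
    vals, vecs = np.linalg.eigh(Omega)
    vals = np.maximum(vals, _OMEGA_EIG_FLOOR)
    return (vecs * vals) @ vecs.T


def _fit_em_core(
    st: _SuffStats,
    scalar_omega: bool,
    tol: float = 1e-6,
    max_iter: int = 1000,
    fix_omega: np.ndarray | None = None,
    init: dict | None = None,
):
    """EM on sufficient statistics with a general fixed-effect design.

    Returns a dict with theta, Omega, alpha, eta, posterior moments, loglik
    trace and convergence flag.  Monotone in the marginal likelihood: the
    E-step posterior is exact by conjugacy and the M-step maximizes the three
    separable blocks (theta | Omega | alpha,eta) of the expected complete-data
    log-likelihood jointly.

    ``init`` may supply starting values (theta, Omega, alpha, eta); nested
    model sequences warm-start richer models from restricted fits, which keeps
    log-likelihoods ordered by construction (EM monotonicity).
    """
    S, K1, p = st.S, st.K1, st.p
    eye_p = np.eye(p)

    if init is not None:
        theta = np.asarray(init["theta"], dtype=float)
        Omega = np.asarray(init["Omega"], dtype=float)
        alpha = float(init["alpha"])
        eta = float(init["eta"])
        if fix_omega is not None:
            Omega = np.asarray(fix_omega, dtype=float)
            if Omega.ndim == 0:
                Omega = float(Omega) * np.eye(K1)
    else:
        # --- initialization: per-sample OLS spline fits -> moments ---------
        theta = np.linalg.solve(st.G.sum(0) + _RIDGE * eye_p, st.g.sum(0))
        b0 = np.linalg.solve(st.A + _RIDGE * np.eye(K1)[None], st.a[..., None])[..., 0]
        rss = np.maximum(
            st.yy - np.einsum("si,si->s", b0, st.a), 1e-12 * np.maximum(st.yy, 1.0)
        )
        sig2 = np.maximum(rss / np.maximum(st.C, 1.0), 1e-10)
        msig, vsig = float(sig2.mean()), float(sig2.var())
        if vsig > 1e-12 and S > 2:
            alpha = max(msig**2 / vsig + 2.0, _ALPHA_FLOOR + 0.04)
        else:
            alpha = 3.0
        eta = msig * (alpha - 1.0)
        if fix_omega is not None:
            Omega = np.asarray(fix_omega, dtype=float)
            if Omega.ndim == 0:
                Omega = float(Omega) * np.eye(K1)
        else:
            d = b0 - b0.mean(0)
            Omega = (d.T @ d) / max(S - 1, 1) / msig + 1e-4 * np.eye(K1)
            if scalar_omega:
                Omega = (np.trace(Omega) / K1) * np.eye(K1)

    def em_map(theta, Omega, alpha, eta):
        """One exact EM update; also returns the loglik at the input params
        (free by-product of the E-step)."""
        phi_r, V, m, q, w, elog = _estep(st, theta, Omega, alpha, eta)
        ll_in = _marginal_ll(st, Omega, alpha, eta, q)
        lhs = np.einsum("s,sij->ij", w, st.G)
        rhs = (w[:, None] * (st.g - np.einsum("skp,sk->sp", st.H, m))).sum(0)
        try:
            theta = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            logger.debug("singular normal equations; ridge added")
            theta = np.linalg.solve(lhs + _RIDGE * eye_p, rhs)
        if fix_omega is None:
            Om = (
                w[:, None, None] * m[:, :, None] * m[:, None, :] + V
            ).mean(0)
            if scalar_omega:
                om2 = max(np.trace(Om) / K1, _OMEGA_EIG_FLOOR)
                Omega = om2 * np.eye(K1)
            else:
                Omega = _regularize_omega(Om)
        alpha, eta = _update_alpha_eta(w, elog, alpha)
        return (theta, Omega, alpha, eta), ll_in

    # vector encoding for the extrapolation step (log scale for the
    # positive scalars; scalar-Omega mode encodes log omega^2 only)
    def pack(theta, Omega, alpha, eta):
        if fix_omega is not None:
            om = np.empty(0)
        elif scalar_omega:
            om = np.array([np.log(Omega[0, 0])])
        else:
            om = Omega.ravel()
        return np.concatenate([theta, om, [np.log(alpha), np.log(eta)]])

    def unpack(vec):
        theta = vec[:p]
        if fix_omega is not None:
            Om = Omega_fixed
            rest = vec[p:]
        elif scalar_omega:
            Om = np.exp(vec[p]) * np.eye(K1)
            rest = vec[p + 1:]
        else:
            Om = vec[p:p + K1 * K1].reshape(K1, K1)
            Om = 0.5 * (Om + Om.T)
            rest = vec[p + K1 * K1:]
        alpha = float(np.exp(rest[-2]))
        eta = float(np.exp(rest[-1]))
        return theta, Om, alpha, eta

    def valid(theta, Om, alpha, eta):
        if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(Om))):
            return False
        if not (_ALPHA_FLOOR <= alpha <= 1e8 and 0 < eta < 1e12):
            return False
        try:
            np.linalg.cholesky(Om + _OMEGA_EIG_FLOOR * np.eye(K1))
        except np.linalg.LinAlgError:
            return False
        return True

    Omega_fixed = Omega if fix_omega is not None else None
    params = (theta, Omega, alpha, eta)
    trace = []
    converged = False
    n_map = 0
    # EM with SQUAREM-style extrapolation: each cycle takes two EM steps and
    # tries a quadratic extrapolation of the parameter trajectory, accepted
    # only when it improves the marginal likelihood (so the recorded trace
    # stays monotone while escaping the slow late-stage crawl).
    while n_map < max_iter:
        p1, ll0 = em_map(*params)
        p2, ll1 = em_map(*p1)
        n_map += 2
        trace += [ll0, ll1]
        if len(trace) > 2 and abs(ll1 - ll0) < tol:
            params = p2
            converged = True
            break
        v0, v1, v2 = pack(*params), pack(*p1), pack(*p2)
        r = v1 - v0
        dv = (v2 - v1) - r
        nv = float(np.linalg.norm(dv))
        params = p2
        if nv > 1e-12:
            step = -max(float(np.linalg.norm(r)) / nv, 1.0)
            prop = unpack(v0 - 2 * step * r + step * step * dv)
            if valid(*prop):
                try:
                    p3, ll_prop = em_map(*prop)
                    n_map += 1
                    if ll_prop >= ll1:  # monotone acceptance
                        params = p3
                        trace.append(ll_prop)
                except np.linalg.LinAlgError:
                    pass
    if not converged:
        logger.debug("EM did not converge in %d map evaluations", max_iter)

    theta, Omega, alpha, eta = params
    phi_r, V, m, q, w, elog = _estep(st, theta, Omega, alpha, eta)
    ll = _marginal_ll(st, Omega, alpha, eta, q)
    # E[u u^T] = E[sigma^2] V + m m^T, with E[sigma^2] = bhat / (ahat - 1)
    ahat = alpha + st.C / 2.0
    bhat = eta + q / 2.0
    esig2 = bhat / np.maximum(ahat - 1.0, 1e-8)
    uut = esig2[:, None, None] * V + m[:, :, None] * m[:, None, :]
    return dict(
        theta=theta, Omega=Omega, alpha=alpha, eta=eta, loglik=ll,
        trace=np.array(trace + [ll]), n_iter=n_map, converged=converged,
        m=m, uut=uut, w=w, q=q,
    )


# ---------------------------------------------------------------------------
# Public fitting interface (standard covariate model)
# ---------------------------------------------------------------------------

def _prepare(gene_obs: GeneObservations, sample_design, K: int):
    design = np.asarray(sample_design, dtype=float)
    if design.ndim != 2 or design.shape[0] != gene_obs.S:
        raise ValueError("sample_design must be S x (V+1)")
    basis = make_basis(K)
    phi_list = [basis(t) for t in gene_obs.t]
    return design, basis, phi_list


def scalar_omega_required(S: int, V: int, K: int) -> bool:
    """Not enough samples to estimate a full (K+1)x(K+1) covariance."""
    return S <= V + K + 2


def fit_em(
    gene_obs: GeneObservations,
    sample_design,
    K: int,
    constrain_omega: str = "auto",
    tol: float = 1e-6,
    max_iter: int = 1000,
    fix_omega=None,
) -> FemmFit:
    """Fit the functional mixed-effects model by EM.

    ``constrain_omega``: "auto" applies Omega = omega^2 I iff S <= V + K + 2;
    "scalar" forces it; "full" never applies it.  ``fix_omega`` holds Omega
    fixed at a given matrix (or scalar times identity), useful for the S=1
    degenerate case.
    """
    design, basis, phi_list = _prepare(gene_obs, sample_design, K)
    V = design.shape[1] - 1
    if constrain_omega == "auto":
        scalar = scalar_omega_required(gene_obs.S, V, K)
    elif constrain_omega in ("scalar", "full"):
        scalar = constrain_omega == "scalar"
    else:
        raise ValueError("constrain_omega must be auto|full|scalar")
    F_list = [_kron_design(phi, design[s]) for s, phi in enumerate(phi_list)]
    st = _SuffStats(gene_obs.y, phi_list, F_list)
    res = _fit_em_core(st, scalar, tol=tol, max_iter=max_iter, fix_omega=fix_omega)
    B = res["theta"].reshape(K + 1, V + 1)
    params = FemmParams(B=B, Omega=res["Omega"], alpha=res["alpha"],
                        eta=res["eta"], omega_constrained=scalar)
    return FemmFit(
        params=params, K=K, loglik=res["loglik"], loglik_trace=res["trace"],
        n_iter=res["n_iter"], converged=res["converged"],
        posterior_mean_u=res["m"], posterior_uut=res["uut"],
        posterior_inv_sigma2=res["w"], gene_obs=gene_obs, design=design,
    )


def marginal_loglik(params: FemmParams, gene_obs: GeneObservations,
                    sample_design, K: int | None = None) -> float:
    """Marginal log-likelihood of the data under given parameters."""
    if K is None:
        K = params.B.shape[0] - 1
    design, basis, phi_list = _prepare(gene_obs, sample_design, K)
    F_list = [_kron_design(phi, design[s]) for s, phi in enumerate(phi_list)]
    st = _SuffStats(gene_obs.y, phi_list, F_list)
    _, _, _, q, _, _ = _estep(st, params.beta, params.Omega,
                              params.alpha, params.eta)
    return _marginal_ll(st, params.Omega, params.alpha, params.eta, q)


def posterior_effects(fit: FemmFit):
    """Per-sample posterior moments: E[u_s], E[u_s u_s^T], E[1/sigma_s^2]."""
    return fit.posterior_mean_u, fit.posterior_uut, fit.posterior_inv_sigma2


def predict_curves(
    fit: FemmFit,
    t_grid: np.ndarray,
    level: str = "population",
    x: np.ndarray | None = None,
    sample: int | str | None = None,
) -> np.ndarray:
    """Fitted curve values on a pseudotime grid.

    Population level: phi(t)^T B x for a covariate vector ``x`` (length V+1).
    Sample level: phi(t)^T (B x_s + E[u_s]) for one sample.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.min() < 0 or t_grid.max() > 1:
        raise ValueError("t_grid must lie in [0, 1]")
    phi = make_basis(fit.K)(t_grid)
    if level == "population":
        x = np.asarray(x, dtype=float)
        if x.shape != (fit.params.B.shape[1],):
            raise ValueError("x length must be V+1")
        return phi @ (fit.params.B @ x)
    if level == "sample":
        if sample is None:
            raise ValueError("sample required for sample-level curves")
        if not isinstance(sample, (int, np.integer)):
            sample = fit.gene_obs.samples.index(sample)
        b = fit.params.B @ fit.design[sample] + fit.posterior_mean_u[sample]
        return phi @ b
    raise ValueError("level must be population|sample")


# ---------------------------------------------------------------------------
# Knot selection by BIC
# ---------------------------------------------------------------------------

def _ols_loglik_per_sample(y, phi):
    """Gaussian max-loglik of an OLS B-spline regression for one sample."""
    C = y.size
    coef, *_ = np.linalg.lstsq(phi, y, rcond=None)
    rss = float(np.sum((y - phi @ coef) ** 2))
    sig2 = max(rss / C, 1e-300)
    return -0.5 * C * (np.log(2 * np.pi * sig2) + 1.0)


def bic_for_K(gene_obs: GeneObservations, K: int) -> float:
    """BIC_K = K S ln(sum_s C_s) - 2 sum_s l_{K,s} (constant dropped)."""
    basis = make_basis(K)
    total = gene_obs.total_cells
    ll = sum(_ols_loglik_per_sample(y, basis(t))
             for y, t in zip(gene_obs.y, gene_obs.t))
    return K * gene_obs.S * np.log(total) - 2.0 * ll


def select_K(gene_obs: GeneObservations, K_max: int = 20) -> int:
    """Smallest-BIC number of knots; candidates with C_s <= K+1 are skipped."""
    Cs = gene_obs.cells_per_sample
    best_K, best_bic = None, np.inf
    for K in range(K_max + 1):
        if (Cs <= K + 1).any():
            continue
        bic = bic_for_K(gene_obs, K)
        if bic < best_bic:
            best_K, best_bic = K, bic
    if best_K is None:
        raise ValueError("too few cells per sample for any candidate K")
    return best_K


def fit_summary(fits: dict) -> "pd.DataFrame":
    """Tabulate per-gene fit summaries (K, loglik, B, diag Omega, alpha, eta).

    ``fits`` maps gene id -> FemmFit; the frame is TSV/HDF5-serializable.
    """
    import pandas as pd

    rows = []
    for gene, fit in fits.items():
        row = {"gene": gene, "K": fit.K, "loglik": fit.loglik,
               "alpha": fit.params.alpha, "eta": fit.params.eta,
               "converged": fit.converged}
        for k in range(fit.params.B.shape[0]):
            for v in range(fit.params.B.shape[1]):
                row[f"beta_{k}_{v}"] = fit.params.B[k, v]
            row[f"omega_{k}{k}"] = fit.params.Omega[k, k]
        rows.append(row)
    return pd.DataFrame(rows)


def select_K_batch(
    Y_by_sample: list, t_by_sample: list, K_max: int = 20
) -> np.ndarray:
    """Vectorized BIC knot selection for many genes at once.

    ``Y_by_sample[s]`` is a C_s x G matrix of expression for sample s;
    ``t_by_sample[s]`` the matching pseudotimes.  Returns K* per gene.
    """
    S = len(Y_by_sample)
    G = Y_by_sample[0].shape[1]
    Cs = np.array([Y.shape[0] for Y in Y_by_sample])
    total = int(Cs.sum())
    bic = np.full((K_max + 1, G), np.inf)
    for K in range(K_max + 1):
        if (Cs <= K + 1).any():
            continue
        basis = make_basis(K)
        ll = np.zeros(G)
        for Y, t in zip(Y_by_sample, t_by_sample):
            phi = basis(t)
            gram = phi.T @ phi + _RIDGE * np.eye(K + 1)
            pty = phi.T @ Y
            coef = np.linalg.solve(gram, pty)
            rss = np.maximum(
                np.einsum("cg,cg->g", Y, Y) - np.einsum("kg,kg->g", coef, pty),
                1e-300,
            )
            C = Y.shape[0]
            ll += -0.5 * C * (np.log(2 * np.pi * rss / C) + 1.0)
        bic[K] = K * S * np.log(total) - 2.0 * ll
    return np.argmin(bic, axis=0)
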