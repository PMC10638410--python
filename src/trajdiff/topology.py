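"""Branch uncertainty and differential tree topology.

Branch stability is measured by a *detection rate*: cells are bootstrapped,
the trajectory is rebuilt with the same cluster count, and an original branch
counts as detected when some bootstrap branch overlaps it with a Jaccard index
above a null-calibrated cutoff (the 0.99 quantile of Jaccard indices between
the branch and size-matched random cell sets).

Cross-sample variability is summarized by per-sample *branch cell proportions*
(cells on the branch / cells in the sample; branches that share pre-branching
cells deliberately double-count them).  Covariate effects on proportions are
tested per branch with binomial logistic regression (Wald tests,
Benjamini-Hochberg across branches) or jointly with a baseline-category
multinomial logit whose reference is the most abundant branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trajectory import TrajectoryTree, build_trajectory, cell_pseudotime

logger = logging.getLogger("trajdiff")


# ---------------------------------------------------------------------------
# Jaccard machinery
# ---------------------------------------------------------------------------

def jaccard_index(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def jaccard_cutoff(branch_cells, all_cells, n_draws: int = 1000,
                   q: float = 0.99, seed: int = 1) -> float:
    """Null-calibrated Jaccard cutoff for one branch.

    Draws ``n_draws`` random cell sets of the branch's size from the universe
    and returns the ``q`` quantile of their Jaccard indices with the branch.
    """
    branch = set(branch_cells)
    universe = np.asarray(list(all_cells), dtype=object)
    if not branch:
        raise ValueError("empty branch")
    if len(branch) > universe.size:
        raise ValueError("branch larger than cell universe")
    rng = np.random.default_rng(seed)
    m = len(branch)
    stats = np.empty(n_draws)
    for i in range(n_draws):
        draw = rng.choice(universe.size, size=m, replace=False)
        inter = sum(1 for j in draw if universe[j] in branch)
        stats[i] = inter / (2 * m - inter)
    return float(np.quantile(stats, q))


@dataclass
class DetectionReport:
    branch_names: list
    cutoffs: np.ndarray
    detection_rates: np.ndarray
    n_bootstraps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "branch_id": self.branch_names,
            "cutoff": self.cutoffs,
            "detection_rate": self.detection_rates,
        })


def detection_rates(
    embedding,
    tree: TrajectoryTree,
    n_bootstraps: int = 1000,
    n_null_draws: int = 1000,
    seed: int = 1,
    resample: str = "bootstrap",
) -> DetectionReport:
    """Bootstrap detection rate per original branch.

    Each bootstrap resamples cells with replacement (duplicates collapse to
    unique identities for overlap computation), rebuilds the trajectory with
    the original cluster count, and roots it at the cluster whose cells have
    the smallest mean original pseudotime.  A branch is detected when any
    bootstrap branch reaches its Jaccard cutoff (calibrated once, on the
    original data).  ``resample="identity"`` is a degenerate hook that feeds
    the original cells back in (every branch must then be re-detected).
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    if resample not in ("bootstrap", "identity"):
        raise ValueError("resample must be bootstrap|identity")
    embedding = np.asarray(embedding, dtype=float)
    cell_ids = tree.cell_ids
    n = embedding.shape[0]
    rng = np.random.default_rng(seed)
    orig_pt = cell_pseudotime(tree)

    cutoffs = np.array([
        jaccard_cutoff(br.member_cells, cell_ids, n_draws=n_null_draws,
                       q=0.99, seed=rng.integers(2**31 - 1))
        for br in tree.branches
    ])
    orig_sets = [set(br.member_cells) for br in tree.branches]

    detected = np.zeros(len(tree.branches))
    done = 0
    attempts = 0
    while done < n_bootstraps and attempts < 3 * n_bootstraps:
        attempts += 1
        idx = (np.arange(n) if resample == "identity"
               else rng.integers(0, n, n))
        uniq = np.unique(idx)
        try:
            boot = build_trajectory(
                embedding[uniq], cell_ids=cell_ids[uniq], k=tree.n_clusters,
                origin=0, seed=int(rng.integers(2**31 - 1)),
            )
        except ValueError as exc:
            logger.warning("bootstrap trajectory failed (%s); redrawn", exc)
            continue
        # re-root at the cluster with smallest mean original pseudotime
        means = []
        for c in range(boot.n_clusters):
            cells_c = boot.cell_ids[boot.cluster_of_cell == c]
            means.append(orig_pt.reindex(cells_c).mean())
        origin = int(np.nanargmin(means))
        if origin != boot.origin_cluster:
            boot = build_trajectory(
                embedding[uniq], cell_ids=cell_ids[uniq], k=tree.n_clusters,
                origin=origin, seed=int(rng.integers(2**31 - 1)),
            )
        boot_sets = [set(br.member_cells) for br in boot.branches]
        for bi, (oset, cut) in enumerate(zip(orig_sets, cutoffs)):
            best = max((jaccard_index(oset, bs) for bs in boot_sets),
                       default=0.0)
            if best >= cut:
                detected[bi] += 1
        done += 1
    if done < n_bootstraps:
        raise RuntimeError("too many failed bootstrap trajectories")
    return DetectionReport(
        branch_names=[br.name for br in tree.branches],
        cutoffs=cutoffs,
        detection_rates=detected / n_bootstraps,
        n_bootstraps=n_bootstraps,
    )


# ---------------------------------------------------------------------------
# Branch proportions
# ---------------------------------------------------------------------------

@dataclass
class BranchProportions:
    proportions: pd.DataFrame  # samples x branches
    counts: pd.DataFrame       # samples x branches
    totals: pd.Series          # cells per sample

    @property
    def mean(self) -> pd.Series:
        return self.proportions.mean(axis=0)

    @property
    def variance(self) -> pd.Series:
        return self.proportions.var(axis=0, ddof=1)


def branch_proportions(tree: TrajectoryTree, sample_of_cell) -> BranchProportions:
    """Per-sample branch cell proportions (branch cells / sample cells)."""
    sample_of_cell = pd.Series(sample_of_cell, index=tree.cell_ids)
    samples = sorted(sample_of_cell.unique())
    totals = sample_of_cell.value_counts().reindex(samples)
    empty = totals[totals == 0].index.tolist()
    if empty:
        logger.warning("excluding samples with zero cells: %s", empty)
        samples = [s for s in samples if s not in empty]
        totals = totals.loc[samples]
    names = [br.name for br in tree.branches]
    counts = pd.DataFrame(0, index=samples, columns=names, dtype=int)
    for br in tree.branches:
        vc = sample_of_cell.loc[list(br.member_cells)].value_counts()
        counts[br.name] = vc.reindex(samples).fillna(0).astype(int)
    props = counts.div(totals, axis=0)
    return BranchProportions(proportions=props, counts=counts, totals=totals)


# ---------------------------------------------------------------------------
# Differential topology tests
# ---------------------------------------------------------------------------

def _wald_frame(params, bse, names, covariates):
    from scipy.stats import norm as _norm

    rows = []
    for cov in covariates:
        i = names.index(cov)
        if not np.isfinite(bse[i]) or bse[i] > 1e5:
            rows.append((cov, params[i], np.nan, np.nan))
        else:
            z = params[i] / bse[i]
            rows.append((cov, params[i], z, 2 * _norm.sf(abs(z))))
    return rows


def test_topology_binomial(proportions: BranchProportions,
                           sample_design: pd.DataFrame) -> pd.DataFrame:
    """Per-branch binomial logistic regression of branch counts on covariates.

    Wald p-value per non-intercept covariate; BH FDR across branches within
    each covariate.  Complete separation leaves the coefficient flagged
    non-estimable (p = NA).
    """
    from .diffexpr import bh_adjust

    design = sample_design.loc[proportions.counts.index]
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    covs = [c for c in design.columns if c != design.columns[0]]
    rows = []
    for branch in proportions.counts.columns:
        k = proportions.counts[branch].to_numpy(dtype=float)
        n = proportions.totals.to_numpy(dtype=float)
        endog = np.c_[k, np.maximum(n - k, 0.0)]
        sep = np.all(k == 0) or np.all(k >= n)
        if sep:
            for cov in covs:
                rows.append(dict(branch=branch, covariate=cov,
                                 coefficient=np.nan, statistic=np.nan,
                                 p_value=np.nan))
            continue
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        try:
            fit = model.fit()
            for cov, coef, z, p in _wald_frame(
                    fit.params, fit.bse, list(design.columns), covs):
                rows.append(dict(branch=branch, covariate=cov,
                                 coefficient=coef, statistic=z, p_value=p))
        except Exception as exc:  # noqa: BLE001
            logger.warning("binomial fit failed for %s: %s", branch, exc)
            for cov in covs:
                rows.append(dict(branch=branch, covariate=cov,
                                 coefficient=np.nan, statistic=np.nan,
                                 p_value=np.nan))
    res = pd.DataFrame(rows)
    res["fdr"] = np.nan
    for cov in covs:
        mask = res["covariate"] == cov
        res.loc[mask, "fdr"] = bh_adjust(res.loc[mask, "p_value"])
    return res


def test_topology_multinomial(counts: pd.DataFrame,
                              sample_design: pd.DataFrame) -> pd.DataFrame:
    """Baseline-category multinomial logit over all branches jointly.

    The reference branch is the most abundant one (largest total cell count);
    log(p_l / p_ref) is modeled per non-reference branch.  Wald p per
    (branch, covariate); fitted by ML on cell-level expanded data.
    """
    from .diffexpr import bh_adjust

    if counts.shape[1] < 2:
        raise ValueError("need >= 2 branches")
    design = sample_design.loc[counts.index]
    ref = counts.sum(axis=0).idxmax()
    branches = [b for b in counts.columns if b != ref]
    order = [ref] + branches  # category 0 = reference
    # expand counts to one row per cell
    X_rows, y_rows = [], []
    Xmat = design.to_numpy(dtype=float)
    for si in range(counts.shape[0]):
        for bi, b in enumerate(order):
            c = int(counts.iloc[si][b])
            if c > 0:
                X_rows.append(np.tile(Xmat[si], (c, 1)))
                y_rows.append(np.full(c, bi))
    X = np.vstack(X_rows)
    y = np.concatenate(y_rows)
    covs = [c for c in design.columns if c != design.columns[0]]
    try:
        fit = sm.MNLogit(y, X).fit(disp=False, maxiter=200)
        params = np.asarray(fit.params)        # (V+1) x (L-1)
        bse = np.asarray(fit.bse)
    except Exception as exc:  # noqa: BLE001
        logger.warning("multinomial fit failed: %s", exc)
        params = np.full((Xmat.shape[1], len(branches)), np.nan)
        bse = params.copy()
    from scipy.stats import norm as _norm

    rows = []
    names = list(design.columns)
    for li, b in enumerate(branches):
        for cov in covs:
            i = names.index(cov)
            coef, se = params[i, li], bse[i, li]
            if not np.isfinite(se) or se > 1e5:
                rows.append(dict(branch=b, reference=ref, covariate=cov,
                                 coefficient=np.nan, statistic=np.nan,
                                 p_value=np.nan))
            else:
                z = coef / se
                rows.append(dict(branch=b, reference=ref, covariate=cov,
                                 coefficient=coef, statistic=z,
                                 p_value=2 * _norm.sf(abs(z))))
    res = pd.DataFrame(rows)
    res["fdr"] = np.nan
    for cov in covs:
        mask = res["covariate"] == cov
        res.loc[mask, "fdr"] = bh_adjust(res.loc[mask, "p_value"])
    return res
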