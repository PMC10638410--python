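"""Cell density changes along pseudotime (TCD) and across covariates (XCD).

The pseudotime axis of a branch is divided from 0 to its maximum into equal
intervals (100 by default).  Counting cells of sample ``s`` in interval ``t``
gives ``r_st``; dividing by the sample's total branch cell count ``L_s``
yields per-interval density ratios that sum to one per sample.  The ratios are
then modeled exactly like gene expression — intervals play the role of cells,
placed at interval midpoints — so density testing reuses the TDE and XDE
machinery: a TCD test permutes interval order within samples, an XCD test
permutes the covariate across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import (
    _as_init,
    _tde_llr_once,
    _xde_llrs_once,
    chisq_pvalue,
    kde_tail_pvalue,
)
from .femm import GeneObservations, make_basis, scalar_omega_required, select_K

logger = logging.getLogger("trajdiff")

LOW_COUNT_FLAG = 20  # samples with fewer branch cells have unstable ratios


@dataclass
class DensityMatrix:
    counts: pd.DataFrame     # samples x intervals, r_st
    totals: pd.Series        # L_s per sample
    midpoints: np.ndarray    # interval midpoints on [0, 1]

    @property
    def ratios(self) -> pd.DataFrame:
        return self.counts.div(self.totals, axis=0)

    def to_frame(self) -> pd.DataFrame:
        ratios = self.ratios
        rows = []
        for s in self.counts.index:
            for i, mid in enumerate(self.midpoints):
                rows.append((s, i, mid, int(self.counts.iloc[:, i][s]),
                             ratios.iloc[:, i][s]))
        return pd.DataFrame(rows, columns=["sample", "interval", "midpoint",
                                           "count", "ratio"])


def density_matrix(branch, sample_of_cell, n_intervals: int = 100) -> DensityMatrix:
    """Interval counts of branch cells per sample.

    ``branch`` is a trajectory Branch or a Series mapping cell -> pseudotime;
    pseudotime is normalized by its global maximum over the branch, and the
    intervals are half-open [i/n, (i+1)/n) with the last one closed.
    """
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    if hasattr(branch, "pseudotime"):
        pt = pd.Series(branch.pseudotime, dtype=float)
    else:
        pt = pd.Series(branch, dtype=float)
    tmax = pt.max()
    t = (pt / tmax if tmax > 0 else pt).to_numpy()
    samples_of = pd.Series(sample_of_cell)
    samples_of = samples_of.reindex(pt.index)
    if samples_of.isna().any():
        raise ValueError("every branch cell needs a sample label")
    bins = np.minimum((t * n_intervals).astype(int), n_intervals - 1)
    samples = sorted(samples_of.unique())
    counts = pd.DataFrame(0, index=samples, columns=range(n_intervals), dtype=int)
    for s in samples:
        idx = bins[(samples_of == s).to_numpy()]
        binc = np.bincount(idx, minlength=n_intervals)
        counts.loc[s] = binc
    totals = counts.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        logger.warning("dropping samples with zero branch cells: %s", zero)
        counts = counts.drop(index=zero)
        totals = totals.drop(index=zero)
    low = totals[totals < LOW_COUNT_FLAG].index.tolist()
    if low:
        logger.warning("samples with < %d branch cells (unstable ratios): %s",
                       LOW_COUNT_FLAG, low)
    mids = (np.arange(n_intervals) + 0.5) / n_intervals
    return DensityMatrix(counts=counts, totals=totals, midpoints=mids)


def _density_observations(density: DensityMatrix) -> GeneObservations:
    ratios = density.ratios
    y = [ratios.loc[s].to_numpy(dtype=float) for s in ratios.index]
    t = [density.midpoints.copy() for _ in ratios.index]
    return GeneObservations(y, t, list(ratios.index))


def tcd_test(
    density: DensityMatrix,
    mode: str = "pm",
    n_perm: int = 100,
    seed: int = 1,
    K_max: int = 10,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Does cell density change along pseudotime?

    Density ratios are fed through the pseudotemporal-expression machinery;
    the permutation null shuffles interval order within each sample.
    """
    if density.counts.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    obs = _density_observations(density)
    K = select_K(obs, K_max=K_max)
    design = np.ones((obs.S, 1))
    scalar = scalar_omega_required(obs.S, 0, K)
    phi_list = [make_basis(K)(t) for t in obs.t]
    if K == 0:
        llr, p = 0.0, 1.0
    else:
        llr, (h0, _) = _tde_llr_once(obs.y, phi_list, design, scalar,
                                     tol, max_iter)
        if mode == "chisq":
            p = chisq_pvalue(llr, K)
        else:
            rng = np.random.default_rng(seed)
            null = []
            for _ in range(n_perm):
                boot = [rng.integers(0, len(y), len(y)) for y in obs.y]
                y_b = [y[i] for y, i in zip(obs.y, boot)]
                phi_b = [phi[i][rng.permutation(len(i))]
                         for phi, i in zip(phi_list, boot)]
                null.append(_tde_llr_once(y_b, phi_b, design, scalar,
                                          tol, max_iter,
                                          init0=_as_init(h0))[0])
            p = kde_tail_pvalue(llr, null)
    return pd.DataFrame([dict(test="tcd", K=K, llr=llr, p_value=p,
                              n_permutations=n_perm if mode == "pm" else 0)])


def xcd_test(
    density: DensityMatrix,
    sample_design: pd.DataFrame,
    covariate,
    mode: str = "pm",
    n_perm: int = 100,
    seed: int = 1,
    K_max: int = 10,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Does a sample covariate change the pseudotemporal density curve?

    Density ratios go through the covariate-test machinery (the overall test
    only); the permutation null shuffles the covariate across samples.
    """
    if density.counts.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    obs = _density_observations(density)
    design = sample_design.loc[list(density.counts.index)]
    v = (list(design.columns).index(covariate)
         if isinstance(covariate, str) else int(covariate))
    X = design.to_numpy(dtype=float)
    K = select_K(obs, K_max=K_max)
    scalar = scalar_omega_required(obs.S, X.shape[1] - 1, K)
    phi_list = [make_basis(K)(t) for t in obs.t]
    llr, _, _, (f0, _, _) = _xde_llrs_once(obs.y, phi_list, X, v, scalar,
                                           tol, max_iter)
    if mode == "chisq":
        p = chisq_pvalue(llr, K + 1)
    else:
        rng = np.random.default_rng(seed)
        null = []
        for _ in range(n_perm):
            boot = [rng.integers(0, len(y), len(y)) for y in obs.y]
            y_b = [y[i] for y, i in zip(obs.y, boot)]
            phi_b = [phi[i] for phi, i in zip(phi_list, boot)]
            X_b = X.copy()
            X_b[:, v] = X[rng.permutation(obs.S), v]
            lo, _, _, _ = _xde_llrs_once(y_b, phi_b, X_b, v, scalar, tol,
                                         max_iter, init0=_as_init(f0))
            null.append(lo)
        p = kde_tail_pvalue(llr, null)
    return pd.DataFrame([dict(test="xcd", K=K, llr=llr, p_value=p,
                              n_permutations=n_perm if mode == "pm" else 0)])
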