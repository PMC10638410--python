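"""Benchmark metrics: FDR calibration, sensitivity AUC, and ranked-overlap
permutation tests against a gold gene set."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CalibrationCurve:
    reported_grid: np.ndarray
    realized_fdr: np.ndarray
    fdr_difference: float
    sensitivity: np.ndarray
    auc: float | None = None


def realized_fdr_at(reported, truth, cutoff: float) -> float:
    """Realized false discovery proportion at one reported-FDR cutoff.

    Zero discoveries are assigned realized FDR 0 (conservative for the method
    under evaluation).
    """
    reported = np.asarray(reported, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    disc = reported <= cutoff
    n = int(disc.sum())
    if n == 0:
        return 0.0
    return float((~truth[disc]).sum() / n)


def fdr_curve_difference(reported_fdr, truth) -> CalibrationCurve:
    """Area between the realized-vs-reported FDR curve and the diagonal.

    Realized FDR is recomputed at every reported value (ties grouped:
    discoveries are reported <= cutoff); the curve is trapezoid-integrated on
    the [0, 1] reported-FDR domain and the diagonal's area (0.5) subtracted.
    Positive values mean anticonservative reporting.
    """
    reported = np.asarray(reported_fdr, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if reported.shape != truth.shape:
        raise ValueError("reported_fdr and truth must align")
    ok = np.isfinite(reported)
    reported, truth = reported[ok], truth[ok]
    if np.any((reported < 0) | (reported > 1)):
        raise ValueError("reported FDR values must be in [0, 1]")
    grid = np.unique(np.concatenate([[0.0, 1.0], reported]))
    realized = np.array([realized_fdr_at(reported, truth, c) for c in grid])
    n_true = int(truth.sum())
    sens = np.array([
        (truth & (reported <= c)).sum() / n_true if n_true else np.nan
        for c in grid
    ])
    area = float(np.trapezoid(realized, grid))
    return CalibrationCurve(
        reported_grid=grid, realized_fdr=realized,
        fdr_difference=area - 0.5, sensitivity=sens,
    )


def sensitivity_realfdr_auc(scores_or_fdrs, truth) -> float:
    """Area under the sensitivity ~ realized-FDR curve.

    Cutoffs sweep the ranking (ascending scores = most significant first);
    for each prefix the realized FDR and sensitivity are recorded, the best
    sensitivity achievable at each realized-FDR level forms a step curve on
    [0, 1], right-extended at the final sensitivity.
    """
    scores = np.asarray(scores_or_fdrs, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_true = int(truth.sum())
    if n_true == 0:
        raise ValueError("no true genes: sensitivity undefined")
    order = np.argsort(scores, kind="stable")
    hits = truth[order]
    tp = np.cumsum(hits)
    k = np.arange(1, scores.size + 1)
    realfdr = (k - tp) / k
    sens = tp / n_true
    # best sensitivity at or below each realized-FDR level: a right-continuous
    # step curve, integrated as such (right-extended at the final sensitivity)
    xs = np.sort(np.unique(np.r_[realfdr, 0.0, 1.0]))
    best = np.zeros_like(xs)
    for i, x in enumerate(xs):
        mask = realfdr <= x
        best[i] = sens[mask].max() if mask.any() else 0.0
    best = np.maximum.accumulate(best)
    return float(np.sum(best[:-1] * np.diff(xs)) + 0.0)


def topn_overlap_test(
    ranked_genes,
    gold_set,
    n_grid=None,
    n_perm: int = 10000,
    seed: int = 1,
):
    """Mean top-N overlap with a gold set, against a rank-permutation null.

    ``ranked_genes`` are ordered by increasing FDR (most significant first).
    The statistic is the mean over N in ``n_grid`` of |top-N intersection
    gold|; the null permutes gene order; one-sided
    p = (1 + #null >= observed) / (n_perm + 1).
    """
    ranked = list(ranked_genes)
    gold = set(gold_set)
    if not gold:
        raise ValueError("empty gold set")
    if not gold <= set(ranked):
        raise ValueError("gold set must be a subset of the ranked genes")
    n = len(ranked)
    if n_grid is None:
        n_grid = [N for N in range(10, 501, 10) if N <= n] or [n]
    n_grid = np.asarray(sorted(n_grid))
    is_gold = np.array([g in gold for g in ranked])
    cum = np.cumsum(is_gold)
    observed = float(cum[n_grid - 1].mean())
    rng = np.random.default_rng(seed)
    g = len(gold)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=g, replace=False))
        null[i] = np.searchsorted(pos, n_grid, side="right").mean()
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return observed, null, p
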