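"""Synthetic data generators and benchmark constructions.

Four generators cover the benchmark designs used throughout the package:

* :func:`simulate_femm_data` — samples multi-sample pseudotemporal expression
  directly from the functional mixed-effects generative model (B-spline fixed
  effects, sample random effects with inverse-gamma cell-noise variances).
* :func:`make_null_by_median_matching` — removes any residual between-group
  signal by equalizing per-pseudotime-interval group medians, gene by gene:
  the construction used to build ground-truth null datasets.
* :func:`select_source_genes` / :func:`spike_in` — the spike-in design:
  dynamic "source" gene profiles, stratified by an F-statistic into four
  signal strengths, are added to randomly chosen gold-standard genes as pure
  trend, pure mean-shift, or combined covariate signals.
* :func:`simulate_branch_reduction` and :func:`simulate_branch_counts` — the
  branch-cell-reduction topology designs.

Defaults encode the benchmark study conditions: 8 samples split 4/4 into two
groups, ~300 cells per sample, 1000 genes, 20% gold-standard genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .femm import make_basis
from .io import MultiSampleDataset

logger = logging.getLogger("trajdiff")


@dataclass
class SimConfig:
    """Generative-model settings for the fully synthetic base dataset."""

    S: int = 8
    G: int = 1000
    cells_per_sample: tuple = (250, 350)
    K_true: int = 3
    V: int = 1
    B_intercept_sd: float = 1.0   # spread of per-gene curve coefficients
    B_intercept_mean: float = 1.5
    omega2_true: float = 0.09     # sample random-effect variance scale
    alpha_true: float = 3.0
    eta_true: float = 2.0         # E[sigma^2] = eta/(alpha-1) = 1
    gs_fraction: float = 0.2
    n_strengths: int = 4
    n_source_clusters: int = 5
    n_intervals: int = 100

    def __post_init__(self):
        if not 0 < self.gs_fraction < 1:
            raise ValueError("gs_fraction must be in (0, 1)")
        if min(self.S, self.G, self.K_true + 1, self.V + 1,
               self.n_strengths, self.n_intervals) <= 0:
            raise ValueError("all counts must be positive")
        if self.alpha_true <= 1:
            logger.warning("alpha <= 1: cell-noise variance has no finite mean")


def simulate_femm_data(config: SimConfig = None, seed: int = 1,
                       B_covariate=None):
    """Sample a multi-sample dataset from the generative model.

    Per gene: sigma_s^2 ~ InvGamma(alpha, eta), u_s ~ N(0, sigma_s^2 omega^2 I),
    pseudotime uniform on [0, 1], and y_sc = phi(t_sc)^T (B x_s + u_s) + eps_sc.
    ``B_covariate`` optionally supplies non-null covariate columns (G x (K+1)
    per covariate); the default is a global null (covariate effect zero).

    Returns ``(dataset, truth)`` where truth carries the pseudotime, group
    labels and the true parameters per gene.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    S, G, K = config.S, config.G, config.K_true
    basis = make_basis(K)

    n_cells = rng.integers(config.cells_per_sample[0],
                           config.cells_per_sample[1] + 1, size=S)
    samples = [f"s{j}" for j in range(S)]
    group = np.r_[np.zeros(S - S // 2), np.ones(S // 2)]
    design = pd.DataFrame(
        {"intercept": 1.0, "group": group}, index=samples)

    t_by = [np.sort(rng.uniform(0, 1, int(c))) for c in n_cells]
    phi_by = [basis(t) for t in t_by]

    # gamma-distributed basis coefficients: log-scale expression curves are
    # nonnegative, and genes with higher expression have larger dynamic range
    # (the mean~SD coupling the source-gene selection relies on)
    shape = (config.B_intercept_mean / config.B_intercept_sd) ** 2
    scale = config.B_intercept_sd ** 2 / config.B_intercept_mean
    B0 = rng.gamma(shape, scale, (G, K + 1))
    Bv = np.zeros((G, K + 1)) if B_covariate is None else np.asarray(B_covariate)

    expr_blocks = []
    sig2_all = np.empty((G, S))
    for s in range(S):
        C = int(n_cells[s])
        sig2 = 1.0 / rng.gamma(config.alpha_true, 1.0 / config.eta_true, G)
        sig2_all[:, s] = sig2
        u = rng.normal(0, 1, (G, K + 1)) * np.sqrt(
            sig2[:, None] * config.omega2_true)
        b = B0 + group[s] * Bv + u                      # G x (K+1)
        noise = rng.normal(0, 1, (G, C)) * np.sqrt(sig2)[:, None]
        expr_blocks.append(b @ phi_by[s].T + noise)     # G x C_s
    expression = np.hstack(expr_blocks)

    cell_ids = np.concatenate([
        np.array([f"s{j}_c{i}" for i in range(int(n_cells[j]))], dtype=object)
        for j in range(S)
    ])
    sample_of_cell = np.concatenate([
        np.full(int(n_cells[j]), samples[j], dtype=object) for j in range(S)
    ])
    t_all = np.concatenate(t_by)
    embedding = np.c_[t_all, rng.normal(0, 0.05, t_all.size)]

    dataset = MultiSampleDataset(
        expression=expression,
        gene_ids=np.array([f"g{i}" for i in range(G)], dtype=object),
        cell_ids=cell_ids,
        sample_of_cell=sample_of_cell,
        embedding=embedding,
        sample_design=design,
    )
    truth = dict(
        pseudotime=pd.Series(t_all, index=cell_ids),
        group=pd.Series(group, index=samples),
        B_intercept=B0, B_covariate=Bv,
        sigma2=sig2_all, omega2=config.omega2_true,
        alpha=config.alpha_true, eta=config.eta_true, config=config,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Median-matching null
# ---------------------------------------------------------------------------

def make_null_by_median_matching(
    dataset: MultiSampleDataset,
    group_labels,
    pseudotime: pd.Series,
    n_intervals: int = 100,
) -> MultiSampleDataset:
    """Equalize per-interval group medians so no covariate signal remains.

    Pseudotime is split into ``n_intervals`` equal intervals; within each
    interval and gene, the cells of the group with the lower median are
    shifted up by the between-group median difference.  Intervals empty in
    either group are skipped.  The construction is idempotent.
    """
    group_labels = pd.Series(group_labels)
    groups = sorted(group_labels.unique())
    if len(groups) != 2:
        raise ValueError("median matching needs exactly two sample groups")
    expr = np.asarray(dataset.expression[...], dtype=float).copy()
    t = pseudotime.reindex(dataset.cell_ids).to_numpy(dtype=float)
    tmax = np.nanmax(t)
    bins = np.minimum(((t / tmax if tmax > 0 else t) * n_intervals).astype(int),
                      n_intervals - 1)
    cell_group = group_labels.loc[dataset.sample_of_cell].to_numpy()
    skipped = 0
    for i in range(n_intervals):
        in_bin = bins == i
        g0 = np.flatnonzero(in_bin & (cell_group == groups[0]))
        g1 = np.flatnonzero(in_bin & (cell_group == groups[1]))
        if g0.size == 0 or g1.size == 0:
            skipped += 1
            continue
        med0 = np.median(expr[:, g0], axis=1)
        med1 = np.median(expr[:, g1], axis=1)
        diff = med1 - med0
        expr[:, g0] += np.maximum(diff, 0.0)[:, None]
        expr[:, g1] += np.maximum(-diff, 0.0)[:, None]
    if skipped:
        logger.info("median matching skipped %d intervals empty in one group",
                    skipped)
    return MultiSampleDataset(
        expression=expr, gene_ids=dataset.gene_ids, cell_ids=dataset.cell_ids,
        sample_of_cell=dataset.sample_of_cell, embedding=dataset.embedding,
        sample_design=dataset.sample_design,
    )


# ---------------------------------------------------------------------------
# Gold-standard labels and spike-in
# ---------------------------------------------------------------------------

TRUTH_TYPES = ("trend", "mean", "both")


def assign_gold_labels(gene_ids, gs_fraction: float = 0.2,
                       seed: int = 1) -> pd.DataFrame:
    """Randomly pick gold-standard genes and assign truth types.

    Returns a table (gene, truth) where truth is "null" for non-gold genes
    and one of trend/mean/both (balanced) for gold genes.
    """
    rng = np.random.default_rng(seed)
    genes = np.asarray(gene_ids, dtype=object)
    n_gold = int(round(gs_fraction * genes.size))
    gold = rng.choice(genes.size, size=n_gold, replace=False)
    truth = np.full(genes.size, "null", dtype=object)
    types = np.array(TRUTH_TYPES, dtype=object)[
        np.arange(n_gold) % len(TRUTH_TYPES)]
    rng.shuffle(types)
    truth[gold] = types
    return pd.DataFrame({"gene": genes, "truth": truth})


def _fstat_spline_vs_constant(y, t, K=3):
    phi = make_basis(K)(t)
    coef, *_ = np.linalg.lstsq(phi, y, rcond=None)
    rss1 = float(np.sum((y - phi @ coef) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df1, df2 = K, y.size - (K + 1)
    if df2 <= 0 or rss1 <= 0:
        return np.inf
    return ((rss0 - rss1) / df1) / (rss1 / df2)


def select_source_genes(
    dataset: MultiSampleDataset,
    group0_samples,
    pseudotime: pd.Series,
    candidate_genes,
    n_gold: int,
    n_strengths: int = 4,
    n_source_clusters: int = 5,
    seed: int = 1,
) -> dict:
    """Pick highly variable source genes and stratify them by dynamic range.

    Using group-0 cells only: genes whose expression SD exceeds the value a
    B-spline SD~mean fit predicts are highly variable; these are clustered by
    standardized binned profile (cluster ids recorded), ranked by the
    F-statistic of a spline-vs-constant fit against pseudotime, and the tail
    ``n_gold`` genes are split into ``n_strengths`` equal strata from weakest
    (1) to strongest (n_strengths).
    """
    from sklearn.cluster import KMeans

    candidate_genes = list(candidate_genes)
    cells0 = np.flatnonzero(pd.Series(dataset.sample_of_cell)
                            .isin(list(group0_samples)).to_numpy())
    if cells0.size == 0:
        raise ValueError("no cells in group 0")
    gidx = np.array([dataset.gene_index(g) for g in candidate_genes])
    expr0 = np.asarray(dataset.expression[...], dtype=float)[gidx][:, cells0]
    mean = expr0.mean(axis=1)
    sd = expr0.std(axis=1)
    # SD ~ mean spline fit on min-max scaled means
    span = mean.max() - mean.min()
    mscaled = (mean - mean.min()) / (span if span > 0 else 1.0)
    phi = make_basis(3)(mscaled)
    coef, *_ = np.linalg.lstsq(phi, sd, rcond=None)
    resid = sd - phi @ coef
    hv = resid > 0
    hv_genes = [g for g, keep in zip(candidate_genes, hv) if keep]
    if len(hv_genes) < n_gold:
        raise ValueError(
            f"only {len(hv_genes)} highly variable genes for {n_gold} gold "
            "genes; reduce gs_fraction")

    t0 = pseudotime.reindex(np.asarray(dataset.cell_ids)[cells0]).to_numpy()
    order_t = np.argsort(t0)
    # cluster HV genes on standardized binned profiles
    n_bins = 50
    bins = np.minimum((t0[order_t] * n_bins).astype(int), n_bins - 1)
    prof = np.zeros((len(hv_genes), n_bins))
    hv_rows = expr0[hv][:, order_t]
    for b in range(n_bins):
        m = bins == b
        if m.any():
            prof[:, b] = hv_rows[:, m].mean(axis=1)
    mu = prof.mean(axis=1, keepdims=True)
    sdp = prof.std(axis=1, keepdims=True)
    sdp[sdp == 0] = 1.0
    clusters = KMeans(n_clusters=min(n_source_clusters, len(hv_genes)),
                      n_init=10, random_state=seed).fit_predict(
        (prof - mu) / sdp)

    t_sorted = t0[order_t]
    fstats = np.array([
        _fstat_spline_vs_constant(row, t_sorted) for row in hv_rows
    ])
    info = pd.DataFrame({"gene": hv_genes, "F": fstats, "cluster": clusters})
    info = info.sort_values("F", kind="stable").reset_index(drop=True)
    tail = info.tail(n_gold).reset_index(drop=True)
    strata = {}
    for level, part in enumerate(
            np.array_split(np.arange(len(tail)), n_strengths), start=1):
        strata[level] = list(tail["gene"].iloc[part])
    return dict(info=info, strata=strata)


def spike_in(
    null_dataset: MultiSampleDataset,
    labels: pd.DataFrame,
    source_strata: dict,
    pseudotime: pd.Series,
    group_labels,
    strength_level: int = 2,
    multiplier: float = 1.0,
    source_dataset: MultiSampleDataset | None = None,
    seed: int = 1,
):
    """Add differential signals from source genes to gold-standard genes.

    Per gold gene, a source gene from the requested strength stratum donates
    its per-sample expression profile (ordered by pseudotime, scaled by
    ``multiplier``):

    * ``trend``  — added as-is to group 0 and within-sample permuted to
      group 1 (same marginal, different shape: pure trend contrast);
    * ``mean``   — within-sample permuted before adding to group 0 only
      (adds the source's mean without its shape);
    * ``both``   — added as-is to group 0 only.

    When source and target samples have unequal cell counts the source values
    are interpolated over pseudotime.  ``multiplier=0`` returns the null data
    unchanged.  Returns (dataset, labels-with-strengths).
    """
    rng = np.random.default_rng(seed)
    if strength_level not in source_strata:
        raise ValueError(f"no stratum for strength level {strength_level}")
    src = source_dataset if source_dataset is not None else null_dataset
    group_labels = pd.Series(group_labels)
    groups = sorted(group_labels.unique())
    expr = np.asarray(null_dataset.expression[...], dtype=float).copy()

    cells_by_sample = {
        s: null_dataset.cells_of_sample(s) for s in null_dataset.samples}
    t_all = pseudotime.reindex(null_dataset.cell_ids).to_numpy(dtype=float)
    order_by_sample = {
        s: idx[np.argsort(t_all[idx])] for s, idx in cells_by_sample.items()}

    pool = list(source_strata[strength_level])
    rng.shuffle(pool)
    gold = labels[labels["truth"] != "null"].reset_index(drop=True)
    out_labels = labels.copy()
    out_labels["strength"] = np.where(labels["truth"] != "null",
                                      strength_level, 0)
    out_labels["source_gene"] = None

    src_expr = np.asarray(src.expression[...], dtype=float)
    src_t = pseudotime.reindex(src.cell_ids).to_numpy(dtype=float)
    src_order = {s: np.flatnonzero(src.sample_of_cell == s) for s in src.samples}
    src_order = {s: idx[np.argsort(src_t[idx])] for s, idx in src_order.items()}

    for i, row in gold.iterrows():
        source = pool[i % len(pool)]
        out_labels.loc[out_labels["gene"] == row["gene"], "source_gene"] = source
        si = src.gene_index(source)
        ti = null_dataset.gene_index(row["gene"])
        for s in null_dataset.samples:
            tgt = order_by_sample[s]
            sidx = src_order[s]
            signal = src_expr[si, sidx] * multiplier
            if sidx.size != tgt.size:  # align by pseudotime rank
                logger.debug("interpolating source profile for sample %s", s)
                signal = np.interp(t_all[tgt], src_t[sidx], signal)
            g = group_labels.loc[s]
            if row["truth"] == "trend":
                add = signal if g == groups[0] else rng.permutation(signal)
            elif row["truth"] == "mean":
                add = rng.permutation(signal) if g == groups[0] else None
            else:  # both
                add = signal if g == groups[0] else None
            if add is not None:
                expr[ti, tgt] += add
    dataset = MultiSampleDataset(
        expression=expr, gene_ids=null_dataset.gene_ids,
        cell_ids=null_dataset.cell_ids,
        sample_of_cell=null_dataset.sample_of_cell,
        embedding=null_dataset.embedding,
        sample_design=null_dataset.sample_design,
    )
    return dataset, out_labels


def build_spikein_benchmark(
    seed: int = 1,
    config: SimConfig = None,
    strength_level: int = 2,
    multiplier: float = 1.0,
):
    """End-to-end spike-in benchmark: base data -> median-matched null ->
    spike-in.  Returns (dataset, labels, pseudotime, group labels)."""
    config = config or SimConfig()
    rng = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng]
    base, truth = simulate_femm_data(config, seed=seeds[0])
    pt, group = truth["pseudotime"], truth["group"]
    null = make_null_by_median_matching(base, group, pt,
                                        n_intervals=config.n_intervals)
    labels = assign_gold_labels(base.gene_ids, gs_fraction=config.gs_fraction,
                                seed=seeds[1])
    nongold = labels.loc[labels["truth"] == "null", "gene"]
    n_gold = int((labels["truth"] != "null").sum())
    group0 = group[group == 0].index
    sources = select_source_genes(
        base, group0, pt, nongold, n_gold,
        n_strengths=config.n_strengths,
        n_source_clusters=config.n_source_clusters, seed=seeds[1],
    )
    bench, labels = spike_in(
        null, labels, sources["strata"], pt, group,
        strength_level=strength_level, multiplier=multiplier,
        source_dataset=base, seed=seeds[2],
    )
    return bench, labels, pt, group


# ---------------------------------------------------------------------------
# Topology simulations
# ---------------------------------------------------------------------------

def simulate_branch_reduction(
    dataset: MultiSampleDataset,
    tree,
    branch,
    fraction: float,
    samples: str = "all",
    seed: int = 1,
) -> MultiSampleDataset:
    """Uniformly remove a fraction of one branch's cells.

    ``samples``: "all" removes from every sample, "half" from the first half
    of the sample list only.  Other branches' exclusive cells are untouched.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    br = next(b for b in tree.branches
              if b is branch or b.name == branch)
    target_samples = (dataset.samples if samples == "all"
                      else dataset.samples[: len(dataset.samples) // 2])
    pos = pd.Series(np.arange(dataset.n_cells), index=dataset.cell_ids)
    branch_idx = pos.loc[[c for c in br.member_cells
                          if c in pos.index]].to_numpy()
    in_target = pd.Series(dataset.sample_of_cell).isin(target_samples)
    removable = branch_idx[in_target.to_numpy()[branch_idx]]
    n_remove = int(round(fraction * removable.size))
    removed = rng.choice(removable, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(dataset.n_cells), removed)
    return MultiSampleDataset(
        expression=np.asarray(dataset.expression[...], float)[:, keep],
        gene_ids=dataset.gene_ids, cell_ids=dataset.cell_ids[keep],
        sample_of_cell=dataset.sample_of_cell[keep],
        embedding=dataset.embedding[keep],
        sample_design=dataset.sample_design,
    )


def simulate_branch_counts(
    S: int = 8,
    cells_per_sample: tuple = (800, 1200),
    proportions=(0.40, 0.45, 0.15),
    reduced_fraction: float = 0.0,
    reduced_branch: int = 0,
    reduced_samples=(),
    seed: int = 1,
):
    """Multinomial branch cell counts for topology-test calibration.

    All samples share the branch proportions; in ``reduced_samples`` the
    ``reduced_branch`` loses ``reduced_fraction`` of its cells (binomial
    thinning), mimicking the branch-cell-reduction design.  Returns
    (counts DataFrame samples x branches, totals Series).
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    samples = [f"s{j}" for j in range(S)]
    counts = np.empty((S, p.size), dtype=int)
    for j in range(S):
        n = int(rng.integers(cells_per_sample[0], cells_per_sample[1] + 1))
        counts[j] = rng.multinomial(n, p)
        if reduced_fraction > 0 and samples[j] in set(reduced_samples):
            counts[j, reduced_branch] = rng.binomial(
                counts[j, reduced_branch], 1.0 - reduced_fraction)
    df = pd.DataFrame(counts, index=samples,
                      columns=[f"branch{b}" for b in range(p.size)])
    return df, df.sum(axis=1)


def simulate_branch_embedding(
    S: int = 8,
    cells_per_sample: int = 300,
    proportions=(0.4, 0.4, 0.2),
    arm_length: float = 5.0,
    noise_sd: float = 0.25,
    seed: int = 1,
):
    """Cells on a 3-armed star in 2-D: a known 3-branch topology.

    Arm 0 points left of the origin hub; arms 1 and 2 fan right.  Returns an
    (embedding, cell_ids, sample_of_cell, true_arm, true_position) tuple for
    trajectory and detection-rate tests.
    """
    rng = np.random.default_rng(seed)
    dirs = np.array([[-1.0, 0.0], [1.0, 0.6], [1.0, -0.6]])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    rows, ids, samp, arms, pos = [], [], [], [], []
    for j in range(S):
        arm = rng.choice(len(proportions), size=cells_per_sample,
                         p=np.asarray(proportions) / np.sum(proportions))
        r = rng.uniform(0, arm_length, cells_per_sample)
        xy = dirs[arm] * r[:, None] + rng.normal(0, noise_sd,
                                                 (cells_per_sample, 2))
        rows.append(xy)
        ids.extend(f"s{j}_c{i}" for i in range(cells_per_sample))
        samp.extend([f"s{j}"] * cells_per_sample)
        arms.append(arm)
        pos.append(r)
    return (np.vstack(rows), np.array(ids, dtype=object),
            np.array(samp, dtype=object), np.concatenate(arms),
            np.concatenate(pos))
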