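# Methods

## Trajectory construction

Cells are clustered by k-means on the harmonized embedding (all provided
columns; selecting top principal components is the caller's job). When the
cluster number is not given it is chosen by an elbow rule: the smallest
k ∈ [2, 25] for which adding one more cluster explains less than 10% of the
total variance (within-cluster sum of squares relative to the k = 1
baseline). Both thresholds are exposed in `trajdiff.trajectory`. K-means uses
10 restarts at a fixed seed, and cells are presented in a canonical
lexicographic coordinate order so results are invariant to row permutations
of the input.

A Euclidean minimum spanning tree over the cluster centers is the trajectory
backbone (Kruskal with deterministic lower-index tie-breaks). After the user
fixes an origin cluster — directly or as the cluster with the highest mean
expression of marker genes — every root-to-leaf cluster sequence is a branch;
branches through the same early clusters deliberately share those cells.
Pseudotime is arc length from the origin end to the cell's orthogonal
projection on the nearest backbone segment flanking its own cluster. Terminal
segments project without clipping so cells beyond the first or last center
keep their ordering; each branch is then shifted to start at zero and
rescaled to [0, 1] before any model fitting, so that the equidistant spline
knots are data-range independent.

**Branch uncertainty.** Each of (by default) 1000 bootstrap samples redraws
cells with replacement (duplicates collapse to unique identities, since the
Jaccard index over multisets is not well defined), rebuilds the trajectory
with the original cluster count — re-running the elbow would mix
model-selection noise into topology uncertainty — and roots it at the cluster
with the smallest mean original pseudotime. A branch is *detected* in a
bootstrap when some bootstrap branch overlaps it with a Jaccard index at or
above a cutoff calibrated once on the original data: the 0.99 quantile of
Jaccard indices between the branch and 1000 size-matched random cell sets.
The detection rate is the fraction of bootstraps in which the branch is
detected.

**Differential topology.** Branch cell proportions (branch cells / sample
cells, shared early cells double-counted per branch) are tested per branch by
binomial logistic regression of (count, total−count) on the sample design
(Wald tests, Benjamini–Hochberg across branches), or jointly by a
baseline-category multinomial logit whose reference is the most abundant
branch. Fits are unpenalized ML (statsmodels); complete separation is flagged
as non-estimable (p = NA) rather than penalized.

## The functional mixed-effects model

For one gene on one branch,

y_sc = φ(t_sc)ᵀ(B x_s + u_s) + ε_sc,  ε_sc ~ N(0, σ_s²),
u_s ~ N(0, σ_s² Ω),  σ_s² ~ InvGamma(α, η).

*Basis.* K counts equidistant knots; the basis always has K+1 functions that
are nonnegative and sum to one. K = 0 is the constant basis; 1 ≤ K ≤ 3 a
degree-K Bernstein basis; K ≥ 4 cubic with K−3 equidistant interior knots.
K is selected per gene by BIC over 0…20: `K·S·ln(Σ_s C_s) − 2 Σ_s l_{K,s}`,
with `l_{K,s}` the Gaussian log-likelihood of a per-sample OLS spline
regression; candidates with any `C_s ≤ K+1` are skipped. K is selected once
(it does not depend on the covariates) and shared across all nested fits of
a gene so LLRs compare like with like.

*Degrees of freedom.* A full Ω needs S > V + K + 2 samples; otherwise the
model automatically falls back to Ω = ω²I ("auto" constraint mode).

*Fitting.* Conjugacy gives the exact posterior: σ_s² | y is inverse-gamma
with shape α + C_s/2 and rate η + q_s/2 (q_s the Mahalanobis residual under
the marginal scale Φ_s Ω Φ_sᵀ + I, computed via the Woodbury identity in
(K+1)-space), and u_s | σ_s², y is Gaussian. The M-step is separable: a
weighted least-squares update for the fixed effects, a moment update for Ω
(eigenvalue-floored at 1e-10; trace-averaged in scalar mode), and a
safeguarded 1-D Newton on the profile objective for (α, η) with α floored at
1.01 so the noise-variance prior has a finite mean. All per-iteration work
uses per-sample Gram statistics, so cost is independent of cell count after
a single pass.

Plain EM crawls on fits where the inverse-gamma layer degenerates (α → ∞
when per-sample variances are nearly equal): thousands of iterations to move
the log-likelihood by 0.1. Each EM cycle therefore attempts a SQUAREM-style
quadratic extrapolation of the parameter trajectory (positive scalars on log
scale), accepted only when it does not decrease the marginal likelihood — the
recorded trace stays monotone while late-stage convergence speeds up by more
than an order of magnitude. Marginal log-likelihoods are computed in closed
form (the multivariate-t marginal), and the test suite cross-checks them
against an independent multivariate-t density evaluation and against direct
numerical integration over (u, σ²).

*Initialization.* Per-sample OLS spline coefficients seed the random-effect
covariance and, by pooled OLS, the fixed effects; (α, η) by method of moments
on per-sample residual variances. Singular normal equations get a 1e-8 ridge.

## Differential tests

*XDE.* For covariate v the nested models are M0 (β_.v = 0), M1
(β_.v = c·1 — because the basis sums to one this is a design with a single
extra constant column, i.e. a pure mean shift) and M2 (free). Overall test
M2:M0, mean test M1:M0, trend test M2:M1. Batch or other nuisance columns
stay free in all three models. Each model is fitted cold; if a richer model
ends below a restricted one (a cold-start artifact), it is refitted from the
embedded restricted solution, which restores the nesting order by EM
monotonicity. Raw LLRs are stored; the chi-squared reference uses 2·LLR with
df = K+1 / 1 / K.

*TDE.* H0 constrains each column of B to a constant (flat curves; df of the
comparison is K(V+1)); H1 is free.

*Permutation null (`mode="pm"`).* Per permutation, cells are bootstrapped
within each sample (preserving C_s) to absorb pseudotime variability, then
the tested covariate column is shuffled across samples (XDE; nuisance columns
stay attached to their samples) or pseudotime is shuffled within samples
(TDE). Models are refitted (warm-started from the observed null-model fit)
and the LLRs collected; a Gaussian KDE with Silverman's rule-of-thumb
bandwidth smooths the (default 100) permuted LLRs, and the p-value is the
analytic tail mass of that kernel mixture above the observed LLR, floored at
1e-300 (p-values below the double-precision floor are serialized as
"<2.22e-308"). In pm mode, genes whose chi-squared p-values all exceed 0.1
keep those p-values and skip permutations — they are far from any
significance boundary, and the chi-squared screen only has to be lenient, not
exact. Benjamini–Hochberg runs per test across genes; at the chosen FDR
cutoff genes are classified as meanSig / trendSig / bothSig / otherSig /
nonXDE.

*Permutation granularity.* With S = 8 and a balanced binary covariate there
are only 70 distinct relabelings, two of which (identity and complement)
preserve the signal entirely. The permutation null therefore contains
signal-like draws, flooring attainable p-values around 1/70; single very
strong genes cannot reach extreme p-values, and power saturates before 1.
This is a property of the published permutation scheme at small S, not of the
implementation; with realistic numbers of true genes the BH threshold is
reachable and FDR control is (conservatively) maintained.

*Cell density.* Pseudotime on a branch is divided into (default) 100 equal
intervals from 0 to its global maximum; the per-sample ratios r_st/L_s,
placed at interval midpoints, go through exactly the TDE (TCD test) or XDE
(XCD test, overall only) machinery. Ratios rather than counts are modeled;
a count model (Poisson/NB) is deliberately out of scope. Samples with fewer
than 20 branch cells are flagged as unstable.

## Synthetic benchmarks

`simulate_femm_data` samples the generative model directly. Defaults are the
benchmark study conditions: S = 8 samples split 4/4 into two groups, 250–350
cells per sample, G = 1000 genes, K_true = 3, Ω = 0.09·I (sample-level curve
variation of SD 0.3), α = 3, η = 2 (mean cell-noise variance 1, heavy right
tail), pseudotime uniform on [0, 1]. Per-gene intercept coefficients are
Gamma-distributed with mean 1.5 and SD 1.0: log-scale expression is
nonnegative, and the positive skew couples a gene's expression level to its
dynamic range — the mean–variance relationship that highly-variable-gene
selection presupposes. Covariate effect columns default to zero (a global
null).

The null construction divides pseudotime into 100 intervals and, per gene and
interval, lifts the lower-median group's cells by the between-group median
difference; the construction is idempotent and exactly equalizes interval
medians. Spike-ins then plant truth: 20% of genes become gold-standard,
split evenly into trend / mean / both types. Source genes are
highly-variable non-gold genes (positive residual of a spline SD~mean fit on
group-0 cells), clustered (k-means, 5 clusters, recorded), ranked by the
F-statistic of spline-vs-constant fits against pseudotime, and the tail
split into 4 equal strength strata. A gold gene receives its source gene's
per-sample, pseudotime-ordered profile: as-is to group 0 and within-sample
permuted to group 1 (trend type — same marginal, different shape),
within-sample permuted to group 0 only (mean type), or as-is to group 0 only
(both). A scalar multiplier (0.5–4) scales the signal for power sweeps;
multiplier 0 is the identity. Profiles are pseudotime-interpolated when
source and target cell counts differ.

Topology calibration uses multinomial branch-count simulation (default
proportions 0.40/0.45/0.15, 800–1200 cells per sample) with optional binomial
thinning of one branch in designated samples; `simulate_branch_embedding`
provides a geometric 3-armed star for trajectory-level tests, and
`simulate_branch_reduction` subsamples a real branch's cells.

**What the generator does not emulate.** Counts, dropout/zero-inflation,
gene–gene correlation beyond the shared pseudotime, doublets, batch effects
in the embedding, or uncertainty in the pseudotime itself (tests receive the
true pseudotime). Passing benchmarks therefore demonstrate correctness of
the statistical machinery under the model's own assumptions plus the
spike-in's model-free signals — not robustness to everything real data can
do.

## Evaluation metrics

Realized-vs-reported FDR curves are trapezoid-integrated on [0, 1] and
compared against the diagonal (zero-discovery cutoffs count realized FDR 0,
a convention favorable to the tested method and stated in output metadata).
The sensitivity~realized-FDR AUC integrates the best sensitivity attainable
at each realized-FDR level as a right-continuous step function (trapezoid
interpolation across the sparse step grid would overestimate — an inverted
ranking would score 0.65 instead of its true 0.30), right-extended at the
final sensitivity. The top-N overlap test averages |top-N ∩ gold| over an N
grid (default 10, 20, …, 500 clipped to the universe) against a
rank-permutation null with the add-one p-value correction.

## Problem sizes and runtime

Pipeline fits default to tol 1e-3 and 100 EM map evaluations — LLRs agree
with fully converged fits to ~0.03, far below permutation noise; the public
single-fit API (`fit_em`, `fit_nested_models`) defaults tighter (1e-5/1e-6).
The packaged benchmarks run the spike-in FDR experiment at full size
(1000 genes, 8 × ~300 cells, 50 permutations, ~4 minutes on one CPU), the
topology type-I experiment at 2000 replicates (~35 s), and the power-ordering
sweep at a reduced 250-gene scale with 30 permutations (~3 minutes) — sizes
chosen so the entire suite runs comfortably on a laptop.

## Known limitations

- The Gaussian curve model operates on log-normalized values; zero-heavy raw
  counts should be normalized (and, if desired, imputed) upstream.
- Permutation p-values are granular for small S (see above); the chi-squared
  mode is faster but only asymptotically calibrated and can be mildly
  anticonservative or conservative depending on the random-effect structure.
- Branch pseudotime is treated as fixed in the expression and density tests;
  trajectory uncertainty is quantified separately (detection rates), not
  propagated.
- The multinomial topology test expands counts to cell-level rows; for
  atlas-scale totals the binomial per-branch test is the practical default.
- Disk-backed (HDF5) mode streams genes but the differential tests currently
  materialize the branch submatrix in memory.
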