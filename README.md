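# trajdiff

Differential pseudotime analysis for single-cell RNA-seq studies with
**multiple samples**.

Most trajectory tools treat all cells as if they came from one biological
replicate, so a "differential" result can reflect nothing more than
donor-to-donor variability. `trajdiff` keeps the sample structure explicit at
every step: it builds a cluster-based minimum-spanning-tree trajectory on a
harmonized embedding, quantifies how reproducible each branch is under
bootstrap resampling, tests whether branch cell proportions depend on
sample-level covariates, and fits a functional mixed-effects model that
separates covariate effects on a gene's pseudotemporal curve from random
variation among samples before testing for differential expression or cell
density.

## The model

For one gene, cell `c` of sample `s` at (branch-rescaled) pseudotime
`t_sc ∈ [0,1]`:

```
y_sc = φ(t_sc)ᵀ b_s + ε_sc          ε_sc ~ N(0, σ_s²)
b_s   = B x_s + u_s                  u_s  ~ N(0, σ_s² Ω)
σ_s² ~ InvGamma(α, η)
```

where `φ(t)` are K+1 B-spline bases (K chosen per gene by BIC), `x_s` is the
sample's covariate vector (intercept, group, batch dummies, …), `B` the fixed
effects and `u_s` a sample-level random effect. Integrating `(u_s, σ_s²)` out
gives a closed-form multivariate-t marginal likelihood, maximized by an
accelerated EM algorithm.

Tests are nested-model log-likelihood ratios (LLR):

| test | null | alternative | question |
|------|------|-------------|----------|
| XDE overall | `β_.v = 0` | free | does covariate *v* change the curve? |
| XDE mean    | `β_.v = 0` | `β_.v = c·1` | …by a constant shift? |
| XDE trend   | `β_.v = c·1` | free | …by a shape change? |
| TDE         | all columns of `B` constant | free | does the curve change along pseudotime at all? |

The null distribution of each LLR comes from permutations (bootstrap cells
within samples, then shuffle the covariate across samples, or pseudotime
within samples), smoothed with a kernel density estimate; a faster
chi-squared reference on `2·LLR` is available as `mode="chisq"`. Cell-density
changes (TCD/XCD) reuse the same machinery on per-interval cell-count ratios
`r_st / L_s`.

## Worked example

Build a fully synthetic multi-sample benchmark (8 samples split into two
groups, median-matched so no covariate signal remains, then spike
ground-truth trend/mean/both signals into 20% of genes) and test it:

```python
import trajdiff as td

cfg = td.SimConfig(S=8, G=120, cells_per_sample=(150, 200))
bench, labels, pseudotime, group = td.build_spikein_benchmark(
    seed=4, config=cfg, strength_level=3)
res = td.xde_test(bench, pseudotime, "group", mode="pm", n_perm=50, seed=4)
merged = res.merge(labels, on="gene")
print(merged.loc[merged.fdr_overall <= 0.05,
                 ["gene", "K", "llr_overall", "p_overall", "fdr_overall",
                  "category", "truth"]].head(8).to_string(index=False))
```

```
gene  K  llr_overall     p_overall   fdr_overall category truth
  g0  2    17.824901  4.941767e-03  4.235801e-02  meanSig  mean
  g9  1    13.202016  1.074857e-83  6.449140e-82  meanSig  mean
 g12  1    16.303084  5.980355e-73  2.392142e-71  bothSig  both
 g40  2    17.120992  3.461998e-03  3.195691e-02  meanSig  mean
 g48  2    18.414188  3.226670e-05  3.872004e-04  meanSig  mean
 g56  1    13.102141  2.581460e-09  4.425361e-08 trendSig trend
 g58  1    16.958550 8.401017e-148 1.008122e-145  bothSig  both
 g59  1    13.602140  2.259118e-05  3.012157e-04 trendSig  both
```

Every gene called at 5% FDR in this run is a true spike-in (14 discoveries,
realized FDR 0.000, sensitivity 0.583), and the `category` column recovers
the planted signal type: `meanSig` genes carry a constant between-group
shift, `trendSig` genes a shape change, `bothSig` genes both. `K` is the
per-gene BIC knot choice and `llr_overall` the raw log-likelihood ratio of
the unconstrained versus no-covariate model.

A trajectory workflow on real data starts from a harmonized embedding:

```python
tree = td.build_trajectory(embedding, cell_ids=cells, origin=5, seed=1)
report = td.detection_rates(embedding, tree, n_bootstraps=1000, seed=1)
props = td.branch_proportions(tree, sample_of_cell)
topo = td.test_topology_binomial(props, sample_design)
```

The same pipeline is scriptable from the shell (`trajdiff trajectory`,
`detect-rate`, `topology-test`, `xde`, `tde`, `tcd`, `xcd`, `simulate`,
`evaluate`); run `trajdiff --help`.

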