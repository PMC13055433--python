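# cosmoda

Differential abundance (DA) testing for compositional high-throughput
sequencing data — microbial relative abundances from amplicon sequencing, or
cell-type compositions derived from single-cell RNA-seq — that accounts for
**pairwise feature interactions** while testing for covariate effects.

## Why

Abundance tables are compositional: each sample is a vector of proportions on
the simplex. When two features are ecologically or biologically coupled
(say, taxa *a* and *b* in symbiosis), a treatment that depletes *a* also
drags down *b*. Classical per-feature DA tests cannot distinguish this
secondary, correlation-induced shift from a primary treatment effect and
report both features as differentially abundant. cosmoda fits a generative
model with an explicit interaction matrix so that the covariate effect on
each feature is estimated *given* the interaction structure, sharply
reducing such false discoveries.

## The model

Each sample `x` on the (p−1)-simplex with covariate value `y` follows the
covariate-extended a-b power interaction model

    log p(x) ∝ −½ t_a(x)ᵀ K t_a(x) + (η₀ + y·η₁)ᵀ t_b(x),

where `t_a(x) = (xᵃ − 1)/a` elementwise (`log x` at `a = 0`), `K` is a
symmetric p×p interaction matrix (its off-diagonal support is the feature
"network"), and `η₀`, `η₁` are location vectors. At `a = b = 0` the family
contains the Dirichlet (`K = 0`) and Aitchison's log-ratio class; powers
`a, b > 0` admit zero abundances without pseudocounts.

The normalizing constant is intractable, so parameters are estimated by
**ℓ1-penalized generalized score matching**: the empirical weighted
Hyvärinen divergence collapses to a quadratic form `½θᵀΓθ − gᵀθ` in
`θ = (vec K, η₀, η₁)`, solved by proximal coordinate descent over a
regularization path, with λ₁ chosen by 5-fold cross-validation (1SE rule)
or eBIC. DA testing studentizes each `η̂₁ⱼ` with a sandwich (robust)
standard error; `Tⱼ = η̂₁ⱼ/sêⱼ` is referred to a t(n−3) distribution, with
Benjamini–Hochberg adjustment across features. A Procrustes-alignment
criterion selects a data-driven power `φ = a = b` that best matches the
additive log-ratio geometry without replacing zeros.

## Worked example

Simulate a two-group scenario with a known interaction network (feature 0 is
truly affected; feature 1 is merely coupled to it), then test:

```python
import numpy as np
import cosmoda as cd

K, eta0 = cd.da_base_params()                # synthetic 11-feature network
spec = cd.ScenarioSpec(p=11, n=1000, tau=-0.5, target_features=(0,),
                       base_K=K, base_eta0=eta0, seed=1000)
ds, truth = cd.make_da_scenario(spec)

sel = cd.cross_validate(ds, a=0.0, b=0.0,
                        lambdas=np.geomspace(2, 1e-3, 20), k=5, seed=0)
system = cd.build_score_system(ds, 0.0, 0.0)
fit = cd.prox_coordinate_descent(system, sel.lambda_selected)
S = cd.sandwich_covariance(system, fit.theta_hat)
table = cd.da_test(fit.theta_hat, S, ds.n, system.feature_names)
print(table[["feature", "eta1_hat", "se", "t", "p_adj"]].head(3).round(3))

mask = ~table["is_reference"].to_numpy()
print(cd.da_metrics(table.loc[mask, "p_adj"].to_numpy(), truth[:-1]))
print(cd.da_metrics(cd.log_ttest_baseline(ds.X[:, :10], ds.y), truth[:-1]))
```

Output:

```
     feature  eta1_hat     se      t  p_adj
0  feature_0     0.672  0.116  5.780  0.000
1  feature_1     0.219  0.095  2.299  0.066
2  feature_2     0.069  0.076  0.902  0.498
DAMetrics(fdr=0.0, tpr=1.0, mcc=1.0, n_called=1)
DAMetrics(fdr=0.75, tpr=1.0, mcc=0.408, n_called=4)
```

The covariate effect on feature 0 is recovered accurately
(`eta1_hat = 0.672` against a generating value of 0.685) and it is the only
feature called at `p_adj < 0.05`; its strongly coupled partner (feature 1)
stays above the threshold. The interaction-blind per-feature t-test on log
proportions calls four features on the same data — the three extra calls
are secondary, correlation-induced shifts (FDR 0.75 vs 0). The acceptance
tests rerun this comparison across the full effect-size grid with five
replicates; interaction-aware FDR stays well below the baseline's
throughout, though not always below the nominal 0.05 — strong couplings
still leak at large effect sizes.

The same pipeline is available from the shell:

```sh
cosmoda test --table counts.tsv --metadata meta.tsv --covariate group \
             --reference NK --power auto --seed 1 --out results/
```

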