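# foldedcca

Sparse canonical correlation analysis (SCCA) with folded-concave
(non-convex) penalties, for bi-multivariate association studies such as
imaging genetics: given SNP dosages **X** (n × p) and imaging quantitative
traits **Y** (n × q) measured on the same subjects, find sparse loading
vectors **u**, **v** so that the canonical scores **Xu** and **Yv** are
maximally correlated and the nonzero loadings point at the associated
features.

The ℓ1 norm — the standard sparsity penalty in SCCA — over-penalizes large
coefficients and biases the estimates.  `foldedcca` implements a unified
SCCA model in which the ℓ1 penalty is replaced by any of seven non-convex,
folded-concave penalties that are singular at the origin (hence sparsity-
inducing) but flat for large coefficients (hence nearly unbiased):

| family    | P(t), t = absolute loading                 | concavity parameter γ |
|-----------|--------------------------------------------|------------------------|
| `lgamma`  | λ tᵞ (bridge, 0 < γ < 1)                   | 0.1 – 0.3 |
| `geman`   | λt / (t + γ)                               | 0.001 – 0.1 |
| `scad`    | quadratic spline, flat beyond γλ           | 3.7 |
| `laplace` | λ(1 − e^(−t/γ))                            | 0.001 – 0.1 |
| `mcp`     | λt − t²/(2γ), flat beyond γλ               | 0.001 – 0.1 |
| `etp`     | λ(1 − e^(−γt)) / (1 − e^(−γ))              | 10 – 1000 |
| `log`     | λ log(γt + 1) / log(γ + 1)                 | 10 – 1000 |
| `l1`      | λt (convex baseline)                       | — |

## Model and algorithm

All families are fit by one optimizer, which minimizes the Lagrangian

    L(u, v) = −uᵀXᵀYv + Ω(u) + Ω(v) + (α₁/2)‖Xu‖² + (α₂/2)‖Yv‖²,

subject to ‖Xu‖ = ‖Yv‖ = 1, where Ω(w) = Σᵢ P(|wᵢ|).  Each penalty is
replaced by its local quadratic approximation (LQA) — a quadratic
majorizer built from the penalty's supergradient — which turns the two
blocks into ridge-type problems with closed-form solutions

    u ← (D₁ + α₁XᵀX)⁻¹ XᵀYv,    v ← (D₂ + α₂YᵀY)⁻¹ YᵀXu,

solved alternately (alternate convex search) with unit-norm rescaling of
the scores after each solve, until the maximum coordinate change of both
vectors falls below ε = 10⁻⁵.  Non-convex fits are warm-started from the
converged ℓ1 solution (the standard lasso-initialized strategy for
folded-concave estimators).  Only γ needs tuning; λ = α = 1 works across
the board and γ is selected by 5-fold cross-validated grid search.

## Worked example

The built-in generator draws two views from a shared latent factor
z ~ N(0, 1): rows xᵢ ~ N(zᵢ·s·u, Σx) with kernel noise covariance
(Σx)ⱼₖ = exp(−|uⱼ − uₖ|), block-sparse ground-truth loadings, and more
features than subjects (n = 100 against p = 250, q = 600):

```python
from foldedcca import NonconvexSCCA, generate_dataset, preset_designs, auc_support

design = preset_designs(seed=7)[0]          # strong-signal preset
data = generate_dataset(design)

est = NonconvexSCCA(penalty="log", gamma=100.0).fit(data.X, data.Y)
print("training canonical correlation: %.3f" % est.corr_)
u, v = est.sparse_loadings()
print("nonzero loadings: u %d/250, v %d/600" % ((u != 0).sum(), (v != 0).sum()))
print("support-recovery AUC: u %.2f, v %.2f" % (
    auc_support(est.u_, data.true_u), auc_support(est.v_, data.true_v)))
```

prints

```
training canonical correlation: 0.868
nonzero loadings: u 30/250, v 30/600
support-recovery AUC: u 1.00, v 1.00
```

— the estimator recovers exactly the 30 true signal features in each view
(AUC 1.0 means every true-signal feature outranks every null feature by
absolute loading), and `est.score(X_new, Y_new)` on a fresh draw of the
same design gives a held-out correlation of 0.915.

The same workflow is available from the shell:

```bash
foldedcca simulate --preset 1 --seed 7 --out sim/
foldedcca gridsearch --x sim/X.csv --y sim/Y.csv --penalty log --out gs/
foldedcca cv --x sim/X.csv --y sim/Y.csv --penalty scad --out cv/
```

`cross_validate` / `grid_search` (library) and the `cv` / `gridsearch`
subcommands run the evaluation protocol: a shared seeded 5-fold partition,
per-fold training and held-out canonical correlations, and — when ground
truth is available — per-fold support-recovery AUCs.  An optional
covariate matrix (age, sex, ...) is regressed out of both views first
(`residualize_covariates`).

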