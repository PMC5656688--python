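# Methods

## Model

`foldedcca` estimates one pair of sparse canonical loadings (u, v) for two
views X ∈ ℝ^{n×p}, Y ∈ ℝ^{n×q} sharing rows, by minimizing the penalized
Lagrangian

    L(u, v) = −uᵀXᵀYv + Ω₁(u) + Ω₂(v) + (α₁/2)‖Xu‖² + (α₂/2)‖Yv‖²

with the score-scale constraints ‖Xu‖ = ‖Yv‖ = 1 enforced by rescaling.
Ω(w) = Σᵢ P_{λ,γ}(|wᵢ|) is a separable penalty from one of eight
families: the convex ℓ1 baseline and seven concave ("folded-concave")
penalties (bridge ℓγ, Geman, SCAD, Laplace, MCP, exponential-type,
logarithm).  All eight vanish at the origin, are singular there (which
produces sparsity), and — except ℓ1 — flatten for large |w|, so strong
associations are not shrunk and the estimation bias of ℓ1 is avoided.
Columns of both views are standardized to zero mean and unit variance
before fitting (so the cosine form of the canonical correlation coincides
with the Pearson correlation of the scores); standardization parameters
are stored and applied to any new data passed to `transform`/`score`.

## Optimization

Each penalty term is majorized at the current iterate w_t by its local
quadratic approximation (LQA),

    P(|w|) ≈ P(|w_t|) + P′(|w_t|)·(w² − w_t²) / (2|w_t|),

where P′ is the supergradient (non-increasing on [0, ∞)).  This makes the
objective biconvex, and alternate convex search (ACS) solves the two
ridge-type blocks in closed form,

    u ← (D₁ + α₁XᵀX)⁻¹XᵀYv,    v ← (D₂ + α₂YᵀY)⁻¹YᵀXu,

via symmetric positive-definite linear solves (Cholesky; never an explicit
inverse; Gram matrices XᵀX, YᵀY, XᵀY are formed once per fit).  The
diagonal weights use the perturbed form D(i,i) = P′(max(|wᵢ|, ζ))/(|wᵢ| + ζ)
with ζ = 10⁻⁶: the perturbation keeps weights defined at wᵢ = 0, and
evaluating the supergradient at max(|wᵢ|, ζ) keeps the bridge (ℓγ) family
— whose slope diverges at 0 — finite as well.  Weights are floored at
δ = 10⁻¹²: when SCAD/MCP supergradients are exactly zero beyond the
clipping point and XᵀX is rank-deficient (n < p), the floor keeps the
ridge systems positive-definite without materially moving the estimates.
After each block solve the vector is rescaled so its score has unit norm.
Iteration stops when max|Δuᵢ| ≤ ε and max|Δvⱼ| ≤ ε (ε = 10⁻⁵ by default),
or at `max_iter` = 100, in which case the result is returned flagged
`converged = False` rather than raising.

**Initialization.**  The default is a warm start: the convex ℓ1 problem is
converged first (from the all-ones start, each vector rescaled to unit
score norm) and the non-convex fit continues from its solution — the
standard lasso-initialized strategy for folded-concave estimators.  This
matters for the most aggressive penalties: under the generator below, all
zero-loading features of a view share a single noise vector, and from the
raw all-ones start (which is dominated by that large duplicated block) the
bridge penalty's reweighting (weights ∝ |w|^{γ−2}) can lock onto the
spurious null-block direction and zero out the true signals permanently.
Warm-starting from the ℓ1 support avoids this local minimum;
`init="ones"` and `init="random"` (seeded) remain available.
`n_iter_`/`objective_trace_` describe the refinement phase after the warm
start.

**Monotonicity.**  Each convex subproblem solve cannot increase L relative
to its own expansion point — the majorize–minimize guarantee, recorded per
iteration in `step_descent` when diagnostics are enabled and verified in
the test suite to 10⁻⁸.  The unit-norm rescale, however, is a projection
onto the constraint set and can transiently raise L, so the per-iteration
`objective_trace` (evaluated at the rescaled iterates) is typically but
not provably non-increasing; transient rises of a few percent occur on
weakly-structured problems.  This is a property of the rescaled iteration
itself, not of the implementation.

**Sign convention.**  (u, v) and (−u, −v) give identical objectives; if
the fitted correlation is negative, v is negated so that corr(Xu, Yv) ≥ 0.
The remaining joint sign is pinned by the deterministic initialization.

**Reported sparsity.**  The ridge-type updates never produce exact zeros;
loadings with |w| < 10⁻⁵ are displayed/written as zero (`sparse_loadings`,
the `weight_display` column), while raw values are retained internally and
in the `weight` column, which round-trips at full precision.

## Parameters

| parameter | meaning | default | notes |
|-----------|---------|---------|-------|
| λ (`lam`) | sparsity weight | 1 | with an aggressive γ the penalty approximates ℓ0, so λ (and α) barely matter; they stay fixed at 1 |
| γ (`gamma`) | concavity | family default (grid midpoint; 3.7 for SCAD) | the one parameter worth tuning; grids: ℓγ {0.1, 0.2, 0.3}, SCAD {3.7}, Geman/Laplace/MCP {0.1, 0.01, 0.001}, ETP/Log {10, 100, 1000} |
| α₁, α₂ (`alpha1/2`) | score-scale weights | 1 | Lagrange weights of the unit-score constraints |
| ζ (`zeta`) | LQA perturbation | 10⁻⁶ | "tiny positive"; exposed in `SolverConfig` |
| ε (`tol`) | convergence bound | 10⁻⁵ | max coordinate change of u and v |
| `max_iter` | iteration cap | 100 | non-convergence is flagged, not fatal |

Grid search (`grid_search`) selects γ by the mean held-out canonical
correlation over a 5-fold partition shared across all candidate values
(and across penalty families when the same partition seed is used), since
held-out correlation is the quantity of scientific interest; per-fold
standardization is learned on the training folds only.

## Synthetic data

The generator emulates a single-factor latent model.  Each subject carries
z ~ N(0, 1); the views are drawn row-wise as xᵢ ~ N(zᵢ·s·u, Σx) and
yᵢ ~ N(zᵢ·s·v, Σy), where u, v are block-sparse ground-truth loadings
(contiguous nonzero blocks, zeros elsewhere), s is a signal-strength
multiplier, and the noise covariance follows the exponential kernel
(Σx)ⱼₖ = exp(−|uⱼ − uₖ|) (unit diagonal by construction).  Four preset
designs are provided, n = 100 in all of them (the feature counts exceed
the sample size, the regime in which plain CCA is ill-posed): designs 1–3
at (p, q) = (250, 600) with s = 3.0 / 0.8 / 1.5 — three distinct
population correlation levels, design 2 the hardest — and design 4 at
(500, 900) with s = 3.0.  One covariance Cholesky factor per view is
reused across rows; because equal loading values duplicate kernel rows
exactly (the exp(−|uⱼ−uₖ|) kernel is strictly positive-definite only on
distinct values), a diagonal jitter of 10⁻¹⁰ (escalated if needed) is
added when the factorization requires it.

What this generator does and does not capture: it produces the stated
large-(p+q)-small-n geometry, strong within-block feature correlation and
a single shared factor, so passing tests demonstrate correct optimization
and support recovery under those conditions.  It does not emulate discrete
genotype dosages, linkage-disequilibrium block structure, multi-factor
association, or heavy-tailed imaging noise — performance on real
imaging-genetics data is not implied by these simulations.  A notable
consequence of the kernel is that all zero-loading features within a view
are copies of one noise vector, which makes the null background strongly
self-correlated and is precisely what stresses the aggressive penalties
(see Initialization above).

## Evaluation protocol

- **Canonical correlation**: Pearson correlation of the mean-centered
  scores Xu, Yv (equivalently the cosine form on centered scores).
- **Support-recovery AUC**: area under the ROC curve when features are
  ranked by absolute loading against the binary true support; mid-rank tie
  handling (Mann–Whitney).  Computed per CV fold and reported mean ± sd.
- **Cross-validation**: seeded shuffled k-fold partition (k = 5), disjoint
  near-equal folds, standardization learned on the training folds,
  identical partition reusable across methods for fair comparison.
- **Covariate correction**: each column of a view is replaced by its
  least-squares residual on a full-rank covariate matrix (with intercept)
  before analysis.

## Numerical and design notes

- Degenerate directions (a zero score vector during rescaling, a
  zero-variance score in the correlation) raise immediately with a
  descriptive error.
- Constant columns are left centered but unscaled during standardization;
  they carry no association signal.
- The objective omits the additive constants of the exact Lagrangian
  (−α/2 per view), which do not affect the optimization.
- Stationarity at convergence is checked in fixed-point form: re-running
  one block update at the converged weights reproduces the iterate (to a
  small multiple of ε), and each update solves its linear system to
  10⁻⁸-level residuals.

## Known limitations

- Single canonical pair only; no deflation for further components.
- The post-rescale objective trace is not strictly monotone (see
  Monotonicity); convergence is assessed on iterate changes, as is
  standard for this family of algorithms.
- With exactly duplicated features and a saturating penalty whose
  clipping point falls below the working coefficient scale, the solution
  along within-duplicate contrasts is unidentifiable; the weight floor
  keeps the systems solvable but coefficients on such contrasts are
  arbitrary.  Real data with distinct features is unaffected.
- Structure-aware penalties (fused/group/graph) are out of scope.
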