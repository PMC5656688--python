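"""Biconvex LQA/ACS optimizer for penalized two-view canonical correlation.

The model minimized is the Lagrangian

    L(u, v) = -uᵀXᵀYv + Ω(u) + Ω(v) + (α₁/2)‖Xu‖² + (α₂/2)‖Yv‖²,

where Ω is a (possibly non-convex) separable penalty from
:mod:`foldedcca.penalties`.  Each penalty is replaced by its local
quadratic majorizer (LQA), making the surrogate biconvex; alternate
convex search (ACS) then solves the two ridge-type subproblems

    u ← (D₁ + α₁XᵀX)⁻¹ XᵀYv,     v ← (D₂ + α₂YᵀY)⁻¹ YᵀXu

in closed form (via a symmetric positive-definite linear solve, never an
explicit inverse), with D₁, D₂ the perturbed LQA diagonal weights.  After
each solve the vector is rescaled so that ‖Xu‖ = ‖Yv‖ = 1, enforcing the
unit-variance constraints of the canonical scores.  Iteration stops when
both max-coordinate changes fall below ``epsilon``.

Note on monotonicity: each convex subproblem solve cannot increase the
objective relative to its own expansion point (the majorize–minimize
guarantee), and those per-step inequalities are recorded in
``FitResult.step_descent``.  The rescale step is a projection onto the
constraint set and may transiently raise the Lagrangian, so the
per-iteration ``objective_trace`` (evaluated at the rescaled iterates) is
typically but not provably non-increasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .penalties import PenaltySpec, lqa_diag_weights, penalty_sum

__all__ = [
    "Dataset",
    "SolverConfig",
    "FitResult",
    "objective",
    "update_u",
    "update_v",
    "rescale",
    "converged",
    "fit",
]

logger = logging.getLogger(__name__)

#: Estimated loadings with magnitude below this are displayed/written as zero;
#: raw values are always retained internally.
DISPLAY_ZERO_TOL = 1e-5


@dataclass
class Dataset:
    """Paired data matrices sharing rows (subjects).

    ``X`` is n × p (e.g. SNP dosages), ``Y`` is n × q (e.g. imaging
    quantitative traits).  Simulated datasets carry their ground-truth
    loading vectors, enabling support-recovery evaluation.
    """

    X: np.ndarray
    Y: np.ndarray
    true_u: Optional[np.ndarray] = None
    true_v: Optional[np.ndarray] = None
    row_ids: Optional[Sequence[str]] = None
    x_names: Optional[Sequence[str]] = None
    y_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D matrices")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X and Y must share rows: X has {self.X.shape[0]}, "
                f"Y has {self.Y.shape[0]}"
            )
        for name, M in (("X", self.X), ("Y", self.Y)):
            if not np.all(np.isfinite(M)):
                raise ValueError(f"{name} contains non-finite entries")
        for name, w, dim in (
            ("true_u", self.true_u, self.X.shape[1]),
            ("true_v", self.true_v, self.Y.shape[1]),
        ):
            if w is not None:
                w = np.asarray(w, dtype=float)
                if w.shape != (dim,):
                    raise ValueError(f"{name} must have length {dim}")
                setattr(self, name.replace("true_", "true_"), w)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class SolverConfig:
    """Optimizer settings.

    alpha1, alpha2 : quadratic (scale-constraint) weights α₁, α₂ > 0; default 1.
    zeta : LQA perturbation ζ; tiny positive, default 1e-6.
    epsilon : termination bound on max coordinate change; default 1e-5.
    max_iter : iteration cap; non-convergence is flagged, not raised.
    init : 'warm' (default: converge the ℓ1 problem from the all-ones
        start, then continue with the target penalty — the LLA-style warm
        start that keeps aggressive penalties out of spurious local
        minima), 'ones', or 'random' (requires seed).
    seed : RNG seed for random initialization.
    """

    alpha1: float = 1.0
    alpha2: float = 1.0
    zeta: float = 1e-6
    epsilon: float = 1e-5
    max_iter: int = 100
    init: str = "warm"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("alpha1 and alpha2 must be positive")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.init not in ("warm", "ones", "random"):
            raise ValueError("init must be 'warm', 'ones' or 'random'")
        if self.init == "random" and self.seed is None:
            raise ValueError("random initialization requires a seed")


@dataclass
class FitResult:
    """Converged canonical loadings with optimization metadata.

    ``objective_trace`` holds the Lagrangian value at the rescaled iterates,
    one entry per iteration; ``step_descent`` holds per-iteration tuples
    (L at expansion, L after u-solve, L before v-solve, L after v-solve)
    evaluated at the pre-rescale subproblem minimizers, which the
    majorize–minimize argument guarantees to be non-increasing pairwise.
    """

    u: np.ndarray
    v: np.ndarray
    corr: float
    objective_trace: list[float]
    n_iter: int
    converged: bool
    step_descent: list[tuple[float, float, float, float]] = field(
        default_factory=list
    )


def _check_dims(X, Y, u, v):
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"X and Y row mismatch: {X.shape[0]} vs {Y.shape[0]}"
        )
    if u.shape[0] != X.shape[1]:
        raise ValueError(f"u has length {u.shape[0]} but X has {X.shape[1]} columns")
    if v.shape[0] != Y.shape[1]:
        raise ValueError(f"v has length {v.shape[0]} but Y has {Y.shape[1]} columns")


def objective(
    u: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    spec_u: PenaltySpec,
    spec_v: PenaltySpec,
    config: SolverConfig = SolverConfig(),
) -> float:
    """Lagrangian L(u, v); the additive constants of the exact Lagrangian
    (−α/2 terms from the constraints) are dropped."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    _check_dims(X, Y, u, v)
    Xu = X @ u
    Yv = Y @ v
    return float(
        -Xu @ Yv
        + penalty_sum(u, spec_u)
        + penalty_sum(v, spec_v)
        + 0.5 * config.alpha1 * (Xu @ Xu)
        + 0.5 * config.alpha2 * (Yv @ Yv)
    )


def _ridge_solve(G: np.ndarray, d: np.ndarray, alpha: float, b: np.ndarray) -> np.ndarray:
    """Solve (diag(d) + alpha·G) w = b via a Cholesky factorization."""
    A = alpha * G
    idx = np.diag_indices_from(A)
    A = A.copy()
    A[idx] += d
    try:
        c, low = cho_factor(A, lower=True, check_finite=False)
    except LinAlgError as exc:  # pragma: no cover - floor makes this unreachable
        raise LinAlgError(
            "ridge system not positive-definite "
            f"(min diag weight {d.min():.3e}, alpha {alpha:.3e}): {exc}"
        ) from exc
    return cho_solve((c, low), b, check_finite=False)


def update_u(
    X: np.ndarray,
    Y: np.ndarray,
    v: np.ndarray,
    d1: np.ndarray,
    alpha1: float,
) -> np.ndarray:
    """Closed-form u-update: solve (D₁ + α₁XᵀX) u = XᵀYv."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    v = np.asarray(v, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    if v.shape[0] != Y.shape[1]:
        raise ValueError(f"v has length {v.shape[0]} but Y has {Y.shape[1]} columns")
    if d1.shape[0] != X.shape[1]:
        raise ValueError(f"d1 has length {d1.shape[0]} but X has {X.shape[1]} columns")
    if np.any(d1 <= 0):
        raise ValueError("diagonal weights must be positive (post-floor)")
    b = X.T @ (Y @ v)
    return _ridge_solve(X.T @ X, d1, alpha1, b)


def update_v(
    X: np.ndarray,
    Y: np.ndarray,
    u: np.ndarray,
    d2: np.ndarray,
    alpha2: float,
) -> np.ndarray:
    """Closed-form v-update: solve (D₂ + α₂YᵀY) v = YᵀXu (mirror of u)."""
    return update_u(Y, X, u, d2, alpha2)


def rescale(w: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Return w / ‖Mw‖ so the canonical score Mw has unit norm."""
    w = np.asarray(w, dtype=float)
    nrm = float(np.linalg.norm(np.asarray(M, dtype=float) @ w))
    if not np.isfinite(nrm) or nrm == 0.0:
        raise ValueError("degenerate direction: Mw has zero norm")
    return w / nrm


def converged(
    u_new: np.ndarray,
    u_old: np.ndarray,
    v_new: np.ndarray,
    v_old: np.ndarray,
    epsilon: float,
) -> bool:
    """True iff max|Δu| ≤ ε and max|Δv| ≤ ε."""
    u_new, u_old = np.asarray(u_new), np.asarray(u_old)
    v_new, v_old = np.asarray(v_new), np.asarray(v_old)
    if u_new.shape != u_old.shape:
        raise ValueError("u vectors have mismatched lengths")
    if v_new.shape != v_old.shape:
        raise ValueError("v vectors have mismatched lengths")
    return bool(
        np.max(np.abs(u_new - u_old)) <= epsilon
        and np.max(np.abs(v_new - v_old)) <= epsilon
    )


def _acs_loop(
    X: np.ndarray,
    Y: np.ndarray,
    spec_u: PenaltySpec,
    spec_v: PenaltySpec,
    config: SolverConfig,
    collect_diagnostics: bool = False,
):
    """Core LQA/ACS iteration on (already preprocessed) X, Y.

    Returns (u, v, objective_trace, step_descent, n_iter, converged_flag).
    """
    n, p = X.shape
    q = Y.shape[1]
    XtX = X.T @ X
    YtY = Y.T @ Y
    XtY = X.T @ Y

    if config.init == "warm" and not (
        spec_u.family == "l1" and spec_v.family == "l1"
    ):
        # LLA-style warm start: converge the convex l1 problem first, then
        # continue with the non-convex penalty from that support.
        from dataclasses import replace

        l1_cfg = replace(config, init="ones")
        u, v, *_ = _acs_loop(
            X, Y, PenaltySpec("l1", spec_u.lam), PenaltySpec("l1", spec_v.lam),
            l1_cfg,
        )
    elif config.init == "random":
        rng = np.random.default_rng(config.seed)
        u = rescale(rng.standard_normal(p), X)
        v = rescale(rng.standard_normal(q), Y)
    else:  # 'ones', or 'warm' on a pure-l1 problem
        u = rescale(np.ones(p), X)
        v = rescale(np.ones(q), Y)

    def lagrangian(uu, vv):
        Xu = X @ uu
        Yv = Y @ vv
        return float(
            -Xu @ Yv
            + penalty_sum(uu, spec_u)
            + penalty_sum(vv, spec_v)
            + 0.5 * config.alpha1 * (Xu @ Xu)
            + 0.5 * config.alpha2 * (Yv @ Yv)
        )

    trace: list[float] = []
    steps: list[tuple[float, float, float, float]] = []
    conv = False
    n_iter = 0
    for _ in range(config.max_iter):
        n_iter += 1
        d1 = lqa_diag_weights(u, spec_u, config.zeta)
        u_raw = _ridge_solve(XtX, d1, config.alpha1, XtY @ v)
        u_new = rescale(u_raw, X)

        d2 = lqa_diag_weights(v, spec_v, config.zeta)
        v_raw = _ridge_solve(YtY, d2, config.alpha2, XtY.T @ u_new)
        v_new = rescale(v_raw, Y)

        if collect_diagnostics:
            steps.append(
                (
                    lagrangian(u, v),
                    lagrangian(u_raw, v),
                    lagrangian(u_new, v),
                    lagrangian(u_new, v_raw),
                )
            )
        trace.append(lagrangian(u_new, v_new))
        done = converged(u_new, u, v_new, v, config.epsilon)
        u, v = u_new, v_new
        if done:
            conv = True
            break
    return u, v, trace, steps, n_iter, conv


def fit(
    dataset: Dataset,
    spec_u: PenaltySpec,
    spec_v: PenaltySpec,
    config: SolverConfig = SolverConfig(),
    standardize: bool = True,
    collect_diagnostics: bool = False,
) -> FitResult:
    """Fit one pair of penalized canonical loadings on a dataset.

    Thin functional wrapper over :class:`foldedcca.estimator.NonconvexSCCA`;
    returns a :class:`FitResult` with loadings satisfying ‖Xu‖ = ‖Yv‖ = 1 on
    the (standardized) training data and sign chosen so corr(Xu, Yv) ≥ 0.
    """
    from .estimator import NonconvexSCCA

    est = NonconvexSCCA(
        penalty=spec_u.family,
        lam=spec_u.lam,
        gamma=spec_u.gamma,
        penalty_v=spec_v.family,
        lam_v=spec_v.lam,
        gamma_v=spec_v.gamma,
        alpha1=config.alpha1,
        alpha2=config.alpha2,
        zeta=config.zeta,
        tol=config.epsilon,
        max_iter=config.max_iter,
        init=config.init,
        random_state=config.seed,
        standardize=standardize,
        collect_diagnostics=collect_diagnostics,
    )
    est.fit(dataset.X, dataset.Y)
    if not est.converged_:
        warnings.warn(
            f"solver did not converge within {config.max_iter} iterations "
            f"(penalties {spec_u.family}/{spec_v.family})",
            RuntimeWarning,
            stacklevel=2,
        )
    return FitResult(
        u=est.u_,
        v=est.v_,
        corr=est.corr_,
        objective_trace=est.objective_trace_,
        n_iter=est.n_iter_,
        converged=est.converged_,
        step_descent=est.step_descent_,
    )
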