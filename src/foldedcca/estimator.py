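"""Scikit-learn style estimator for penalized two-view CCA."""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .penalties import DEFAULT_GAMMA, PenaltySpec
from .solver import DISPLAY_ZERO_TOL, SolverConfig, _acs_loop

__all__ = ["NonconvexSCCA"]


class NonconvexSCCA(BaseEstimator):
    """Sparse CCA with a folded-concave (or ℓ1) penalty per view.

    Finds sparse loading vectors u, v maximizing the correlation between
    the canonical scores Xu and Yv, by minimizing

        -uᵀXᵀYv + Ω₁(u) + Ω₂(v) + (α₁/2)‖Xu‖² + (α₂/2)‖Yv‖²

    with the unit-score constraints enforced by rescaling.  Non-convex
    penalties (SCAD, MCP, ...) shrink small coefficients to (near) zero
    while leaving large coefficients essentially unpenalized, avoiding the
    estimation bias of the ℓ1 norm.

    Parameters
    ----------
    penalty : str, default 'scad'
        Penalty family for the X-view loadings: one of 'l1', 'lgamma',
        'geman', 'scad', 'laplace', 'mcp', 'etp', 'log'.
    lam : float, default 1.0
        Sparsity weight λ₁ for the X view.
    gamma : float, optional
        Concavity parameter γ for the X view; family default if omitted.
    penalty_v, lam_v, gamma_v : optional
        Same for the Y view; default to the X-view settings.
    alpha1, alpha2 : float, default 1.0
        Quadratic constraint weights.
    zeta : float, default 1e-6
        LQA perturbation.
    tol : float, default 1e-5
        Convergence bound ε on the max coordinate change of u and v.
    max_iter : int, default 100
        Iteration cap; non-convergence sets ``converged_ = False``.
    init : {'warm', 'ones', 'random'}, default 'warm'
        Initialization; 'warm' converges the ℓ1 problem first and warm-starts
        the non-convex fit from it; 'random' requires ``random_state``.
    random_state : int, optional
        Seed for random initialization.
    standardize : bool, default True
        Standardize columns of X and Y to zero mean, unit variance before
        fitting (parameters stored for transforming new data).
    collect_diagnostics : bool, default False
        Record per-step majorize–minimize objective values in
        ``step_descent_``.

    Attributes
    ----------
    u_ : ndarray of shape (p,)
        X-view canonical loadings, ‖Xu‖ = 1 on the training data.
    v_ : ndarray of shape (q,)
        Y-view canonical loadings, ‖Yv‖ = 1 on the training data.
    corr_ : float
        Training canonical correlation between Xu and Yv (≥ 0 by sign
        convention).
    objective_trace_ : list of float
        Lagrangian at each (rescaled) iterate.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        penalty: str = "scad",
        lam: float = 1.0,
        gamma: Optional[float] = None,
        penalty_v: Optional[str] = None,
        lam_v: Optional[float] = None,
        gamma_v: Optional[float] = None,
        alpha1: float = 1.0,
        alpha2: float = 1.0,
        zeta: float = 1e-6,
        tol: float = 1e-5,
        max_iter: int = 100,
        init: str = "warm",
        random_state: Optional[int] = None,
        standardize: bool = True,
        collect_diagnostics: bool = False,
    ):
        self.penalty = penalty
        self.lam = lam
        self.gamma = gamma
        self.penalty_v = penalty_v
        self.lam_v = lam_v
        self.gamma_v = gamma_v
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.zeta = zeta
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state
        self.standardize = standardize
        self.collect_diagnostics = collect_diagnostics

    # -- configuration ----------------------------------------------------
    def _specs(self) -> tuple[PenaltySpec, PenaltySpec]:
        fam_u = self.penalty
        spec_u = PenaltySpec(
            fam_u,
            self.lam,
            self.gamma if self.gamma is not None else DEFAULT_GAMMA.get(fam_u),
        )
        fam_v = self.penalty_v if self.penalty_v is not None else fam_u
        gam_v = self.gamma_v
        if gam_v is None:
            gam_v = self.gamma if (self.penalty_v is None and self.gamma is not None) \
                else DEFAULT_GAMMA.get(fam_v)
        spec_v = PenaltySpec(
            fam_v,
            self.lam_v if self.lam_v is not None else self.lam,
            gam_v,
        )
        return spec_u, spec_v

    def _config(self) -> SolverConfig:
        return SolverConfig(
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            zeta=self.zeta,
            epsilon=self.tol,
            max_iter=self.max_iter,
            init=self.init,
            seed=self.random_state,
        )

    # -- fitting -----------------------------------------------------------
    def fit(self, X, Y):
        """Fit canonical loadings on paired matrices X (n×p) and Y (n×q)."""
        X = check_array(X, dtype=float, ensure_min_samples=2)
        Y = check_array(Y, dtype=float, ensure_min_samples=2)
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"X and Y must share rows: got {X.shape[0]} and {Y.shape[0]}"
            )
        spec_u, spec_v = self._specs()
        config = self._config()

        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            self.y_mean_ = Y.mean(axis=0)
            x_scale = X.std(axis=0)
            y_scale = Y.std(axis=0)
            # constant columns carry no association signal; leave them centered
            self.x_scale_ = np.where(x_scale == 0, 1.0, x_scale)
            self.y_scale_ = np.where(y_scale == 0, 1.0, y_scale)
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.y_mean_ = np.zeros(Y.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
            self.y_scale_ = np.ones(Y.shape[1])
        Xs = (X - self.x_mean_) / self.x_scale_
        Ys = (Y - self.y_mean_) / self.y_scale_

        u, v, trace, steps, n_iter, conv = _acs_loop(
            Xs, Ys, spec_u, spec_v, config,
            collect_diagnostics=self.collect_diagnostics,
        )

        xu = Xs @ u
        yv = Ys @ v
        corr = _safe_corr(xu, yv)
        if corr < 0:  # sign convention: positive canonical correlation
            v = -v
            corr = -corr

        self.u_ = u
        self.v_ = v
        self.corr_ = float(corr)
        self.objective_trace_ = trace
        self.step_descent_ = steps
        self.n_iter_ = n_iter
        self.converged_ = conv
        self.n_features_x_ = X.shape[1]
        self.n_features_y_ = Y.shape[1]
        return self

    # -- application -------------------------------------------------------
    def transform(self, X, Y=None):
        """Project new data onto the canonical directions.

        Returns the X scores, or (X scores, Y scores) when Y is given.
        Standardization parameters learned at fit time are applied.
        """
        check_is_fitted(self, "u_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_x_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_x_}"
            )
        xs = ((X - self.x_mean_) / self.x_scale_) @ self.u_
        if Y is None:
            return xs
        Y = check_array(Y, dtype=float)
        if Y.shape[1] != self.n_features_y_:
            raise ValueError(
                f"Y has {Y.shape[1]} columns, expected {self.n_features_y_}"
            )
        ys = ((Y - self.y_mean_) / self.y_scale_) @ self.v_
        return xs, ys

    def score(self, X, Y):
        """Canonical correlation between Xu and Yv on new data."""
        xs, ys = self.transform(X, Y)
        return _safe_corr(xs - xs.mean(), ys - ys.mean())

    # -- reporting ----------------------------------------------------------
    def sparse_loadings(self, tol: float = DISPLAY_ZERO_TOL):
        """Loadings with entries of magnitude below ``tol`` displayed as 0."""
        check_is_fitted(self, "u_")
        u = np.where(np.abs(self.u_) < tol, 0.0, self.u_)
        v = np.where(np.abs(self.v_) < tol, 0.0, self.v_)
        return u, v


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("undefined correlation: a score vector has zero variance")
    return float(a @ b / (na * nb))
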