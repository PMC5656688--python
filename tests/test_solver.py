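"""Optimizer: closed-form updates against dense oracles, constraint and
convergence handling, and the fitted solution's structural properties."""

import numpy as np
import pytest

from foldedcca import (
    Dataset,
    PenaltySpec,
    SolverConfig,
    converged,
    fit,
    objective,
    penalty_sum,
    rescale,
    update_u,
    update_v,
)
from foldedcca.penalties import WEIGHT_FLOOR, lqa_diag_weights
from foldedcca.solver import _acs_loop
from tests.conftest import ALL_SPECS


L0 = PenaltySpec("l1", 0.0)  # zero penalty


# -- objective -------------------------------------------------------------

def test_objective_vanishes_for_zero_vectors():
    X = np.eye(3)
    Y = np.eye(3)
    assert objective(np.zeros(3), np.zeros(3), X, Y, L0, L0) == 0.0


def test_objective_identity_example():
    X = Y = np.eye(2)
    u = v = np.array([1.0, 0.0])
    # -u'v + 0.5||u||^2 + 0.5||v||^2 = -1 + 0.5 + 0.5
    assert objective(u, v, X, Y, L0, L0) == pytest.approx(0.0, abs=1e-15)


def test_objective_matches_term_by_term_oracle(rng):
    X = rng.standard_normal((12, 5))
    Y = rng.standard_normal((12, 7))
    u = rng.standard_normal(5)
    v = rng.standard_normal(7)
    su = PenaltySpec("scad", 0.8, 4.0)
    sv = PenaltySpec("log", 1.1, 50.0)
    cfg = SolverConfig(alpha1=0.7, alpha2=1.9)
    expected = (
        -float(u @ X.T @ Y @ v)
        + penalty_sum(u, su)
        + penalty_sum(v, sv)
        + 0.35 * float(np.linalg.norm(X @ u) ** 2)
        + 0.95 * float(np.linalg.norm(Y @ v) ** 2)
    )
    assert objective(u, v, X, Y, su, sv, cfg) == pytest.approx(expected, rel=1e-10)


def test_objective_dimension_mismatch_named():
    with pytest.raises(ValueError, match="u has length"):
        objective(np.zeros(4), np.zeros(3), np.eye(3), np.eye(3), L0, L0)


# -- closed-form updates ---------------------------------------------------

def test_update_u_identity_example():
    u = update_u(np.eye(2), np.eye(2), np.array([1.0, 0.0]), np.ones(2), 1.0)
    np.testing.assert_allclose(u, [0.5, 0.0], atol=1e-12)


def test_update_v_mirror_example():
    v = update_v(np.eye(2), np.eye(2), np.array([0.0, 1.0]), np.ones(2), 1.0)
    np.testing.assert_allclose(v, [0.0, 0.5], atol=1e-12)


def test_updates_match_dense_inverse_oracle(rng):
    X = rng.standard_normal((10, 8))
    Y = rng.standard_normal((10, 6))
    v = rng.standard_normal(6)
    d1 = rng.uniform(0.1, 2.0, 8)
    a1 = 1.3
    u = update_u(X, Y, v, d1, a1)
    oracle = np.linalg.inv(np.diag(d1) + a1 * X.T @ X) @ (X.T @ Y @ v)
    np.testing.assert_allclose(u, oracle, atol=1e-9)
    # stationarity residual of the linear system
    res = -(X.T @ Y @ v) + (np.diag(d1) + a1 * X.T @ X) @ u
    b = X.T @ Y @ v
    assert np.abs(res).max() <= 1e-8 * (1 + np.abs(b).max())


def test_update_v_equals_swapped_update_u(rng):
    X = rng.standard_normal((9, 5))
    Y = rng.standard_normal((9, 7))
    u = rng.standard_normal(5)
    d2 = rng.uniform(0.5, 1.5, 7)
    np.testing.assert_allclose(
        update_v(X, Y, u, d2, 0.9), update_u(Y, X, u, d2, 0.9), atol=1e-12
    )


def test_update_u_rejects_nonpositive_weights():
    with pytest.raises(ValueError, match="positive"):
        update_u(np.eye(2), np.eye(2), np.ones(2), np.array([1.0, 0.0]), 1.0)


# -- rescale / converged ---------------------------------------------------

def test_rescale_examples():
    np.testing.assert_allclose(rescale(np.array([3.0, 4.0]), np.eye(2)), [0.6, 0.8])
    w = np.array([0.6, 0.8])
    np.testing.assert_allclose(rescale(w, np.eye(2)), w)  # already unit
    np.testing.assert_allclose(
        rescale(7.3 * np.array([3.0, 4.0]), np.eye(2)), [0.6, 0.8]
    )  # scale invariance


def test_rescale_degenerate_direction():
    M = np.array([[1.0, 0.0], [0.0, 0.0]])
    with pytest.raises(ValueError, match="degenerate"):
        rescale(np.array([0.0, 1.0]), M)


def test_converged_cases():
    a = np.array([1.0, 2.0])
    assert converged(a, a, a, a, 1e-5)
    assert not converged(a + 2e-5, a, a, a, 1e-5)  # both sides required
    assert converged(a + 9e-6, a, a + 9e-6, a, 1e-5)
    with pytest.raises(ValueError):
        converged(a, np.zeros(3), a, a, 1e-5)


# -- full fits -------------------------------------------------------------

@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
def test_fit_constraints_and_mm_descent(random_dataset, spec):
    """Unit score norms at the solution and per-step majorize-minimize
    descent of the two convex subproblem solves."""
    res = fit(random_dataset, spec, spec, collect_diagnostics=True)
    X = (random_dataset.X - random_dataset.X.mean(0)) / random_dataset.X.std(0)
    Y = (random_dataset.Y - random_dataset.Y.mean(0)) / random_dataset.Y.std(0)
    assert np.linalg.norm(X @ res.u) == pytest.approx(1.0, abs=1e-8)
    assert np.linalg.norm(Y @ res.v) == pytest.approx(1.0, abs=1e-8)
    assert res.corr >= 0
    assert len(res.objective_trace) == res.n_iter
    for before_u, after_u, before_v, after_v in res.step_descent:
        assert after_u <= before_u + 1e-8 * (1 + abs(before_u))
        assert after_v <= before_v + 1e-8 * (1 + abs(before_v))


def test_unit_norms_hold_at_every_iterate(small_dataset):
    """Truncating the iteration at any point leaves rescaled iterates."""
    spec = PenaltySpec("geman")
    X = (small_dataset.X - small_dataset.X.mean(0)) / small_dataset.X.std(0)
    Y = (small_dataset.Y - small_dataset.Y.mean(0)) / small_dataset.Y.std(0)
    full = fit(small_dataset, spec, spec)
    for m in range(1, full.n_iter + 1):
        cfg = SolverConfig(max_iter=m)
        u, v, _, _, _, _ = _acs_loop(X, Y, spec, spec, cfg)
        assert np.linalg.norm(X @ u) == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(Y @ v) == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
def test_stationarity_at_convergence(random_dataset, spec):
    """At the fixed point, re-running one block update reproduces the
    iterate, and the update solves its linear system to high accuracy."""
    res = fit(random_dataset, spec, spec)
    assert res.converged
    X = (random_dataset.X - random_dataset.X.mean(0)) / random_dataset.X.std(0)
    Y = (random_dataset.Y - random_dataset.Y.mean(0)) / random_dataset.Y.std(0)
    cfg = SolverConfig()
    d1 = lqa_diag_weights(res.u, spec, cfg.zeta)
    u_solve = update_u(X, Y, res.v, d1, cfg.alpha1)
    b = X.T @ Y @ res.v
    lin_res = -(b) + (np.diag(d1) + cfg.alpha1 * X.T @ X) @ u_solve
    assert np.abs(lin_res).max() <= 1e-6 * (1 + np.abs(b).max())
    np.testing.assert_allclose(
        rescale(u_solve, X), res.u, atol=20 * cfg.epsilon
    )
    d2 = lqa_diag_weights(res.v, spec, cfg.zeta)
    v_solve = update_v(X, Y, res.u, d2, cfg.alpha2)
    np.testing.assert_allclose(
        rescale(v_solve, Y), res.v, atol=20 * cfg.epsilon
    )


def test_view_symmetry(small_dataset):
    spec = PenaltySpec("geman")
    fwd = fit(small_dataset, spec, spec)
    swapped = Dataset(X=small_dataset.Y, Y=small_dataset.X)
    bwd = fit(swapped, spec, spec)
    # same solution up to a joint sign
    sign = np.sign(fwd.u @ bwd.v) or 1.0
    np.testing.assert_allclose(fwd.u, sign * bwd.v, atol=1e-4)
    np.testing.assert_allclose(fwd.v, sign * bwd.u, atol=1e-4)
    assert fwd.corr == pytest.approx(bwd.corr, abs=1e-6)


def test_permutation_equivariance(small_dataset, rng):
    spec = PenaltySpec("laplace")
    base = fit(small_dataset, spec, spec)
    pi = rng.permutation(small_dataset.p)
    tau = rng.permutation(small_dataset.q)
    permuted = Dataset(X=small_dataset.X[:, pi], Y=small_dataset.Y[:, tau])
    res = fit(permuted, spec, spec)
    np.testing.assert_allclose(res.u, base.u[pi], atol=1e-6)
    np.testing.assert_allclose(res.v, base.v[tau], atol=1e-6)


def test_deterministic_given_init(small_dataset):
    spec = PenaltySpec("etp")
    a = fit(small_dataset, spec, spec)
    b = fit(small_dataset, spec, spec)
    np.testing.assert_array_equal(a.u, b.u)
    cfg = SolverConfig(init="random", seed=7)
    c = fit(small_dataset, spec, spec, cfg)
    d = fit(small_dataset, spec, spec, cfg)
    np.testing.assert_array_equal(c.u, d.u)


def test_random_init_requires_seed():
    with pytest.raises(ValueError, match="seed"):
        SolverConfig(init="random")


def test_nonconvergence_is_flagged_not_raised(small_dataset):
    spec = PenaltySpec("geman")
    with pytest.warns(RuntimeWarning, match="did not converge"):
        res = fit(small_dataset, spec, spec, SolverConfig(max_iter=1))
    assert not res.converged
    assert res.n_iter == 1


def test_l1_shrinkage_monotone_in_lambda(small_dataset):
    """Support size (|u_i| > 1e-3) does not grow as lambda increases."""
    counts = []
    for lam in (0.2, 0.5, 1.0, 2.0, 4.0):
        res = fit(small_dataset, PenaltySpec("l1", lam), PenaltySpec("l1", lam))
        counts.append(int(np.sum(np.abs(res.u) > 1e-3)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_folded_concave_leaves_large_coefficients_unpenalized(spiked_dataset):
    """For SCAD/MCP, converged coefficients beyond gamma*lam carry the
    floor weight (no shrinkage), unlike l1 whose weights stay positive."""
    for spec in (PenaltySpec("mcp", 1.0, 0.01), PenaltySpec("scad", 0.005, 3.7)):
        res = fit(spiked_dataset, spec, spec)
        big = np.abs(res.u) >= spec.gamma * spec.lam
        assert big.any(), "expected some coefficients beyond the clipping point"
        w = lqa_diag_weights(res.u, spec, 1e-6)
        assert np.all(w[big] == WEIGHT_FLOOR)
    res = fit(spiked_dataset, PenaltySpec("l1"), PenaltySpec("l1"))
    w = lqa_diag_weights(res.u, PenaltySpec("l1"), 1e-6)
    assert np.all(w > WEIGHT_FLOOR)
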