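"""Solver unit and property tests, checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect, minimize

from maxentpop import (
    ConditioningError,
    ConstraintSet,
    ConvergenceError,
    FeasibilityError,
    ProbabilityVector,
    SolverOptions,
    constraint_residuals,
    shannon_entropy,
    solve_maxent,
)


def geometric_family_oracle(g, C):
    """1-D bisection on the single-constraint exponential family.

    For one row the solution is p_i ~ exp(-lam*g_i) with lam chosen so the
    expectation of g equals C; the expectation is monotone in lam, so
    bisection brackets it independently of the Newton path.
    """

    def mean(lam):
        w = np.exp(-lam * (g - g.min()))
        return (g * w).sum() / w.sum() - C

    lam = bisect(mean, -200.0, 200.0, xtol=1e-14)
    w = np.exp(-lam * (g - g.min()))
    return w / w.sum()


def scipy_maxent_oracle(G, C):
    """Generic constrained optimizer: maximize entropy over the simplex."""

    def neg_entropy(p):
        p = np.clip(p, 1e-300, None)
        return float(np.sum(p * np.log(p)))

    n = G.shape[1]
    cons = [{"type": "eq", "fun": lambda p: p.sum() - 1.0}]
    for r in range(G.shape[0]):
        cons.append({"type": "eq", "fun": lambda p, r=r: G[r] @ p - C[r]})
    res = minimize(
        neg_entropy,
        np.full(n, 1.0 / n),
        method="SLSQP",
        bounds=[(1e-12, 1.0)] * n,
        constraints=cons,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x


class TestSolveMaxent:
    def test_unconstrained_solution_is_uniform(self):
        sol = solve_maxent(ConstraintSet.empty(33))
        np.testing.assert_allclose(sol.p.p, 1.0 / 33, atol=1e-15)
        assert sol.entropy == pytest.approx(np.log(33), abs=1e-12)
        assert sol.converged

    def test_symmetric_mean_target_keeps_uniform(self):
        cs = ConstraintSet(np.array([[1.0, 2, 3, 4, 5]]), np.array([3.0]))
        sol = solve_maxent(cs)
        np.testing.assert_allclose(sol.p.p, 0.2, atol=1e-12)
        assert sol.lambdas[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_bisection_oracle_on_geometric_family(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        cs = ConstraintSet(g[None, :], np.array([1.75]))
        sol = solve_maxent(cs)
        p_oracle = geometric_family_oracle(g, 1.75)
        np.testing.assert_allclose(sol.p.p, p_oracle, atol=1e-8)

    def test_duplicated_rows_raise_conditioning_error(self):
        G = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        with pytest.raises(ConditioningError):
            solve_maxent(ConstraintSet(G, np.array([2.0, 2.0])))

    @pytest.mark.parametrize("target", [0.5, 4.0, 1.0])
    def test_target_outside_open_range_raises_feasibility_error(self, target):
        cs = ConstraintSet(np.array([[1.0, 2, 3, 4]]), np.array([target]))
        with pytest.raises(FeasibilityError):
            solve_maxent(cs)

    def test_constant_row_with_wrong_target_is_infeasible(self):
        cs = ConstraintSet(np.array([[2.0, 2, 2, 2]]), np.array([3.0]))
        with pytest.raises(FeasibilityError):
            solve_maxent(cs)

    def test_iteration_budget_exhaustion_names_worst_row(self):
        cs = ConstraintSet(
            np.array([[1.0, 2, 3, 4]]), np.array([1.01]), labels=("mean",)
        )
        with pytest.raises(ConvergenceError, match="mean"):
            solve_maxent(cs, SolverOptions(max_iterations=1))
        sol = solve_maxent(
            cs, SolverOptions(max_iterations=1, raise_on_failure=False)
        )
        assert not sol.converged

    def test_exponential_form_holds_with_original_rows(self):
        idx = np.arange(1.0, 11.0)
        G = np.vstack([idx, idx**2, idx**3])
        p_ref = np.linspace(2, 1, 10)
        p_ref /= p_ref.sum()
        sol = solve_maxent(ConstraintSet(G, G @ p_ref))
        recon = np.exp(-sol.lambda0 - sol.lambdas @ G)
        np.testing.assert_allclose(recon, sol.p.p, atol=1e-10)

    def test_converged_residuals_within_tolerance(self):
        idx = np.arange(1.0, 34.0)
        G = np.vstack([idx**m for m in (1, 2, 5)])
        p_ref = np.exp(-0.1 * idx)
        p_ref /= p_ref.sum()
        cs = ConstraintSet(G, G @ p_ref)
        sol = solve_maxent(cs)
        assert sol.converged
        rel = np.abs(sol.residuals) / np.maximum(1.0, np.abs(cs.C))
        assert rel.max() <= 1e-10

    def test_agrees_with_generic_optimizer_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 7))
            G = rng.uniform(-1, 1, size=(2, n))
            p_feas = rng.dirichlet(np.ones(n) * 3)
            cs = ConstraintSet(G, G @ p_feas)
            sol = solve_maxent(cs)
            p_oracle = scipy_maxent_oracle(cs.G, cs.C)
            assert np.max(np.abs(sol.p.p - p_oracle)) <= 1e-6

    def test_entropy_decreases_for_nested_constraint_sets(self, rng):
        idx = np.arange(1.0, 9.0)
        p_feas = rng.dirichlet(np.ones(8))
        small = ConstraintSet(idx[None, :], np.array([idx @ p_feas]))
        big = ConstraintSet(
            np.vstack([idx, idx**2]), np.array([idx @ p_feas, (idx**2) @ p_feas])
        )
        assert solve_maxent(big).entropy <= solve_maxent(small).entropy + 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        factor=st.floats(min_value=1e-4, max_value=1e6),
        target=st.floats(min_value=1.2, max_value=3.8),
    )
    def test_row_rescaling_leaves_solution_unchanged(self, factor, target):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        # tight tolerance: the residual criterion is absolute for small |C|,
        # and the property concerns the exact solution map
        opts = SolverOptions(tolerance=1e-14)
        base = solve_maxent(ConstraintSet(g[None, :], np.array([target])), opts)
        scaled = solve_maxent(
            ConstraintSet(factor * g[None, :], np.array([factor * target])), opts
        )
        np.testing.assert_allclose(base.p.p, scaled.p.p, atol=1e-10)

    def test_exact_interpolation_recovers_any_positive_distribution(self, rng):
        for n in (4, 6):
            p_star = rng.dirichlet(np.ones(n) * 2)
            p_star = np.maximum(p_star, 1e-4)
            p_star /= p_star.sum()
            idx = np.arange(1.0, n + 1)
            G = np.vstack([idx**m for m in range(1, n)])
            sol = solve_maxent(ConstraintSet(G, G @ p_star))
            np.testing.assert_allclose(sol.p.p, p_star, atol=1e-8)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.full(33, 1 / 33), np.log(33)),
            (np.array([1.0, 0.0, 0.0]), 0.0),
            (np.array([0.5, 0.25, 0.25]), 1.5 * np.log(2)),
        ],
    )
    def test_known_values(self, p, expected):
        assert shannon_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_entries_and_bad_sums(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([0.6, 0.6, -0.2]))
        with pytest.raises(ValueError):
            shannon_entropy(np.array([0.3, 0.3, 0.3]))

    def test_entropy_bounded_by_log_n(self, rng):
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            assert 0.0 <= shannon_entropy(p) <= np.log(6) + 1e-12


class TestConstraintResiduals:
    def test_known_residuals(self):
        cs = ConstraintSet(np.array([[1.0, 2, 3, 4]]), np.array([2.5]))
        assert constraint_residuals(np.full(4, 0.25), cs)[0] == pytest.approx(0.0)
        assert constraint_residuals(
            ProbabilityVector(np.array([1.0, 0, 0, 0])), cs
        )[0] == pytest.approx(-1.5)

    def test_dimension_mismatch_rejected(self):
        cs = ConstraintSet(np.array([[1.0, 2, 3, 4]]), np.array([2.5]))
        with pytest.raises(ValueError):
            constraint_residuals(np.full(5, 0.2), cs)


class TestConstraintSetValidation:
    def test_too_many_rows_rejected(self):
        idx = np.arange(1.0, 5.0)
        G = np.vstack([idx**m for m in range(1, 5)])  # 4 rows on 4 units
        with pytest.raises(ValueError, match="N-1"):
            ConstraintSet(G, np.ones(4))

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="identically zero"):
            ConstraintSet(np.array([[0.0, 0, 0, 0]]), np.array([0.0]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet(np.array([[1.0, np.inf, 3, 4]]), np.array([2.0]))
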