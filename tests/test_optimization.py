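import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calfcontrib import (
    FrameProblem,
    SolverError,
    solve_frame,
    solve_trial,
)
from calfcontrib.dynamics import JointMomentSeries


def brute_force_1dof(r, f_max, M, grid=0.1):
    """Independent oracle: exhaustive 0.1 N grid search for one DOF.

    Grids all muscles but the last; the last force is solved from the
    equality constraint, so every evaluated point satisfies R F = M exactly.
    """
    r = np.asarray(r, dtype=float)
    f_max = np.asarray(f_max, dtype=float)
    n = f_max.size
    best, best_obj = None, np.inf
    axes = [np.arange(0.0, f_max[i] + grid / 2, grid) for i in range(n - 1)]
    for combo in itertools.product(*axes):
        f_last = (M - np.dot(r[:-1], combo)) / r[-1]
        if not -1e-9 <= f_last <= f_max[-1] + 1e-9:
            continue
        f = np.array(list(combo) + [min(max(f_last, 0.0), f_max[-1])])
        obj = np.sum((f / f_max) ** 2)
        if obj < best_obj:
            best_obj, best = obj, f
    return best, best_obj


def kkt_equal_arms(f_max, r, M):
    """Closed-form KKT for one DOF, equal arms, no active bounds:
    F_i proportional to f_max_i^2."""
    f_max = np.asarray(f_max, dtype=float)
    lam = M / (r * np.sum(f_max**2))
    return lam * f_max**2


class TestSolveFrameClosedForm:
    def test_equal_arms_forces_proportional_to_fmax_squared(self):
        sol = solve_frame(FrameProblem([[0.05, 0.05]], [25.0], [1000.0, 500.0]))
        np.testing.assert_allclose(sol.forces, [400.0, 100.0], rtol=1e-6)
        assert sol.status == "solved"
        assert sol.residual <= 1e-6 * 26

    def test_zero_moment(self):
        sol = solve_frame(FrameProblem([[0.05, -0.03]], [0.0], [1000.0, 500.0]))
        np.testing.assert_allclose(sol.forces, 0.0, atol=1e-9)
        assert sol.objective == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        sol = solve_frame(FrameProblem([[0.04, 0.04]], [40.0], [1000.0, 1000.0]))
        np.testing.assert_allclose(sol.forces, [500.0, 500.0], rtol=1e-9)

    def test_active_upper_bound(self):
        # M = 72 N*m saturates muscle 1 (f_max 1000), remainder on muscle 2
        sol = solve_frame(FrameProblem([[0.05, 0.05]], [72.0], [1000.0, 500.0]))
        np.testing.assert_allclose(sol.forces, [1000.0, 440.0], rtol=1e-6)

    def test_matches_kkt_closed_form_generic(self):
        f_max = np.array([900.0, 300.0, 1500.0])
        expected = kkt_equal_arms(f_max, 0.04, 30.0)
        sol = solve_frame(FrameProblem([[0.04, 0.04, 0.04]], [30.0], f_max))
        np.testing.assert_allclose(sol.forces, expected, rtol=1e-6)

    def test_infeasible_reported_not_clamped(self):
        sol = solve_frame(FrameProblem([[0.05]], [100.0], [1000.0]))  # max 50 N*m
        assert sol.status == "infeasible"
        assert np.all(np.isnan(sol.forces))

    def test_relax_mode_projects_moment(self):
        sol = solve_frame(
            FrameProblem([[0.05]], [100.0], [1000.0]), relax=True
        )
        assert sol.status == "solved"
        np.testing.assert_allclose(sol.forces, [1000.0], rtol=1e-6)
        assert sol.residual == pytest.approx(50.0, rel=1e-6)

    def test_degenerate_zero_column_gets_zero_force(self):
        sol = solve_frame(FrameProblem([[0.05, 0.0]], [25.0], [1000.0, 500.0]))
        assert sol.forces[1] == pytest.approx(0.0, abs=1e-9)
        assert sol.forces[0] == pytest.approx(500.0, rel=1e-9)

    def test_opposite_arms_antagonist_loading(self):
        # brute-force verified optimum with an antagonist pair
        r = [[0.05, -0.04]]
        f_max = [1000.0, 500.0]
        sol = solve_frame(FrameProblem(r, [20.0], f_max))
        brute, _ = brute_force_1dof(np.array(r[0]), f_max, 20.0, grid=0.05)
        np.testing.assert_allclose(sol.forces, brute, atol=0.1)


class TestBruteForceOracle:
    @pytest.mark.parametrize(
        "r,f_max,M",
        [
            ([0.05, 0.05], [1000.0, 500.0], 25.0),
            ([0.05, 0.05], [1000.0, 500.0], 72.0),
            ([0.04, -0.03], [800.0, 400.0], 18.0),
            ([0.05, 0.03, 0.04], [600.0, 900.0, 300.0], 40.0),
        ],
    )
    def test_solver_matches_grid_search(self, r, f_max, M):
        sol = solve_frame(FrameProblem([r], [M], f_max))
        brute, brute_obj = brute_force_1dof(np.array(r), f_max, M, grid=0.1)
        assert sol.status == "solved"
        np.testing.assert_allclose(sol.forces, brute, atol=0.2)
        assert sol.objective <= brute_obj + 1e-9


class TestProperties:
    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_scaling(self, c):
        base = FrameProblem([[0.05, 0.05], [0.01, -0.02]], [25.0, 2.0], [1000.0, 500.0])
        scaled = FrameProblem(base.R, base.M * c, base.f_max * c)
        a1 = solve_frame(base).activations
        a2 = solve_frame(scaled).activations
        np.testing.assert_allclose(a1, a2, atol=1e-7)
        np.testing.assert_allclose(
            solve_frame(scaled).forces, solve_frame(base).forces * c, rtol=1e-6
        )

    def test_objective_monotone_in_moment(self):
        objs = [
            solve_frame(FrameProblem([[0.05, 0.05]], [m], [1000.0, 500.0])).objective
            for m in np.linspace(0, 70, 15)
        ]
        assert np.all(np.diff(objs) >= -1e-12)

    def test_equality_residual_bound(self, rng):
        for _ in range(20):
            R = rng.normal(size=(3, 8)) * 0.04
            f_max = rng.uniform(200, 2000, size=8)
            a_true = rng.uniform(0.05, 0.6, size=8)
            M = R @ (a_true * f_max)  # guaranteed feasible
            sol = solve_frame(FrameProblem(R, M, f_max))
            assert sol.status == "solved"
            assert sol.residual <= 1e-6 * (1 + np.linalg.norm(M))
            assert np.all(sol.forces >= -1e-9)
            assert np.all(sol.forces <= f_max + 1e-6)


class TestSolveTrial:
    def test_constant_moments_identical_solutions(self, model):
        M = np.tile([[-80.0, 3.0, -5.0]], (10, 1))
        series = JointMomentSeries(
            np.arange(10) / 1000.0, M, ("ankle_flexion", "subtalar", "mtp_flexion")
        )
        sol = solve_trial(model, series)
        assert np.all(sol.status == "solved")
        for k in range(1, 10):
            np.testing.assert_allclose(sol.forces[k], sol.forces[0], atol=1e-8)

    def test_too_weak_model_raises(self, model):
        M = np.tile([[-5000.0, 0.0, 0.0]], (5, 1))
        series = JointMomentSeries(
            np.arange(5) / 1000.0, M, ("ankle_flexion", "subtalar", "mtp_flexion")
        )
        with pytest.raises(SolverError, match="model too weak for trial"):
            solve_trial(model, series)

    def test_noiseless_trial_all_frames_solved(self, model, noiseless_trial):
        sol = solve_trial(model, noiseless_trial.truth_moments)
        assert sol.n_infeasible == 0
        # truth forces are the QP optimum of the truth moments: exact recovery
        np.testing.assert_allclose(
            sol.forces, noiseless_trial.truth_forces, atol=1e-6
        )
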