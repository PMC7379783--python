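"""Static optimization: distribute net DOF moments across muscles.

Per frame, solve the convex quadratic program

    minimize    sum_i (F_i / f_max_i)^2
    subject to  R F = M,   0 <= F_i <= f_max_i

In activation variables ``a_i = F_i / f_max_i`` this is a box-constrained
minimum-norm problem ``min ||a||^2  s.t.  A a = M,  0 <= a <= 1`` with
``A = R diag(f_max)``, solved by a primal active-set method on the KKT
system.  Problems are tiny (tens of variables, a few equality rows), so the
method favours robustness and exactness over speed; a vectorized fast path
handles the common strictly interior frames in one least-squares solve.

Infeasible frames (moment outside the attainable polytope) are reported as
such, never silently relaxed; ``relax=True`` first minimizes the equality
residual and then the objective over the residual-optimal set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .errors import SolverError
from .dynamics import JointMomentSeries
from .model import ModelDefinition, moment_arm_matrix

__all__ = [
    "FrameProblem",
    "FrameSolution",
    "MuscleForceSolution",
    "solve_frame",
    "solve_trial",
]

_BOUND_TOL = 1e-9
_STAT_TOL = 1e-8
_MAX_ITER = 200


@dataclass(frozen=True)
class FrameProblem:
    """One frame's moment-distribution problem."""

    R: np.ndarray  # (n_dof, n_muscle) moment arms, m
    M: np.ndarray  # (n_dof,) net DOF moments, N*m
    f_max: np.ndarray  # (n_muscle,) force upper bounds, N

    def __post_init__(self) -> None:
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        M = np.atleast_1d(np.asarray(self.M, dtype=float))
        f_max = np.atleast_1d(np.asarray(self.f_max, dtype=float))
        if R.shape != (M.size, f_max.size):
            raise SolverError(
                f"dimension mismatch: R {R.shape}, M {M.shape}, f_max {f_max.shape}"
            )
        if np.any(f_max <= 0):
            raise SolverError("f_max must be positive elementwise")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "f_max", f_max)


@dataclass(frozen=True)
class FrameSolution:
    forces: np.ndarray
    activations: np.ndarray
    objective: float
    status: str  # "solved" | "infeasible"
    residual: float  # ||R F - M||


@dataclass(frozen=True)
class MuscleForceSolution:
    """Per-frame muscle forces for a whole trial."""

    time: np.ndarray
    forces: np.ndarray  # (n_frames, n_muscle), NaN on infeasible frames
    activations: np.ndarray
    objective: np.ndarray  # (n_frames,)
    status: np.ndarray  # (n_frames,) of str
    residual: np.ndarray
    muscle_order: tuple[str, ...]

    @property
    def n_infeasible(self) -> int:
        return int(np.sum(self.status != "solved"))

    @property
    def solved_mask(self) -> np.ndarray:
        return self.status == "solved"


def _feasibility_tol(M: np.ndarray) -> float:
    return 1e-6 * (1.0 + float(np.linalg.norm(M)))


def _feasible_point(A: np.ndarray, M: np.ndarray) -> np.ndarray | None:
    """Phase-1: any a in [0,1]^n with A a = M, or None if infeasible."""
    n = A.shape[1]
    res = linprog(
        c=np.zeros(n),
        A_eq=A,
        b_eq=M,
        bounds=[(0.0, 1.0)] * n,
        method="highs",
    )
    if not res.success:
        return None
    a = np.clip(res.x, 0.0, 1.0)
    if np.linalg.norm(A @ a - M) > _feasibility_tol(M):
        return None
    return a


def _min_norm_active_set(
    A: np.ndarray, M: np.ndarray, a0: np.ndarray
) -> np.ndarray:
    """Primal active-set solve of min ||a||^2 s.t. A a = M, 0 <= a <= 1.

    ``a0`` must be feasible; returns the unique minimizer.
    """
    n = A.shape[1]
    a = a0.copy()
    lower = a <= _BOUND_TOL
    upper = a >= 1.0 - _BOUND_TOL

    for _ in range(_MAX_ITER):
        free = ~(lower | upper)
        rhs = M - A[:, upper].sum(axis=1)
        Af = A[:, free]
        if free.any():
            af, *_ = np.linalg.lstsq(Af, rhs, rcond=None)
        else:
            af = np.zeros(0)
        cand = np.where(lower, 0.0, np.where(upper, 1.0, 0.0))
        cand[free] = af
        d = cand - a

        if np.linalg.norm(d, ord=np.inf) > _STAT_TOL:
            # longest feasible step toward the candidate
            alpha = 1.0
            blocking = -1
            block_upper = False
            for i in np.flatnonzero(free):
                if d[i] > _BOUND_TOL:
                    step = (1.0 - a[i]) / d[i]
                    if step < alpha - 1e-15:
                        alpha, blocking, block_upper = step, i, True
                elif d[i] < -_BOUND_TOL:
                    step = -a[i] / d[i]
                    if step < alpha - 1e-15:
                        alpha, blocking, block_upper = step, i, False
            a = a + alpha * d
            if blocking >= 0:
                if block_upper:
                    a[blocking] = 1.0
                    upper[blocking] = True
                else:
                    a[blocking] = 0.0
                    lower[blocking] = True
                continue
            a = np.clip(a, 0.0, 1.0)

        # stationary for the current working set: check bound multipliers
        # free-variable stationarity: a_free = (A^T lam)_free
        if free.any():
            lam, *_ = np.linalg.lstsq(Af.T, a[free], rcond=None)
        else:
            lam, *_ = np.linalg.lstsq(A.T, a, rcond=None)
        grad = a - A.T @ lam  # = bound multipliers (lower: -mu, upper: +mu)
        release = -1
        worst = _STAT_TOL
        for i in np.flatnonzero(lower):
            # require (A^T lam)_i <= 0  <=>  grad_i >= 0
            if -grad[i] > worst:
                worst, release = -grad[i], i
        for i in np.flatnonzero(upper):
            # require (A^T lam)_i >= 1  <=>  grad_i <= 0
            if grad[i] > worst:
                worst, release = grad[i], i
        if release < 0:
            return np.clip(a, 0.0, 1.0)
        lower[release] = False
        upper[release] = False

    raise SolverError("active-set solver failed to converge")


def _dual_newton(
    A: np.ndarray,
    M: np.ndarray,
    lam0: np.ndarray | None = None,
    max_iter: int = 60,
    center: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Semismooth Newton on the dual of the box-constrained projection QP
    ``min ||a - center||^2  s.t.  A a = M,  0 <= a <= 1`` (center = 0 gives
    the minimum-norm problem used by the solver).

    At the optimum the KKT conditions collapse to
    ``a = clip(center + A^T lam, 0, 1)`` with ``A a = M``; we solve that
    piecewise-linear system for lam.  Returns (a, lam) on convergence (then
    a is exactly the global minimizer), or None (caller falls back to the
    active-set path; e.g. infeasible M, where the dual diverges).
    """
    n_dof = A.shape[0]
    lam = np.zeros(n_dof) if lam0 is None else lam0.copy()
    tol = 1e-9 * (1.0 + float(np.linalg.norm(M)))
    z = center + A.T @ lam
    a = np.clip(z, 0.0, 1.0)
    r = A @ a - M
    rn = float(np.linalg.norm(r))
    for _ in range(max_iter):
        if rn <= tol:
            return a, lam
        # semismooth subgradient of clip: include boundary ties as active
        free = (z >= -1e-12) & (z <= 1.0 + 1e-12)
        J = (A[:, free] @ A[:, free].T) + 1e-10 * np.eye(n_dof)
        try:
            step_dir = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step_dir, *_ = np.linalg.lstsq(J, -r, rcond=None)
        step = 1.0
        while step > 1e-8:
            lam_try = lam + step * step_dir
            z_try = center + A.T @ lam_try
            a_try = np.clip(z_try, 0.0, 1.0)
            r_try = A @ a_try - M
            rn_try = float(np.linalg.norm(r_try))
            if rn_try < rn * (1.0 - 1e-4 * step) or rn_try <= tol:
                lam, z, a, r, rn = lam_try, z_try, a_try, r_try, rn_try
                break
            step *= 0.5
        else:
            return None
    return (a, lam) if rn <= tol else None


def _solution_from_a(
    a: np.ndarray, problem: FrameProblem, status: str
) -> FrameSolution:
    forces = a * problem.f_max
    residual = float(np.linalg.norm(problem.R @ forces - problem.M))
    return FrameSolution(
        forces=forces,
        activations=a,
        objective=float(np.dot(a, a)),
        status=status,
        residual=residual,
    )


def solve_frame(problem: FrameProblem, relax: bool = False) -> FrameSolution:
    """Solve one frame's QP to the global minimum.

    With ``relax=True`` an unattainable moment is projected onto the
    attainable polytope (minimum equality residual) before minimizing the
    objective; the returned status is then ``"solved"`` with a nonzero
    residual.  By default unattainable moments yield status ``"infeasible"``
    and NaN forces.
    """
    A = problem.R * problem.f_max  # column scaling: variables are activations
    M = problem.M

    # fast path: solve the piecewise-linear dual KKT system directly
    newton = _dual_newton(A, M)
    if newton is not None:
        return _solution_from_a(newton[0], problem, "solved")

    a0 = _feasible_point(A, M)
    if a0 is None:
        if not relax:
            n = problem.f_max.size
            return FrameSolution(
                forces=np.full(n, np.nan),
                activations=np.full(n, np.nan),
                objective=np.nan,
                status="infeasible",
                residual=np.nan,
            )
        # minimize ||A a - M|| over the box, then ||a||^2 over that optimum:
        # projected-moment subproblem with the reachable moment target.
        a_ls = _box_least_squares(A, M)
        M_proj = A @ a_ls
        a0 = _feasible_point(A, M_proj)
        if a0 is None:  # numerical edge: accept the least-squares point
            return _solution_from_a(a_ls, problem, "solved")
        a_opt = _min_norm_active_set(A, M_proj, a0)
        # residual reported against the *original* moment target
        return _solution_from_a(a_opt, problem, "solved")

    a_opt = _min_norm_active_set(A, M, a0)
    return _solution_from_a(a_opt, problem, "solved")


def _box_least_squares(A: np.ndarray, M: np.ndarray) -> np.ndarray:
    """min ||A a - M|| over 0 <= a <= 1 (projected gradient, small problems)."""
    from scipy.optimize import lsq_linear

    res = lsq_linear(A, M, bounds=(0.0, 1.0), tol=1e-12)
    return np.clip(res.x, 0.0, 1.0)


def solve_trial(
    model: ModelDefinition,
    moments: JointMomentSeries,
    max_infeasible_frac: float = 0.05,
    relax: bool = False,
) -> MuscleForceSolution:
    """Per-frame static optimization across a moment series.

    Frames are independent; a batched least-squares pass resolves all frames
    whose unconstrained minimum-norm activations are already within bounds,
    and the active-set solver handles the rest.  More than
    ``max_infeasible_frac`` infeasible frames raises
    ``"model too weak for trial"``.
    """
    mam = moment_arm_matrix(model)
    order = [mam.dof_order.index(d) for d in moments.dof_order]
    R = mam.values[order, :]
    f_max = model.f_max
    A = R * f_max
    Mmat = np.asarray(moments.values, dtype=float)
    if not np.all(np.isfinite(Mmat)):
        raise SolverError("moments must be finite over stance")
    n_frames, n_muscles = Mmat.shape[0], f_max.size

    forces = np.full((n_frames, n_muscles), np.nan)
    activations = np.full((n_frames, n_muscles), np.nan)
    objective = np.full(n_frames, np.nan)
    status = np.full(n_frames, "infeasible", dtype=object)
    residual = np.full(n_frames, np.nan)

    # warm-started dual Newton across frames (results are warm-start
    # independent: the converged point is the unique KKT solution)
    lam = None
    for k in range(n_frames):
        newton = _dual_newton(A, Mmat[k], lam0=lam)
        if newton is not None:
            a, lam = newton
            activations[k] = a
            forces[k] = a * f_max
            objective[k] = float(np.dot(a, a))
            residual[k] = float(np.linalg.norm(R @ forces[k] - Mmat[k]))
            status[k] = "solved"
            continue
        lam = None
        sol = solve_frame(FrameProblem(R, Mmat[k], f_max), relax=relax)
        forces[k] = sol.forces
        activations[k] = sol.activations
        objective[k] = sol.objective
        status[k] = sol.status
        residual[k] = sol.residual

    n_bad = int(np.sum(status != "solved"))
    if n_frames and n_bad / n_frames > max_infeasible_frac:
        raise SolverError(
            f"model too weak for trial: {n_bad}/{n_frames} infeasible frames"
        )
    return MuscleForceSolution(
        time=np.asarray(moments.time, dtype=float),
        forces=forces,
        activations=activations,
        objective=objective,
        status=np.asarray(status, dtype=object),
        residual=residual,
        muscle_order=model.muscle_names,
    )
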