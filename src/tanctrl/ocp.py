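"""Pontryagin optimal control of drug infusions via the forward–backward
sweep method (FBSM), with isoperimetric (fixed total dose) constraints.

A subproblem minimises

    J(u) = ∫ [ T(t) + (B1/2)·u_L² + (B2/2)·u_S² ] dt

over box-bounded infusion rates 0 ≤ u_i ≤ u_i_max, subject to the full
TAN dynamics (some states optionally frozen), and optionally to exact
dose budgets ∫u_i dt = A_i.  The budgets are enforced through constant
multipliers θ_i added to the Hamiltonian, determined by an outer secant
iteration (with a bracketing/bisection fallback) on the inner FBSM solve.

The sweep core (:func:`fbsm_sweep`) is generic over the dynamics and cost
callables so that it can be exercised against closed-form linear-quadratic
solutions independent of the tumour model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dynamics import full_jacobian
from .parameters import ModelParameters
from .states import FULL_STATE_NAMES

__all__ = [
    "OCPSpec",
    "OCPSolution",
    "SweepProblem",
    "control_characterization",
    "adjoint_rhs",
    "fbsm_sweep",
    "fbsm_solve",
    "isoperimetric_solve",
    "InfeasibleBudgetError",
]

_IDX = {n: i for i, n in enumerate(FULL_STATE_NAMES)}
#: state whose costate enters each control's characterization
_CONTROL_ENTRY = {"u_L": _IDX["L"], "u_S": _IDX["S"]}
_CONTROL_COL = {"u_L": 0, "u_S": 1}

# default bound factors when a budget is given but no explicit box bound:
# the bound is factor * A / horizon, loose enough that optimal schedules
# stay interior
_BOUND_FACTOR = {"u_L": 5.0, "u_S": 2.0}


class InfeasibleBudgetError(RuntimeError):
    """A dose budget outside the achievable range [0, u_max·(t1−t0)]."""


class ConvergenceError(RuntimeError):
    """An inner FBSM solve failed to converge during the multiplier
    iteration."""


@dataclass
class OCPSpec:
    """One optimal-control subproblem.

    ``frozen_states`` maps state names to constant values that are held
    fixed (never integrated, contributing no costate), e.g. ``{"S": 0.2}``
    for the TGF-β-inhibitor-only scenario.
    """

    initial_state: np.ndarray
    horizon: tuple[float, float] = (0.0, 1.0)
    active_controls: tuple[str, ...] = ("u_L",)
    B1: float = 1.0
    B2: float = 1.0
    A1: float | None = None
    A2: float | None = None
    u_L_max: float | None = None
    u_S_max: float | None = None
    frozen_states: dict[str, float] = field(default_factory=dict)
    step: float = 0.01
    relaxation: float = 0.5
    tolerance: float = 1e-6
    max_iter: int = 500

    def __post_init__(self) -> None:
        self.initial_state = np.asarray(self.initial_state, float)
        if self.initial_state.shape != (6,):
            raise ValueError("initial_state must have 6 components (L, G, C, S, I, T)")
        for c in self.active_controls:
            if c not in _CONTROL_ENTRY:
                raise ValueError(f"unknown control {c!r}")
        for s in self.frozen_states:
            if s not in _IDX:
                raise ValueError(f"unknown frozen state {s!r}")
        t0, t1 = self.horizon
        if not t1 > t0:
            raise ValueError("degenerate horizon")
        span = t1 - t0
        if self.u_L_max is None:
            self.u_L_max = _BOUND_FACTOR["u_L"] * self.A1 / span if self.A1 else np.inf
        if self.u_S_max is None:
            self.u_S_max = _BOUND_FACTOR["u_S"] * self.A2 / span if self.A2 else np.inf
        for name, A, hi in (("A1", self.A1, self.u_L_max), ("A2", self.A2, self.u_S_max)):
            if A is not None and not (0.0 <= A <= hi * span + 1e-9):
                raise InfeasibleBudgetError(
                    f"{name}={A} outside feasible dose range [0, {hi * span}]"
                )

    def bound(self, control: str) -> float:
        return self.u_L_max if control == "u_L" else self.u_S_max

    def weight(self, control: str) -> float:
        return self.B1 if control == "u_L" else self.B2

    def budget(self, control: str) -> float | None:
        return self.A1 if control == "u_L" else self.A2

    @property
    def frozen_mask(self) -> np.ndarray:
        m = np.zeros(6, bool)
        for s in self.frozen_states:
            m[_IDX[s]] = True
        return m

    def resolved_initial_state(self) -> np.ndarray:
        x0 = self.initial_state.copy()
        for s, v in self.frozen_states.items():
            x0[_IDX[s]] = v
        return x0


@dataclass
class OCPSolution:
    """Converged control/state/adjoint trajectories of one subproblem."""

    t: np.ndarray
    controls: np.ndarray  # (n, 2) columns u_L, u_S
    states: np.ndarray  # (n, 6)
    adjoints: np.ndarray  # (n, 6); frozen rows identically zero
    theta: tuple[float, float]
    objective: float
    doses: tuple[float, float]
    dose_residuals: tuple[float, float]
    iterations: int
    converged: bool
    spec: OCPSpec

    def pontryagin_residual(self) -> np.ndarray:
        """Projected gradient |∂H/∂u| per grid point and active control:
        zero at interior stationary points, clipped to the feasible sign
        at active box bounds."""
        out = []
        for c in self.spec.active_controls:
            col = _CONTROL_COL[c]
            u = self.controls[:, col]
            p = self.adjoints[:, _CONTROL_ENTRY[c]]
            th = self.theta[col]
            grad = self.spec.weight(c) * u + p + th
            hi = self.spec.bound(c)
            res = np.abs(grad)
            res[(u <= 1e-12) & (grad > 0)] = 0.0  # lower bound active, pushing down
            res[(u >= hi - 1e-12) & (grad < 0)] = 0.0  # upper bound active, pushing up
            out.append(res)
        return np.column_stack(out)


def control_characterization(
    costate: float | np.ndarray, theta: float, B: float, u_max: float
) -> float | np.ndarray:
    """Optimal control from the Hamiltonian stationarity condition,
    projected onto the admissible box: clip(−(costate + θ)/B, 0, u_max)."""
    if B <= 0:
        raise ValueError("B must be > 0 (bang-bang control is unsupported)")
    return np.clip(-(np.asarray(costate, float) + theta) / B, 0.0, u_max)


def adjoint_rhs(
    state: np.ndarray,
    adjoint: np.ndarray,
    u_L: float,
    u_S: float,
    params: ModelParameters,
    spec: OCPSpec,
    theta: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Costate derivatives −∂H/∂x for the full system.

    H = T + (B1/2)u_L² + (B2/2)u_S² + θ1·u_L + θ2·u_S + Σ λ_x f_x.
    Frozen states contribute no costate; their rows are zero.
    """
    x = np.asarray(state, float)
    p = np.asarray(adjoint, float)
    J = full_jacobian(x, params)
    mask = spec.frozen_mask
    J[mask, :] = 0.0  # frozen states have no dynamics
    gx = np.zeros(6)
    gx[_IDX["T"]] = 1.0
    dp = -(gx + J.T @ p)
    dp[mask] = 0.0
    return dp


# ---------------------------------------------------------------------------
# generic sweep core
# ---------------------------------------------------------------------------


@dataclass
class SweepProblem:
    """Callable bundle defining one FBSM problem on an arbitrary system.

    f(x, u) -> dx; fx(x, u) -> ∂f/∂x; g(x, u) -> running cost;
    gx(x) -> ∂g/∂x; ustar(p) -> control from the costate vector.
    """

    n_x: int
    n_u: int
    f: Callable[[np.ndarray, np.ndarray], np.ndarray]
    fx: Callable[[np.ndarray, np.ndarray], np.ndarray]
    g: Callable[[np.ndarray, np.ndarray], float]
    gx: Callable[[np.ndarray], np.ndarray]
    ustar: Callable[[np.ndarray], np.ndarray]
    nonneg: bool = True  # clip forward states at zero (biological densities)
    ustar_grid: Callable[[np.ndarray], np.ndarray] | None = None  # vectorized over the grid


def _forward(problem: SweepProblem, x0: np.ndarray, U: np.ndarray, h: float) -> np.ndarray:
    n = len(U) - 1
    X = np.empty((n + 1, problem.n_x))
    X[0] = x0
    x = x0.astype(float)
    f = problem.f
    for i in range(n):
        u0, u1 = U[i], U[i + 1]
        um = 0.5 * (u0 + u1)
        k1 = f(x, u0)
        k2 = f(x + 0.5 * h * k1, um)
        k3 = f(x + 0.5 * h * k2, um)
        k4 = f(x + h * k3, u1)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if problem.nonneg:
            x = np.where(x < 0, 0.0, x)
        X[i + 1] = x
    return X


def _backward(problem: SweepProblem, X: np.ndarray, U: np.ndarray, h: float) -> np.ndarray:
    n = len(U) - 1
    P = np.zeros((n + 1, problem.n_x))
    p = np.zeros(problem.n_x)
    fx, gx = problem.fx, problem.gx

    def pdot(x, u, p):
        return -(gx(x) + fx(x, u).T @ p)

    for i in range(n, 0, -1):
        x1, x0 = X[i], X[i - 1]
        xm = 0.5 * (x0 + x1)
        u1, u0 = U[i], U[i - 1]
        um = 0.5 * (u0 + u1)
        k1 = pdot(x1, u1, p)
        k2 = pdot(xm, um, p - 0.5 * h * k1)
        k3 = pdot(xm, um, p - 0.5 * h * k2)
        k4 = pdot(x0, u0, p - h * k3)
        p = p - (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        P[i - 1] = p
    return P


def fbsm_sweep(
    problem: SweepProblem,
    t: np.ndarray,
    x0: np.ndarray,
    u0: np.ndarray | None = None,
    relaxation: float = 0.5,
    tolerance: float = 1e-6,
    max_iter: int = 500,
):
    """Iterate forward state / backward adjoint sweeps with relaxed
    control updates until the relative sup-norm change of the control
    drops below ``tolerance``.

    Returns ``(U, X, P, objective_history, iterations, converged)``.
    """
    h = float(t[1] - t[0])
    U = np.zeros((len(t), problem.n_u)) if u0 is None else np.array(u0, float)
    J_hist: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        X = _forward(problem, x0, U, h)
        P = _backward(problem, X, U, h)
        running = np.array([problem.g(X[i], U[i]) for i in range(len(t))])
        J_hist.append(float(np.trapezoid(running, dx=h)))
        if problem.ustar_grid is not None:
            U_char = problem.ustar_grid(P)
        else:
            U_char = np.apply_along_axis(problem.ustar, 1, P)
        U_new = (1.0 - relaxation) * U + relaxation * U_char
        delta = np.max(np.abs(U_new - U)) / max(float(np.max(np.abs(U_new))), 1e-12)
        U = U_new
        if delta < tolerance:
            converged = True
            break
    return U, X, P, J_hist, it, converged


# ---------------------------------------------------------------------------
# model-specific solvers
# ---------------------------------------------------------------------------


def _model_problem(spec: OCPSpec, params: ModelParameters, theta: tuple[float, float]) -> SweepProblem:
    # rhs/Jacobian are inlined (no validation, minimal allocation): they sit
    # in the innermost RK4 loops of every sweep
    mask = spec.frozen_mask
    iT = _IDX["T"]
    active = spec.active_controls
    uLmax, uSmax = spec.bound("u_L"), spec.bound("u_S")
    B1, B2 = spec.B1, spec.B2
    th1, th2 = theta
    iL, iS = _IDX["L"], _IDX["S"]
    p = params
    lam, lamG, lamS = p.lambda_il6, p.lambda_G, p.lambda_S
    k1, k2, k32, k42 = p.k1, p.k2, p.k3**2, p.k4**2
    al, be, mu = p.alpha, p.beta, p.mu
    r, K, g1, T0, de = p.r, p.K, p.gamma1, p.T0, p.delta
    GS, muG, gL, muL, muS = p.GS, p.mu_G, p.gamma_L, p.mu_L, p.mu_S
    keep = (~mask).astype(float)

    def f(x, u):
        L, G, C, S, I, T = x
        gfac = K + g1 * I
        logi = 1.0 - T / T0
        dx = np.array(
            [
                u[0] - muL * L,
                GS - muG * G - gL * L * G,
                lam + lamG * G + k1 / (k32 + al * I * I) - C,
                u[1] - muS * S,
                lamS * S + k2 / (k42 + be * C * C) - mu * I,
                r * (1.0 + C / gfac) * T * logi - de * I * T,
            ]
        )
        return dx * keep

    def fx(x, u):
        L, G, C, S, I, T = x
        J = np.zeros((6, 6))
        J[0, 0] = -muL
        J[1, 0] = -gL * G
        J[1, 1] = -muG - gL * L
        J[2, 1] = lamG
        J[2, 2] = -1.0
        dI2 = k32 + al * I * I
        J[2, 4] = -2.0 * al * I * k1 / (dI2 * dI2)
        J[3, 3] = -muS
        dC2 = k42 + be * C * C
        J[4, 2] = -2.0 * be * C * k2 / (dC2 * dC2)
        J[4, 3] = lamS
        J[4, 4] = -mu
        gfac = K + g1 * I
        logi = 1.0 - T / T0
        J[5, 2] = r * T * logi / gfac
        J[5, 4] = -r * C * T * logi * g1 / (gfac * gfac) - de * T
        J[5, 5] = r * (1.0 + C / gfac) * (1.0 - 2.0 * T / T0) - de * I
        J[mask, :] = 0.0
        return J

    def g(x, u):
        cost = x[iT]
        if "u_L" in active:
            cost += 0.5 * B1 * u[0] ** 2 + th1 * u[0]
        if "u_S" in active:
            cost += 0.5 * B2 * u[1] ** 2 + th2 * u[1]
        return cost

    gxv = np.zeros(6)
    gxv[iT] = 1.0

    def gx(x):
        return gxv

    def ustar(p_):
        u = np.zeros(2)
        if "u_L" in active:
            u[0] = control_characterization(p_[iL], th1, B1, uLmax)
        if "u_S" in active:
            u[1] = control_characterization(p_[iS], th2, B2, uSmax)
        return u

    def ustar_grid(P):
        U = np.zeros((len(P), 2))
        if "u_L" in active:
            U[:, 0] = np.clip(-(P[:, iL] + th1) / B1, 0.0, uLmax)
        if "u_S" in active:
            U[:, 1] = np.clip(-(P[:, iS] + th2) / B2, 0.0, uSmax)
        return U

    return SweepProblem(
        n_x=6, n_u=2, f=f, fx=fx, g=g, gx=gx, ustar=ustar, ustar_grid=ustar_grid
    )


def _grid(spec: OCPSpec) -> np.ndarray:
    t0, t1 = spec.horizon
    n = max(1, round((t1 - t0) / spec.step))
    return t0 + (t1 - t0) / n * np.arange(n + 1)


def fbsm_solve(
    spec: OCPSpec,
    params: ModelParameters,
    theta: tuple[float, float] = (0.0, 0.0),
    u0: np.ndarray | None = None,
) -> OCPSolution:
    """Solve one subproblem at fixed multipliers θ by FBSM."""
    t = _grid(spec)
    problem = _model_problem(spec, params, theta)
    x0 = spec.resolved_initial_state()
    U, X, P, J_hist, it, conv = fbsm_sweep(
        problem,
        t,
        x0,
        u0=u0,
        relaxation=spec.relaxation,
        tolerance=spec.tolerance,
        max_iter=spec.max_iter,
    )
    h = t[1] - t[0]
    doses = (float(np.trapezoid(U[:, 0], dx=h)), float(np.trapezoid(U[:, 1], dx=h)))
    resid = tuple(
        abs(doses[i] - A) if A is not None else 0.0
        for i, A in enumerate((spec.A1, spec.A2))
    )
    # objective without the multiplier terms (θ is internal bookkeeping)
    running = X[:, _IDX["T"]].copy()
    if "u_L" in spec.active_controls:
        running = running + 0.5 * spec.B1 * U[:, 0] ** 2
    if "u_S" in spec.active_controls:
        running = running + 0.5 * spec.B2 * U[:, 1] ** 2
    J = float(np.trapezoid(running, dx=h))
    return OCPSolution(
        t=t,
        controls=U,
        states=X,
        adjoints=P,
        theta=theta,
        objective=J,
        doses=doses,
        dose_residuals=resid,
        iterations=it,
        converged=conv,
        spec=spec,
    )


def _solve_theta(
    spec: OCPSpec,
    params: ModelParameters,
    control: str,
    theta: list[float],
    theta_guess: float,
    dose_tol: float,
    u_warm: np.ndarray | None = None,
):
    """Secant iteration (brentq fallback) on one multiplier so that the
    budget residual of the inner FBSM solve vanishes."""
    col = _CONTROL_COL[control]
    A = spec.budget(control)
    span = spec.horizon[1] - spec.horizon[0]
    hi = spec.bound(control)
    B = spec.weight(control)

    cache: dict = {}
    if u_warm is not None:
        cache["u"] = u_warm

    def residual(th: float) -> float:
        theta[col] = th
        sol = fbsm_solve(spec, params, tuple(theta), u0=cache.get("u"))
        if not sol.converged:
            raise ConvergenceError(
                f"inner FBSM did not converge in {sol.iterations} iterations "
                f"at theta[{control}]={th:.4g}"
            )
        cache["u"] = sol.controls
        cache[th] = sol
        return sol.doses[col] - A

    def solve_checked(th: float) -> OCPSolution:
        theta[col] = th
        sol = fbsm_solve(spec, params, tuple(theta))
        if not sol.converged:
            raise ConvergenceError(
                f"inner FBSM did not converge in {sol.iterations} iterations "
                f"at theta[{control}]={th:.4g}"
            )
        return sol

    # saturated / empty budgets have closed-form multipliers
    if A <= dose_tol:
        sol = solve_checked(theta[col])
        th = float(np.max(-sol.adjoints[:, _CONTROL_ENTRY[control]])) + 1.0
        return solve_checked(th), th
    if A >= hi * span - dose_tol:
        sol = solve_checked(theta[col])
        th = float(np.min(-sol.adjoints[:, _CONTROL_ENTRY[control]])) - B * hi - 1.0
        return solve_checked(th), th

    # secant step from the warm-started guess; the residual is monotone
    # non-increasing and ~linear in theta on the interior, so this usually
    # lands within tolerance in 2-3 inner solves
    t0_ = theta_guess
    r0 = residual(t0_)
    if abs(r0) <= dose_tol:
        return cache[t0_], t0_
    t1_ = t0_ - np.sign(r0) * max(0.25 * B * abs(r0) / span, 1e-3)
    r1 = residual(t1_)
    for _ in range(20):
        if abs(r1) <= dose_tol:
            return cache[t1_], t1_
        if r1 == r0 or not np.isfinite(r1 - r0):
            break
        t2 = t1_ - r1 * (t1_ - t0_) / (r1 - r0)
        if not np.isfinite(t2) or abs(t2 - t1_) > 10.0 * (abs(t1_) + B * hi + 1.0):
            break  # degenerate secant (dose pinned at a bound); bisect instead
        t0_, r0, t1_ = t1_, r1, t2
        r1 = residual(t1_)

    # fallback: expand a bracket, then bisection-safe root finding
    lo_th, hi_th = min(t0_, t1_), max(t0_, t1_)
    r_lo, r_hi = residual(lo_th), residual(hi_th)
    width = max(1.0, B * A / span)
    for _ in range(80):
        if r_lo > 0:
            break
        lo_th -= width
        width *= 2.0
        r_lo = residual(lo_th)
    width = max(1.0, B * A / span)
    for _ in range(80):
        if r_hi < 0:
            break
        hi_th += width
        width *= 2.0
        r_hi = residual(hi_th)
    if abs(r_lo) <= dose_tol:
        return cache[lo_th], lo_th
    if abs(r_hi) <= dose_tol:
        return cache[hi_th], hi_th
    if not (r_lo > 0 > r_hi):
        raise InfeasibleBudgetError(
            f"budget A={A} for {control} not bracketable; achievable dose range "
            f"≈ [{max(0.0, A + r_hi):.4g}, {A + r_lo:.4g}]"
        )
    from scipy.optimize import brentq

    th = float(brentq(residual, lo_th, hi_th, xtol=1e-10, rtol=1e-12))
    if th not in cache or abs(cache[th].doses[col] - A) > dose_tol:
        residual(th)
    return cache[th], th


def isoperimetric_solve(
    spec: OCPSpec,
    params: ModelParameters,
    theta_guess: tuple[float, float] = (0.0, 0.0),
    dose_tol: float = 1e-5,
    max_outer: int = 10,
    u_warm: np.ndarray | None = None,
) -> OCPSolution:
    """Solve a budgeted subproblem: for each active control with a dose
    budget, the constant multiplier θ is driven so that ∫u dt = A.

    With two budgeted controls the multipliers are relaxed alternately
    (block-coordinate secant); the cross-coupling through the state is
    weak, so a few outer cycles suffice.
    """
    budgeted = [c for c in spec.active_controls if spec.budget(c) is not None]
    theta = [0.0, 0.0]
    for c in spec.active_controls:
        theta[_CONTROL_COL[c]] = theta_guess[_CONTROL_COL[c]]
    if not budgeted:
        return fbsm_solve(spec, params, tuple(theta))

    sol = None
    for _outer in range(max_outer):
        for c in budgeted:
            sol, th = _solve_theta(
                spec, params, c, theta, theta[_CONTROL_COL[c]], dose_tol, u_warm=u_warm
            )
            theta[_CONTROL_COL[c]] = th
            u_warm = sol.controls
        ok = all(
            sol.dose_residuals[_CONTROL_COL[c]] <= max(dose_tol, 1e-4) for c in budgeted
        )
        if ok:
            break
    return sol
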