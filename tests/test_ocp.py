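"""Forward–backward sweep solver: characterization, adjoints, convergence
and the isoperimetric outer iteration.

Closed-form linear-quadratic problems serve as independent oracles for
the sweep core; finite differences of the Hamiltonian and of the
objective validate the model-specific adjoint field and search direction.
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from tanctrl import (
    ModelParameters,
    OCPSpec,
    adjoint_rhs,
    control_characterization,
    fbsm_solve,
    isoperimetric_solve,
)
from tanctrl.ocp import InfeasibleBudgetError, SweepProblem, fbsm_sweep


@pytest.fixture(scope="module")
def q4_state():
    # high-risk start under the inhibitor-only scenario, S frozen at 0.2
    return np.array([0.0, 1.0, 4.0, 0.2, 0.3, 10.0])


@pytest.fixture(scope="module")
def inhibitor_spec(q4_state):
    return OCPSpec(
        initial_state=q4_state,
        horizon=(0.0, 1.0),
        active_controls=("u_L",),
        A1=1.0,
        frozen_states={"S": 0.2},
    )


class TestCharacterization:
    @pytest.mark.parametrize(
        "costate,expected", [(-2.0, 2.0), (3.0, 0.0), (-10.0, 5.0)]
    )
    def test_interior_and_projected_points(self, costate, expected):
        assert control_characterization(costate, theta=0.0, B=1.0, u_max=5.0) == expected

    def test_bang_bang_unsupported(self):
        with pytest.raises(ValueError):
            control_characterization(-1.0, 0.0, B=0.0, u_max=5.0)


class TestAdjointField:
    def test_zero_costates_leave_only_running_cost(self, params, inhibitor_spec):
        dp = adjoint_rhs(
            np.array([0.1, 0.5, 2.0, 0.2, 1.0, 10.0]),
            np.zeros(6), 0.5, 0.0, params, inhibitor_spec,
        )
        # only the tumour component of the running cost survives
        np.testing.assert_array_equal(dp[:5], 0.0)
        assert dp[5] == -1.0

    def test_matches_finite_differences_of_hamiltonian(self, params, rng):
        """-dH/dx from the analytic Jacobian vs central differences of
        H = T + (B/2)u² + θ·u + Σ λ·f on 100 random points."""
        spec = OCPSpec(
            initial_state=np.zeros(6),
            horizon=(0.0, 1.0),
            active_controls=("u_L", "u_S"),
        )
        from tanctrl.dynamics import full_rhs

        def hamiltonian(x, p, uL, uS, theta):
            return (
                x[5]
                + 0.5 * (uL**2 + uS**2)
                + theta[0] * uL
                + theta[1] * uS
                + p @ full_rhs(x, uL, uS, params)
            )

        h = 1e-6
        for _ in range(100):
            x = rng.uniform(0.05, 3.0, 6)
            p = rng.uniform(-2.0, 2.0, 6)
            uL, uS = rng.uniform(0, 2, 2)
            theta = tuple(rng.uniform(-1, 1, 2))
            dp = adjoint_rhs(x, p, uL, uS, params, spec, theta)
            for j in range(6):
                e = np.zeros(6)
                e[j] = h
                fd = -(
                    hamiltonian(x + e, p, uL, uS, theta)
                    - hamiltonian(x - e, p, uL, uS, theta)
                ) / (2 * h)
                assert dp[j] == pytest.approx(fd, rel=1e-6, abs=1e-7)

    def test_inhibitor_costate_couples_through_tgfb_degradation(self, params):
        """The L-equation of the adjoint field carries the +λ_G·γ_L·G and
        +λ_L·μ_L terms of -dH/dL (checked symbolically)."""
        import sympy as sp

        L, G = sp.symbols("L G", positive=True)
        lam_L, lam_G = sp.symbols("lam_L lam_G")
        H_L_terms = lam_L * (-params.mu_L * L) + lam_G * (-params.gamma_L * L * G)
        minus_dH_dL = sp.expand(-sp.diff(H_L_terms, L))
        expected = lam_L * params.mu_L + lam_G * params.gamma_L * G
        assert sp.simplify(minus_dH_dL - expected) == 0
        spec = OCPSpec(initial_state=np.zeros(6), horizon=(0, 1), active_controls=("u_L",))
        x = np.array([0.3, 0.7, 1.0, 0.2, 1.0, 10.0])
        p = np.array([2.0, -1.5, 0.0, 0.0, 0.0, 0.0])
        dp = adjoint_rhs(x, p, 0.0, 0.0, params, spec)
        assert dp[0] == pytest.approx(2.0 * params.mu_L + (-1.5) * params.gamma_L * 0.7)


def _lq_riccati_problem():
    """min ∫₀¹ (x² + u²/2) dt, dx/dt = u, x(0)=1: the Riccati solution is
    P(t)=√2·tanh(√2(1−t)), x(t)=cosh(√2(1−t))/cosh(√2), u=−P·x."""
    return SweepProblem(
        n_x=1,
        n_u=1,
        f=lambda x, u: np.array([u[0]]),
        fx=lambda x, u: np.zeros((1, 1)),
        g=lambda x, u: x[0] ** 2 + 0.5 * u[0] ** 2,
        gx=lambda x: np.array([2.0 * x[0]]),
        ustar=lambda p: np.array([-p[0]]),
        nonneg=False,
    )


class TestSweepCore:
    def test_lq_control_matches_riccati_closed_form(self):
        t = np.linspace(0, 1, 201)
        U, X, P, J_hist, it, conv = fbsm_sweep(
            _lq_riccati_problem(), t, np.array([1.0]), tolerance=1e-10, max_iter=2000
        )
        assert conv
        s2 = np.sqrt(2.0)
        x_exact = np.cosh(s2 * (1 - t)) / np.cosh(s2)
        u_exact = -s2 * np.tanh(s2 * (1 - t)) * x_exact
        assert np.abs(U[:, 0] - u_exact).max() <= 1e-3
        assert np.abs(X[:, 0] - x_exact).max() <= 1e-3

    def test_lq_isoperimetric_matches_lagrange_closed_form(self):
        """min ∫₀¹ (x + u²/2) dt, dx/dt = u, x(0)=0, ∫u dt = 1: the
        stationarity condition u = −(p+θ) with p = 1−t gives
        u(t) = t + 1/2 at θ = −3/2."""
        t = np.linspace(0, 1, 201)

        def make(theta):
            return SweepProblem(
                n_x=1,
                n_u=1,
                f=lambda x, u: np.array([u[0]]),
                fx=lambda x, u: np.zeros((1, 1)),
                g=lambda x, u: x[0] + 0.5 * u[0] ** 2 + theta * u[0],
                gx=lambda x: np.array([1.0]),
                ustar=lambda p: np.array([-(p[0] + theta)]),
                nonneg=False,
            )

        def dose_residual(theta):
            U, *_ = fbsm_sweep(make(theta), t, np.array([0.0]), tolerance=1e-10, max_iter=2000)
            return np.trapezoid(U[:, 0], t) - 1.0

        theta = brentq(dose_residual, -5.0, 5.0, xtol=1e-12)
        assert theta == pytest.approx(-1.5, abs=1e-4)
        U, *_ = fbsm_sweep(make(theta), t, np.array([0.0]), tolerance=1e-10, max_iter=2000)
        assert np.abs(U[:, 0] - (t + 0.5)).max() <= 1e-3

    def test_objective_descends_monotonically(self, params, inhibitor_spec):
        sol = fbsm_solve(inhibitor_spec, params, theta=(-1.0, 0.0))
        # recompute the history from a fresh solve via the history list
        from tanctrl.ocp import _grid, _model_problem

        t = _grid(inhibitor_spec)
        problem = _model_problem(inhibitor_spec, params, (-1.0, 0.0))
        _, _, _, J_hist, _, conv = fbsm_sweep(
            problem, t, inhibitor_spec.resolved_initial_state(),
            relaxation=inhibitor_spec.relaxation,
        )
        assert conv
        diffs = np.diff(J_hist)
        assert (diffs <= 1e-8).all()

    def test_pure_control_cost_gives_zero_control(self, params, q4_state):
        # no dose budget: the only incentive on u_L is its quadratic cost,
        # and the tumour term cannot be reduced enough within a day to
        # overcome it at B=1... verified: control collapses to ~0
        spec = OCPSpec(
            initial_state=q4_state, horizon=(0.0, 1.0),
            active_controls=("u_L",), u_L_max=5.0, frozen_states={"S": 0.2},
        )
        p = params.replace(delta=0.0, r=1e-12)  # tumour insensitive to treatment
        sol = fbsm_solve(spec, p)
        assert sol.converged
        assert np.abs(sol.controls).max() <= 1e-6

    def test_heavier_cost_weight_shrinks_unbudgeted_dose(self, params, q4_state):
        doses = []
        for B1 in (0.5, 1.0, 2.0, 4.0):
            spec = OCPSpec(
                initial_state=q4_state, horizon=(0.0, 1.0),
                active_controls=("u_L",), u_L_max=5.0, B1=B1,
                frozen_states={"S": 0.2},
            )
            sol = fbsm_solve(spec, params)
            assert sol.converged
            doses.append(sol.doses[0])
        assert all(a >= b - 1e-12 for a, b in zip(doses, doses[1:]))

    def test_search_direction_matches_objective_gradient(self, params, inhibitor_spec, rng):
        """Directional derivatives of J from the adjoint-based gradient
        B·u + λ_L vs central finite differences of J, cosine similarity
        over 20 random perturbation directions."""
        from tanctrl.ocp import _grid, _model_problem

        spec = OCPSpec(
            initial_state=inhibitor_spec.initial_state, horizon=(0.0, 1.0),
            active_controls=("u_L",), u_L_max=10.0, frozen_states={"S": 0.2},
        )
        t = _grid(spec)
        problem = _model_problem(spec, params, (0.0, 0.0))
        from tanctrl.ocp import _backward, _forward

        h = t[1] - t[0]
        U0 = np.column_stack([1.0 + 0.5 * np.sin(2 * np.pi * t), np.zeros_like(t)])

        def J(U):
            X = _forward(problem, spec.resolved_initial_state(), U, h)
            g = np.array([problem.g(X[i], U[i]) for i in range(len(t))])
            return np.trapezoid(g, dx=h)

        X0 = _forward(problem, spec.resolved_initial_state(), U0, h)
        P0 = _backward(problem, X0, U0, h)
        grad = spec.B1 * U0[:, 0] + P0[:, 0]  # dH/du_L along the trajectory

        analytic, numeric = [], []
        eps = 1e-5
        for _ in range(20):
            d = rng.standard_normal(len(t))
            dU = np.column_stack([d, np.zeros_like(d)])
            analytic.append(np.trapezoid(grad * d, dx=h))
            numeric.append((J(U0 + eps * dU) - J(U0 - eps * dU)) / (2 * eps))
        analytic, numeric = np.array(analytic), np.array(numeric)
        cosine = analytic @ numeric / (np.linalg.norm(analytic) * np.linalg.norm(numeric))
        assert cosine > 0.99


class TestIsoperimetric:
    def test_budget_met_with_interior_control(self, params, inhibitor_spec):
        sol = isoperimetric_solve(inhibitor_spec, params)
        assert sol.converged
        assert sol.dose_residuals[0] <= 1e-4
        u = sol.controls[:, 0]
        assert 0.0 < u.min() and u.max() < inhibitor_spec.u_L_max

    def test_pontryagin_residual_at_convergence(self, params, inhibitor_spec):
        sol = isoperimetric_solve(inhibitor_spec, params)
        res = sol.pontryagin_residual()
        assert np.mean(res <= 1e-4) >= 0.99

    def test_zero_budget_gives_zero_control(self, params, q4_state):
        spec = OCPSpec(
            initial_state=q4_state, horizon=(0.0, 1.0),
            active_controls=("u_L",), A1=0.0, u_L_max=5.0,
            frozen_states={"S": 0.2},
        )
        sol = isoperimetric_solve(spec, params)
        np.testing.assert_array_equal(sol.controls[:, 0], 0.0)
        # the multiplier pushes the characterization onto the lower bound
        assert (-(sol.adjoints[:, 0] + sol.theta[0]) <= 0).all()

    def test_full_budget_saturates_control(self, params, q4_state):
        spec = OCPSpec(
            initial_state=q4_state, horizon=(0.0, 1.0),
            active_controls=("u_L",), A1=5.0, u_L_max=5.0,
            frozen_states={"S": 0.2},
        )
        sol = isoperimetric_solve(spec, params)
        # the relaxed update approaches the bound geometrically down to
        # the sweep's own convergence tolerance
        np.testing.assert_allclose(sol.controls[:, 0], 5.0, rtol=1e-5)

    def test_infeasible_budget_rejected(self, q4_state):
        with pytest.raises(InfeasibleBudgetError):
            OCPSpec(
                initial_state=q4_state, horizon=(0.0, 1.0),
                active_controls=("u_L",), A1=6.0, u_L_max=5.0,
            )

    def test_two_budgeted_controls(self, params, q4_state):
        spec = OCPSpec(
            initial_state=q4_state, horizon=(0.0, 1.0),
            active_controls=("u_L", "u_S"), A1=1.0, A2=2.0,
        )
        sol = isoperimetric_solve(spec, params)
        assert sol.converged
        assert max(sol.dose_residuals) <= 1e-4
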