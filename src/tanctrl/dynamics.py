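"""Right-hand sides, Jacobians and the fixed-step trajectory integrator.

The reduced system tracks the fast C–I phenotype switch (with the tumour
slaved to it); the full system adds the pharmacokinetics of the TGF-β
inhibitor (L), TGF-β (G) and IFN-β (S) together with the two infusion
controls.  A classical fixed-step RK4 scheme is used throughout so that
forward state sweeps and backward adjoint sweeps share an identical grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ModelParameters
from .states import FULL_STATE_NAMES, ControlSignal, FullState, ReducedState

__all__ = [
    "reduced_rhs",
    "full_rhs",
    "reduced_jacobian",
    "full_jacobian",
    "integrate_trajectory",
    "Trajectory",
    "IntegrationFailure",
]

#: tolerated negative undershoot of one RK4 step before it is treated as
#: a sign of an unstable step size
UNDERSHOOT_TOL = 1e-9


class IntegrationFailure(RuntimeError):
    """Raised when a trajectory leaves the admissible region (non-finite
    state or negative undershoot beyond tolerance)."""


def _validate(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"invalid state: non-finite components in {x!r}")


def reduced_rhs(
    state: ReducedState | np.ndarray,
    G: float,
    S: float,
    params: ModelParameters,
) -> np.ndarray:
    """Time derivatives (dC/dt, dI/dt, dT/dt) of the reduced system.

    dC/dt = λ + λG·G + k1/(k3² + α·I²) − C
    dI/dt = λS·S + k2/(k4² + β·C²) − μ·I
    dT/dt = r·(1 + C/(K + γ1·I))·T·(1 − T/T0) − δ·I·T
    """
    x = state.as_array() if isinstance(state, ReducedState) else np.asarray(state, float)
    _validate(x)
    if not (np.isfinite(G) and np.isfinite(S)):
        raise ValueError(f"signals G={G}, S={S} must be finite")
    C, I, T = x
    p = params
    dC = p.lambda_il6 + p.lambda_G * G + p.k1 / (p.k3**2 + p.alpha * I**2) - C
    dI = p.lambda_S * S + p.k2 / (p.k4**2 + p.beta * C**2) - p.mu * I
    dT = p.r * (1.0 + C / (p.K + p.gamma1 * I)) * T * (1.0 - T / p.T0) - p.delta * I * T
    return np.array([dC, dI, dT])


def full_rhs(
    state: FullState | np.ndarray,
    u_L: float,
    u_S: float,
    params: ModelParameters,
    u_L_max: float = np.inf,
    u_S_max: float = np.inf,
) -> np.ndarray:
    """Time derivatives of the full controlled system (L, G, C, S, I, T)."""
    x = state.as_array() if isinstance(state, FullState) else np.asarray(state, float)
    _validate(x)
    for name, u, hi in (("u_L", u_L, u_L_max), ("u_S", u_S, u_S_max)):
        if not np.isfinite(u) or u < -1e-12 or u > hi + 1e-12:
            raise ValueError(f"control {name}={u} outside bounds [0, {hi}]")
    L, G, C, S, I, T = x
    p = params
    dL = u_L - p.mu_L * L
    dG = p.GS - p.mu_G * G - p.gamma_L * L * G
    dS = u_S - p.mu_S * S
    dC, dI, dT = reduced_rhs(np.array([C, I, T]), G, S, params)
    return np.array([dL, dG, dC, dS, dI, dT])


def reduced_jacobian(
    state: ReducedState | np.ndarray, params: ModelParameters
) -> np.ndarray:
    """2×2 Jacobian of the (dC/dt, dI/dt) field with respect to (C, I).

    G and S enter the C and I equations additively, so the C–I Jacobian is
    independent of them.
    """
    x = state.as_array() if isinstance(state, ReducedState) else np.asarray(state, float)
    _validate(x)
    C, I = x[0], x[1]
    p = params
    dCdC = -1.0
    dCdI = -2.0 * p.alpha * I * p.k1 / (p.k3**2 + p.alpha * I**2) ** 2
    dIdC = -2.0 * p.beta * C * p.k2 / (p.k4**2 + p.beta * C**2) ** 2
    dIdI = -p.mu
    return np.array([[dCdC, dCdI], [dIdC, dIdI]])


def full_jacobian(x: np.ndarray, params: ModelParameters) -> np.ndarray:
    """6×6 Jacobian ∂f/∂x of the full system at state ``x`` (controls are
    additive and do not enter).  State order is (L, G, C, S, I, T)."""
    L, G, C, S, I, T = np.asarray(x, float)
    p = params
    J = np.zeros((6, 6))
    J[0, 0] = -p.mu_L
    J[1, 0] = -p.gamma_L * G
    J[1, 1] = -p.mu_G - p.gamma_L * L
    J[2, 1] = p.lambda_G
    J[2, 2] = -1.0
    J[2, 4] = -2.0 * p.alpha * I * p.k1 / (p.k3**2 + p.alpha * I**2) ** 2
    J[3, 3] = -p.mu_S
    J[4, 2] = -2.0 * p.beta * C * p.k2 / (p.k4**2 + p.beta * C**2) ** 2
    J[4, 3] = p.lambda_S
    J[4, 4] = -p.mu
    gfac = p.K + p.gamma1 * I
    logi = 1.0 - T / p.T0
    J[5, 2] = p.r * T * logi / gfac
    J[5, 4] = -p.r * C * T * logi * p.gamma1 / gfac**2 - p.delta * T
    J[5, 5] = p.r * (1.0 + C / gfac) * (1.0 - 2.0 * T / p.T0) - p.delta * I
    return J


@dataclass
class Trajectory:
    """A fixed-step trajectory on a uniform time grid."""

    t: np.ndarray
    states: np.ndarray  # (n, d)
    names: tuple[str, ...]
    controls: np.ndarray | None = None  # (n, 2) columns u_L, u_S
    clip_events: int = field(default=0)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]

    def final(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a DataFrame with columns time, L, G, C, S, I, T, u_L, u_S.

        Components absent from a reduced trajectory are filled with NaN so the
        CSV schema is stable across system kinds.
        """
        df = pd.DataFrame({"time": self.t})
        for name in FULL_STATE_NAMES:
            df[name] = self[name] if name in self.names else np.nan
        u = self.controls if self.controls is not None else np.zeros((len(self.t), 2))
        df["u_L"] = u[:, 0]
        df["u_S"] = u[:, 1]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rk4_step(f, x: np.ndarray, t: float, h: float) -> np.ndarray:
    k1 = f(t, x)
    k2 = f(t + h / 2, x + h / 2 * k1)
    k3 = f(t + h / 2, x + h / 2 * k2)
    k4 = f(t + h, x + h * k3)
    return x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def integrate_trajectory(
    kind: str,
    initial_state,
    params: ModelParameters,
    horizon: tuple[float, float],
    step: float = 0.01,
    controls: ControlSignal | None = None,
    G: float = 0.0,
    S: float = 0.0,
) -> Trajectory:
    """Integrate the reduced or full system with classical RK4.

    Parameters
    ----------
    kind : {"reduced", "full"}
        Which right-hand side to integrate.  The reduced system needs the
        frozen signal levels ``G`` and ``S``; the full system takes a
        :class:`ControlSignal` (defaults to no infusion).
    horizon : (t_start, t_end)
        Integration window in days; must be non-degenerate.
    step : float
        Uniform step in days (> 0).  The number of steps is rounded so the
        grid hits ``t_end`` exactly.

    Tiny negative undershoots (< 1e-9) are clipped to zero and counted;
    anything larger raises :class:`IntegrationFailure` naming the time.
    """
    t0, t1 = float(horizon[0]), float(horizon[1])
    if step <= 0:
        raise ValueError("step must be > 0")
    if not t1 > t0:
        raise ValueError(f"degenerate horizon {horizon!r}")
    n_steps = max(1, round((t1 - t0) / step))
    h = (t1 - t0) / n_steps

    if kind == "reduced":
        names = ("C", "I", "T")
        x0 = (
            initial_state.as_array()
            if isinstance(initial_state, ReducedState)
            else np.asarray(initial_state, float)
        )
        rhs = lambda t, x: reduced_rhs(x, G, S, params)
        ctrl = None
    elif kind == "full":
        names = FULL_STATE_NAMES
        x0 = (
            initial_state.as_array()
            if isinstance(initial_state, FullState)
            else np.asarray(initial_state, float)
        )
        ctrl = controls if controls is not None else ControlSignal()

        def rhs(t, x):
            uL, uS = ctrl.values(t)
            return full_rhs(x, uL, uS, params, ctrl.u_L_max, ctrl.u_S_max)

    else:
        raise ValueError(f"unknown system kind {kind!r}")

    t_grid = t0 + h * np.arange(n_steps + 1)
    X = np.empty((n_steps + 1, len(names)))
    X[0] = x0
    clips = 0
    x = x0.astype(float).copy()
    for i in range(n_steps):
        x = _rk4_step(rhs, x, t_grid[i], h)
        if not np.all(np.isfinite(x)):
            raise IntegrationFailure(
                f"non-finite state at t={t_grid[i + 1]:.4f} (step {h} too coarse?)"
            )
        neg = x < 0
        if np.any(neg):
            worst = float(x[neg].min())
            if worst < -UNDERSHOOT_TOL:
                raise IntegrationFailure(
                    f"negative undershoot {worst:.3e} at t={t_grid[i + 1]:.4f}; "
                    "reduce the integration step"
                )
            x = np.where(neg, 0.0, x)
            clips += int(neg.sum())
        X[i + 1] = x

    traj_controls = None
    if kind == "full":
        traj_controls = np.array([ctrl.values(t) for t in t_grid])
    return Trajectory(t=t_grid, states=X, names=names, controls=traj_controls, clip_events=clips)
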