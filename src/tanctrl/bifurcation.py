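"""Equilibria, fold points, bistability windows and the cusp point of the
C–I subsystem.

Because the I-nullcline can be solved exactly for I as a function of C,

    I(C) = (λS·S + k2/(k4² + β·C²)) / μ,

equilibrium finding reduces to the roots of the scalar function

    F(C; G, S) = λ + λG·G + k1/(k3² + α·I(C)²) − C,

and fold/cusp continuation to root-finding on (F, ∂F/∂C, ∂²F/∂C²).  This
replaces full pseudo-arclength continuation, which the two-dimensional
fast subsystem does not need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dynamics import reduced_jacobian
from .parameters import ModelParameters

__all__ = [
    "Equilibrium",
    "BistabilityWindow",
    "CuspPoint",
    "equilibria_at",
    "bistability_window",
    "locate_cusp",
    "two_parameter_fold_curve",
    "ScanRangeError",
    "DegenerateStructureError",
]

#: default upper end of the C scan range (well above any equilibrium at
#: the default calibration) and coarse scan resolution
C_SCAN_MAX = 20.0
SCAN_POINTS = 2000


class ScanRangeError(RuntimeError):
    """An equilibrium sits at the boundary of the C scan range."""


class DegenerateStructureError(RuntimeError):
    """An equilibrium count other than 1 or 3 was encountered."""


@dataclass
class Equilibrium:
    """A steady state of the C–I subsystem with its linear stability."""

    C_star: float
    I_star: float
    eigenvalues: tuple[complex, complex]
    stability: str  # "stable" | "unstable" | "marginal"

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class BistabilityWindow:
    """Fold-point pair [lower, upper] of a one-parameter sweep; ``empty``
    when the equilibrium count never exceeds one."""

    parameter_name: str
    lower: float | None
    upper: float | None
    empty: bool

    @property
    def width(self) -> float:
        return 0.0 if self.empty else self.upper - self.lower


@dataclass
class CuspPoint:
    """Codimension-2 point where the two fold branches meet.

    The state coordinates (C_star, I_star) are the phenotype thresholds
    separating N1- from N2-dominant microenvironments.
    """

    G_star: float
    S_star: float
    C_star: float
    I_star: float
    residuals: tuple[float, float, float]


def _nullcline_I(C, S: float, p: ModelParameters):
    return (p.lambda_S * S + p.k2 / (p.k4**2 + p.beta * C**2)) / p.mu


def _F(C, G: float, S: float, p: ModelParameters):
    I = _nullcline_I(C, S, p)
    return p.lambda_il6 + p.lambda_G * G + p.k1 / (p.k3**2 + p.alpha * I**2) - C


def equilibria_at(
    G: float,
    S: float,
    params: ModelParameters,
    C_scan_max: float = C_SCAN_MAX,
    scan_points: int = SCAN_POINTS,
) -> list[Equilibrium]:
    """All equilibria of the C–I subsystem at signal levels (G, S).

    Roots of F are bracketed on a uniform coarse grid and refined by
    bisection (brentq) to |F| ≤ 1e-12; stability is classified from the
    eigenvalues of the reduced Jacobian, with |max Re λ| ≤ 1e-8 reported
    as "marginal" rather than silently stable.
    """
    if G < 0 or S < 0:
        raise ValueError("G and S must be non-negative")
    # every root satisfies C = λ + λG·G + k1/(k3² + αI²) ≤ λ + λG·G + k1/k3²
    root_bound = params.lambda_il6 + params.lambda_G * G + params.k1 / params.k3**2
    if C_scan_max <= root_bound:
        raise ScanRangeError(
            f"C_scan_max={C_scan_max} does not cover the root bound {root_bound:.3g}; "
            "enlarge C_scan_max"
        )
    grid = np.linspace(0.0, C_scan_max, scan_points)
    f = _F(grid, G, S, params)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = f[i], f[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(
                float(
                    brentq(
                        _F, grid[i], grid[i + 1], args=(G, S, params), xtol=1e-14, rtol=1e-15
                    )
                )
            )
    out = []
    for C_star in roots:
        I_star = float(_nullcline_I(C_star, S, params))
        eig = np.linalg.eigvals(reduced_jacobian(np.array([C_star, I_star, 0.0]), params))
        max_re = float(np.max(eig.real))
        if abs(max_re) <= 1e-8:
            stab = "marginal"
        elif max_re < 0:
            stab = "stable"
        else:
            stab = "unstable"
        out.append(
            Equilibrium(
                C_star=C_star,
                I_star=I_star,
                eigenvalues=(complex(eig[0]), complex(eig[1])),
                stability=stab,
            )
        )
    return sorted(out, key=lambda e: e.C_star)


def _count(G: float, S: float, params: ModelParameters, **kw) -> int:
    n = len(equilibria_at(G, S, params, **kw))
    if n not in (1, 3):
        raise DegenerateStructureError(
            f"equilibrium count {n} at (G={G}, S={S}); expected 1 or 3"
        )
    return n


def bistability_window(
    scan_parameter: str,
    fixed_value: float,
    scan_range: tuple[float, float],
    params: ModelParameters,
    coarse_points: int = 400,
    refine_tol: float = 1e-4,
) -> BistabilityWindow:
    """Locate the fold pair of a one-parameter sweep in G (S fixed) or S
    (G fixed).

    The parameter is swept on a coarse grid; each 1↔3 transition is then
    refined by bisection on the parameter to within ``refine_tol``.
    Returns an empty window if the count never exceeds one.
    """
    if scan_parameter not in ("G", "S"):
        raise ValueError("scan_parameter must be 'G' or 'S'")
    lo, hi = float(scan_range[0]), float(scan_range[1])
    if not (0.0 <= lo < hi <= 2.0):
        raise ValueError("scan_range must lie within [0, 2]")
    if fixed_value < 0:
        raise ValueError("fixed_value must be non-negative")

    def count_at(v: float) -> int:
        if scan_parameter == "G":
            return _count(v, fixed_value, params)
        return _count(fixed_value, v, params)

    grid = np.linspace(lo, hi, coarse_points)
    counts = np.array([count_at(v) for v in grid])
    if counts.max() == 1:
        return BistabilityWindow(scan_parameter, None, None, True)

    def refine(a: float, b: float, ca: int) -> float:
        # bisect the parameter interval [a, b] across a 1<->3 transition
        while b - a > refine_tol:
            m = 0.5 * (a + b)
            if count_at(m) == ca:
                a = m
            else:
                b = m
        return 0.5 * (a + b)

    trans = np.nonzero(counts[:-1] != counts[1:])[0]
    folds = [refine(grid[i], grid[i + 1], counts[i]) for i in trans]
    if len(folds) != 2:
        raise DegenerateStructureError(
            f"expected 2 fold transitions in sweep, found {len(folds)}"
        )
    return BistabilityWindow(scan_parameter, min(folds), max(folds), False)


def _fold_system(C: float, S: float, params: ModelParameters):
    """Analytic (∂F/∂C, ∂²F/∂C²); G drops out because it enters F
    additively.  With D = k4² + βC², E = k3² + αI²:

        I   = (λS·S + k2/D)/μ
        I'  = −2βCk2/(μD²)
        I'' = −(2βk2/μ)(D − 4βC²)/D³
        F'  = −2αk1·I·I'/E² − 1
        F'' = −2αk1·[(I'² + I·I'')/E² − 4αI²I'²/E³]
    """
    p = params
    D = p.k4**2 + p.beta * C**2
    I = (p.lambda_S * S + p.k2 / D) / p.mu
    Ip = -2.0 * p.beta * C * p.k2 / (p.mu * D**2)
    Ipp = -(2.0 * p.beta * p.k2 / p.mu) * (D - 4.0 * p.beta * C**2) / D**3
    E = p.k3**2 + p.alpha * I**2
    d1 = -2.0 * p.alpha * p.k1 * I * Ip / E**2 - 1.0
    d2 = -2.0 * p.alpha * p.k1 * (
        (Ip**2 + I * Ipp) / E**2 - 4.0 * p.alpha * I**2 * Ip**2 / E**3
    )
    return d1, d2


def locate_cusp(
    params: ModelParameters,
    initial_guess: tuple[float, float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> CuspPoint:
    """Solve F = ∂F/∂C = ∂²F/∂C² = 0 for the cusp point.

    Since G appears additively in F, the problem splits: a damped Newton
    iteration on (C, S) drives (∂F/∂C, ∂²F/∂C²) to zero, after which
    G_star follows explicitly from F = 0.  The default starting point is
    derived from the fold pair of a G-sweep at S = 0.2.
    """
    if initial_guess is None:
        w = bistability_window("G", 0.2, (0.0, 1.0), params)
        if w.empty:
            raise DegenerateStructureError(
                "no fold found at S=0.2 to seed the cusp search"
            )
        # the fold C-coordinates at the window edges straddle the cusp C
        eq = equilibria_at(0.5 * (w.lower + w.upper), 0.2, params)
        C0 = eq[1].C_star if len(eq) == 3 else eq[0].C_star
        S0 = 0.3
    else:
        C0, S0 = initial_guess

    x = np.array([C0, S0], float)
    for _ in range(max_iter):
        g1, g2 = _fold_system(x[0], x[1], params)
        res = np.array([g1, g2])
        if np.max(np.abs(res)) < tol:
            break
        # finite-difference Jacobian of the analytic (g1, g2) wrt (C, S)
        J = np.zeros((2, 2))
        for j, h in enumerate((1e-7, 1e-7)):
            xp = x.copy()
            xp[j] += h
            g1p, g2p = _fold_system(xp[0], xp[1], params)
            J[0, j] = (g1p - g1) / h
            J[1, j] = (g2p - g2) / h
        try:
            dx = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError as e:
            raise RuntimeError(f"singular Newton system near {x}: {e}") from e
        # damping: halve the step until the residual decreases
        step = 1.0
        n0 = np.max(np.abs(res))
        for _damp in range(30):
            xn = x + step * dx
            if xn[0] > 0 and xn[1] >= 0:
                g1n, g2n = _fold_system(xn[0], xn[1], params)
                if np.max(np.abs([g1n, g2n])) < n0:
                    break
            step *= 0.5
        x = x + step * dx
    else:
        g1, g2 = _fold_system(x[0], x[1], params)
        raise RuntimeError(
            f"cusp Newton iteration did not converge in {max_iter} iterations; "
            f"final residuals dF/dC={g1:.3e}, d2F/dC2={g2:.3e}"
        )

    C_star, S_star = float(x[0]), float(x[1])
    I_star = float(_nullcline_I(C_star, S_star, params))
    # F(C*; G*, S*) = 0  =>  G* = (C* - λ - k1/(k3² + α I*²)) / λG
    if params.lambda_G == 0:
        raise ValueError("lambda_G must be non-zero to place the cusp in G")
    G_star = (
        C_star
        - params.lambda_il6
        - params.k1 / (params.k3**2 + params.alpha * I_star**2)
    ) / params.lambda_G
    g1, g2 = _fold_system(C_star, S_star, params)
    resid = (float(_F(C_star, G_star, S_star, params)), float(g1), float(g2))
    return CuspPoint(G_star=G_star, S_star=S_star, C_star=C_star, I_star=I_star, residuals=resid)


def two_parameter_fold_curve(
    params: ModelParameters,
    S_grid,
    G_range: tuple[float, float] = (0.0, 2.0),
) -> list[tuple[float, float, float]]:
    """Fold G-values (lower, upper) for each S in ``S_grid``.

    The two branches approach each other as S increases and meet at the
    cusp; S values beyond the cusp yield no entry (empty window).
    """
    out = []
    for S in S_grid:
        w = bistability_window("G", float(S), G_range, params)
        if not w.empty:
            out.append((float(S), w.lower, w.upper))
    return out
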