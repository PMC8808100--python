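"""Adaptive 60-day treatment protocols built on 1-day optimal-control
infusions.

Four clinical strategies are simulated with day-granular monitoring of
the N1-dominance condition C < C_th and I > I_th:

* ``tgfb_only`` — TGF-β inhibitor, 1 unit/administration, IFN-β source
  held constant (S frozen).
* ``ifnb_only`` — IFN-β with an escalating dose ladder (2 → 10 units in
  steps of 2), TGF-β frozen at an intermediate level and no inhibitor.
* ``concomitant`` — both drugs on the same treatment days.
* ``alternating`` — drugs alternate across administration slots,
  inhibitor first.

Each administration is one day of optimally shaped infusion (isoperimetric
FBSM solve) followed by a rest day; infusions are truncated early if the
N1-dominance condition is reached mid-day.  After the condition is first
restored, surveillance uses an anticipatory guard band: re-administration
triggers when C ≥ C_th − ε or I ≤ I_th + ε at a daily check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ocp import ConvergenceError, OCPSolution, OCPSpec, isoperimetric_solve
from .parameters import ModelParameters
from .states import FULL_STATE_NAMES

__all__ = [
    "ProtocolSpec",
    "Administration",
    "TreatmentRecord",
    "Period",
    "PeriodSegmentation",
    "SummaryStats",
    "n1_dominance_check",
    "classify_risk",
    "run_protocol",
    "segment_periods",
    "summarize_protocol",
    "compare_strategies",
    "STRATEGIES",
]

STRATEGIES = ("tgfb_only", "ifnb_only", "concomitant", "alternating")
_IDX = {n: i for i, n in enumerate(FULL_STATE_NAMES)}
_DRUG_CONTROL = {"L": "u_L", "S": "u_S"}


def n1_dominance_check(C: float, I: float, params: ModelParameters) -> bool:
    """True iff the microenvironment is N1-dominant: C < C_th and I > I_th
    (strict inequalities)."""
    if C < 0 or I < 0:
        raise ValueError("C and I must be non-negative")
    return bool(C < params.C_th and I > params.I_th)


def classify_risk(C0: float, I0: float, params: ModelParameters) -> str:
    """Risk quadrant of an initial phenotype state relative to the
    thresholds: both high → low_risk_high, N1-dominant → risk_free,
    both low → low_risk_low, N2-dominant → high_risk."""
    if C0 < 0 or I0 < 0:
        raise ValueError("C0 and I0 must be non-negative")
    if C0 >= params.C_th:
        return "low_risk_high" if I0 > params.I_th else "high_risk"
    return "risk_free" if I0 > params.I_th else "low_risk_low"


@dataclass
class ProtocolSpec:
    """Configuration of one treatment strategy run."""

    strategy: str
    horizon: float = 60.0
    infusion_window: float = 1.0
    rest_window: float = 1.0
    A1_per_administration: float = 1.0
    A2_min: float = 2.0
    A2_step: float = 2.0
    A2_max: float = 10.0
    guard_band: float = 0.05
    B1: float = 1.0
    B2: float = 1.0
    step: float = 0.01
    T_init: float = 10.0
    L_init: float = 0.0
    S_init: float = 0.0
    G_init: float | None = None  # None -> untreated equilibrium GS/mu_G
    S_const: float = 0.2  # frozen IFN-β level for tgfb_only
    G_const: float = 0.45  # frozen TGF-β level for ifnb_only
    inhibitor_first: bool = True  # alternating order
    fbsm_relaxation: float = 0.5
    fbsm_tolerance: float = 1e-6
    fbsm_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.infusion_window <= 0 or self.rest_window <= 0:
            raise ValueError("infusion and rest windows must be positive")
        if not self.A2_min <= self.A2_max:
            raise ValueError("A2_min must not exceed A2_max")
        if self.horizon <= 0 or self.step <= 0:
            raise ValueError("horizon and step must be positive")

    def frozen_states(self) -> dict[str, float]:
        if self.strategy == "tgfb_only":
            return {"S": self.S_const}
        if self.strategy == "ifnb_only":
            return {"G": self.G_const, "L": 0.0}
        return {}

    def initial_state(self, C0: float, I0: float, params: ModelParameters) -> np.ndarray:
        G0 = self.G_init if self.G_init is not None else params.GS / params.mu_G
        x = np.array([self.L_init, G0, C0, self.S_init, I0, self.T_init])
        for s, v in self.frozen_states().items():
            x[_IDX[s]] = v
        return x


@dataclass
class Administration:
    """Log entry of one drug administration (one infusion day)."""

    day: int
    drug: str  # "L" or "S"
    budget: float
    delivered: float
    truncated: bool
    converged: bool
    iterations: int
    theta: float


@dataclass
class Period:
    label: str
    start: float
    end: float

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class PeriodSegmentation:
    """Ordered, disjoint labelled intervals covering [0, horizon]."""

    periods: list[Period]

    def __iter__(self):
        return iter(self.periods)

    def by_label(self, label: str) -> list[Period]:
        return [p for p in self.periods if p.label == label]


@dataclass
class TreatmentRecord:
    """Full record of one protocol run."""

    strategy: str
    spec: ProtocolSpec
    params: ModelParameters
    start: tuple[float, float]  # (C0, I0)
    t: np.ndarray
    states: np.ndarray  # (n, 6)
    controls: np.ndarray  # (n, 2)
    admins: list[Administration]
    daily: pd.DataFrame  # day, C, I, condition_ok, trigger
    all_converged: bool

    def state_at_day(self, day: float) -> np.ndarray:
        i = int(round(day / self.spec.step))
        return self.states[min(i, len(self.t) - 1)]

    def condition_at_day(self, day: float) -> bool:
        x = self.state_at_day(day)
        return n1_dominance_check(x[_IDX["C"]], x[_IDX["I"]], self.params)

    def first_condition_day(self) -> int | None:
        """First integer day at which the N1-dominance condition holds
        after the first administration (daily monitoring)."""
        if not self.admins:
            return None
        d0 = self.admins[0].day
        ok = self.daily[(self.daily["day"] > d0) & self.daily["condition_ok"]]
        return int(ok["day"].iloc[0]) if len(ok) else None

    def total_delivered(self, drug: str) -> float:
        return sum(a.delivered for a in self.admins if a.drug == drug)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(FULL_STATE_NAMES))
        df.insert(0, "time", self.t)
        df["u_L"] = self.controls[:, 0]
        df["u_S"] = self.controls[:, 1]
        return df

    def admins_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "day": a.day,
                    "drug": a.drug,
                    "budget": a.budget,
                    "delivered": a.delivered,
                    "truncated": a.truncated,
                    "converged": a.converged,
                    "iterations": a.iterations,
                    "theta": a.theta,
                }
                for a in self.admins
            ]
        )


@dataclass
class SummaryStats:
    """Per-period N2/N1 averages (τ) and drug-cost summaries."""

    tau_by_period: dict[str, float]
    tau_max_over_min: float
    total_drug: dict[str, float]
    final_tumour: float


class ProtocolError(RuntimeError):
    pass


def _integrate_uncontrolled(x, frozen_idx, params: ModelParameters, days, h):
    """RK4 integration with zero infusion; frozen components held fixed."""
    p = params
    lam, lamG, lamS = p.lambda_il6, p.lambda_G, p.lambda_S
    k1_, k2_, k32, k42 = p.k1, p.k2, p.k3**2, p.k4**2
    al, be, mu = p.alpha, p.beta, p.mu
    r, K, g1, T0, de = p.r, p.K, p.gamma1, p.T0, p.delta
    GS, muG, gL, muL, muS = p.GS, p.mu_G, p.gamma_L, p.mu_L, p.mu_S
    keep = np.ones(6)
    keep[frozen_idx] = 0.0

    def f(y):
        L, G, C, S, I, T = y
        return keep * np.array(
            [
                -muL * L,
                GS - muG * G - gL * L * G,
                lam + lamG * G + k1_ / (k32 + al * I * I) - C,
                -muS * S,
                lamS * S + k2_ / (k42 + be * C * C) - mu * I,
                r * (1.0 + C / (K + g1 * I)) * T * (1.0 - T / T0) - de * I * T,
            ]
        )

    n = max(1, round(days / h))
    X = np.empty((n + 1, 6))
    X[0] = x
    xi = np.array(x, float)
    for _ in range(n):
        k1 = f(xi)
        k2 = f(xi + h / 2 * k1)
        k3 = f(xi + h / 2 * k2)
        k4 = f(xi + h * k3)
        xi = xi + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        xi = np.where(xi < 0, 0.0, xi)
        X[_ + 1] = xi
    return X


def run_protocol(
    spec: ProtocolSpec,
    initial_CI: tuple[float, float],
    params: ModelParameters,
) -> TreatmentRecord:
    """Simulate one strategy over the full horizon.

    The event loop walks integer days.  At each decision day the
    N1-dominance condition is evaluated; treatment triggers when the
    condition fails, or — once at least one administration has been given
    and the condition restored — when the state enters the guard band
    around the thresholds.  A triggered administration solves the 1-day
    isoperimetric subproblem for the strategy's drug(s), applies the
    optimal infusion (truncated early if the condition is reached mid-day
    during a treatment administration), and is followed by a rest day.
    """
    C0, I0 = initial_CI
    x = spec.initial_state(C0, I0, params)
    frozen = spec.frozen_states()
    frozen_idx = np.array([_IDX[s] for s in frozen], dtype=int)
    h = spec.step
    horizon = spec.horizon

    # accumulated fine-grid trajectory
    t_parts = [np.array([0.0])]
    x_parts = [x[None, :]]
    u_parts = [np.zeros((1, 2))]

    admins: list[Administration] = []
    daily_rows = []
    all_converged = True

    # IFN-β escalation ladder state
    current_A2 = spec.A2_min
    # alternating slot state
    next_drug = "L" if spec.inhibitor_first else "S"
    # warm-start caches per drug combination
    warm_theta: dict[str, float] = {}
    warm_u: dict[str, np.ndarray] = {}
    treated_once = False
    condition_restored = False  # condition held at some daily check after treatment

    def cond(xv) -> bool:
        return n1_dominance_check(xv[_IDX["C"]], xv[_IDX["I"]], params)

    def guard(xv) -> bool:
        return (
            xv[_IDX["C"]] >= params.C_th - spec.guard_band
            or xv[_IDX["I"]] <= params.I_th + spec.guard_band
        )

    def append(T, X, U):
        t_parts.append(T[1:])
        x_parts.append(X[1:])
        u_parts.append(U[1:])

    def administer(day: float, drugs: list[tuple[str, float]], early_stop: bool):
        """Solve and apply one infusion day for the given (drug, budget)
        pairs; returns the end-of-day state."""
        nonlocal all_converged
        key = "+".join(d for d, _ in drugs)
        active = tuple(_DRUG_CONTROL[d] for d, _ in drugs)
        budgets = {d: A for d, A in drugs}
        ocp = OCPSpec(
            initial_state=x.copy(),
            horizon=(0.0, spec.infusion_window),
            active_controls=active,
            B1=spec.B1,
            B2=spec.B2,
            A1=budgets.get("L"),
            A2=budgets.get("S"),
            frozen_states=dict(frozen),
            step=h,
            relaxation=spec.fbsm_relaxation,
            tolerance=spec.fbsm_tolerance,
            max_iter=spec.fbsm_max_iter,
        )
        guess = (warm_theta.get(key + ":u_L", 0.0), warm_theta.get(key + ":u_S", 0.0))
        try:
            sol: OCPSolution = isoperimetric_solve(
                ocp, params, theta_guess=guess, u_warm=warm_u.get(key)
            )
        except ConvergenceError as e:
            raise ProtocolError(
                f"inner FBSM failed on day {day} (strategy {spec.strategy}, "
                f"drugs {key}): {e}"
            ) from e
        if not sol.converged:
            raise ProtocolError(
                f"inner FBSM failed to converge on day {day} "
                f"(strategy {spec.strategy}, drugs {key}, {sol.iterations} iterations)"
            )
        warm_theta[key + ":u_L"], warm_theta[key + ":u_S"] = sol.theta
        warm_u[key] = sol.controls

        U = sol.controls.copy()
        X = sol.states.copy()
        truncated_at = None
        if early_stop:
            for i in range(len(X)):
                if cond(X[i]):
                    truncated_at = i
                    break
        if truncated_at is not None and truncated_at < len(X) - 1:
            U[truncated_at:] = 0.0
            tail = _integrate_uncontrolled(
                X[truncated_at], frozen_idx, params,
                (len(X) - 1 - truncated_at) * h, h,
            )
            X[truncated_at:] = tail
        T = day + sol.t
        append(T, X, U)
        for d, A in drugs:
            col = 0 if d == "L" else 1
            delivered = float(np.trapezoid(U[:, col], dx=h))
            admins.append(
                Administration(
                    day=int(day),
                    drug=d,
                    budget=A,
                    delivered=delivered,
                    truncated=truncated_at is not None,
                    converged=sol.converged,
                    iterations=sol.iterations,
                    theta=sol.theta[col],
                )
            )
        return X[-1]

    def log_day(d, xv, trigger):
        if daily_rows and daily_rows[-1]["day"] == d:
            return
        daily_rows.append(
            {
                "day": int(d),
                "C": xv[_IDX["C"]],
                "I": xv[_IDX["I"]],
                "condition_ok": cond(xv),
                "trigger": trigger,
            }
        )

    day = 0
    while day < horizon:
        ok = cond(x)
        if treated_once and ok:
            condition_restored = True
        trigger = (not ok) or (treated_once and condition_restored and guard(x))
        log_day(day, x, trigger)
        if trigger:
            # choose drug(s) and budget for this administration
            in_treatment_episode = not ok
            if spec.strategy == "tgfb_only":
                drugs = [("L", spec.A1_per_administration)]
            elif spec.strategy == "ifnb_only":
                if not in_treatment_episode:
                    current_A2 = spec.A2_min  # maintenance dosing
                drugs = [("S", current_A2)]
            elif spec.strategy == "concomitant":
                if not in_treatment_episode:
                    current_A2 = spec.A2_min
                drugs = [("L", spec.A1_per_administration), ("S", current_A2)]
            else:  # alternating
                if next_drug == "L":
                    drugs = [("L", spec.A1_per_administration)]
                else:
                    if not in_treatment_episode:
                        current_A2 = spec.A2_min
                    drugs = [("S", current_A2)]
                next_drug = "S" if next_drug == "L" else "L"
            x = administer(day, drugs, early_stop=in_treatment_episode)
            treated_once = True
            log_day(day + spec.infusion_window, x, False)
            # escalate the IFN-β ladder for the next administration of an
            # unfinished treatment episode; reset once the condition holds
            if any(d == "S" for d, _ in drugs):
                if in_treatment_episode and not cond(x):
                    current_A2 = min(current_A2 + spec.A2_step, spec.A2_max)
                else:
                    current_A2 = spec.A2_min
            day += spec.infusion_window
            if day < horizon:  # rest day
                rest = min(spec.rest_window, horizon - day)
                X = _integrate_uncontrolled(x, frozen_idx, params, rest, h)
                T = day + h * np.arange(len(X))
                append(T, X, np.zeros((len(X), 2)))
                x = X[-1]
                day += rest
        else:
            X = _integrate_uncontrolled(x, frozen_idx, params, 1.0, h)
            T = day + h * np.arange(len(X))
            append(T, X, np.zeros((len(X), 2)))
            x = X[-1]
            day += 1

    t_all = np.concatenate(t_parts)
    x_all = np.vstack(x_parts)
    u_all = np.vstack(u_parts)
    log_day(int(horizon), x, False)  # final-day snapshot
    daily = pd.DataFrame(daily_rows)
    return TreatmentRecord(
        strategy=spec.strategy,
        spec=spec,
        params=params,
        start=(C0, I0),
        t=t_all,
        states=x_all,
        controls=u_all,
        admins=admins,
        daily=daily,
        all_converged=all_converged,
    )


def segment_periods(record: TreatmentRecord, spec: ProtocolSpec | None = None) -> PeriodSegmentation:
    """Label the run with clinical periods.

    Strategies with relapse semantics (tgfb_only, concomitant,
    alternating): treatment (first administration → first sustained
    N1-dominance), cancer-free (→ next administration), relapse
    (remainder).  For ifnb_only the post-treatment labels are critical
    (→ first maintenance administration) and maintenance.  A leading
    interval before the first administration is labelled cancer-free.
    """
    spec = spec or record.spec
    horizon = spec.horizon
    if not record.admins:
        return PeriodSegmentation([Period("cancer_free", 0.0, horizon)])

    first = record.admins[0].day
    daily = record.daily.set_index("day")["condition_ok"]
    pt_end = None
    days = [d for d in daily.index if d > first]
    for d in days:
        nxt = d + 1
        if daily.loc[d] and (nxt not in daily.index or daily.loc[nxt]):
            pt_end = float(d)
            break
    periods: list[Period] = []
    if first > 0:
        periods.append(Period("cancer_free", 0.0, float(first)))
    if pt_end is None:
        periods.append(Period("treatment", float(first), horizon))
        return PeriodSegmentation(periods)
    periods.append(Period("treatment", float(first), pt_end))

    later = [a.day for a in record.admins if a.day >= pt_end]
    mid_label = "critical" if record.strategy == "ifnb_only" else "cancer_free"
    tail_label = "maintenance" if record.strategy == "ifnb_only" else "relapse"
    if later:
        boundary = float(later[0])
        if boundary > pt_end:
            periods.append(Period(mid_label, pt_end, boundary))
        periods.append(Period(tail_label, boundary, horizon))
    else:
        periods.append(Period(mid_label, pt_end, horizon))
    return PeriodSegmentation(periods)


def summarize_protocol(
    record: TreatmentRecord, segmentation: PeriodSegmentation | None = None
) -> SummaryStats:
    """Time-averaged N2/N1 ratio (τ) per period, overall τ_max/τ_min,
    drug totals and final tumour volume."""
    segmentation = segmentation or segment_periods(record)
    C = record.states[:, _IDX["C"]]
    I = record.states[:, _IDX["I"]]
    if np.any(I <= 0):
        raise ProtocolError("N2/N1 ratio undefined: I(t) reached zero")
    ratio = C / I
    tau = {}
    for p in segmentation:
        sel = (record.t >= p.start) & (record.t <= p.end)
        label = p.label
        key = label if label not in tau else f"{label}_{p.start:g}"
        tau[key] = float(np.mean(ratio[sel]))
    return SummaryStats(
        tau_by_period=tau,
        tau_max_over_min=float(ratio.max() / ratio.min()),
        total_drug={
            "L": record.total_delivered("L"),
            "S": record.total_delivered("S"),
        },
        final_tumour=float(record.states[-1, _IDX["T"]]),
    )


def compare_strategies(records: dict[tuple[str, str], TreatmentRecord]) -> pd.DataFrame:
    """Relative per-drug totals across strategies × initial conditions.

    ``records`` maps (strategy, start_label) to runs; totals are
    normalised within each (strategy, drug) to the maximum across the
    initial conditions.  Raises on an incomplete grid.
    """
    strategies = sorted({k[0] for k in records})
    starts = sorted({k[1] for k in records})
    missing = [(s, q) for s in strategies for q in starts if (s, q) not in records]
    if missing:
        raise ProtocolError(f"incomplete strategy × start grid; missing {missing}")
    rows = []
    for s in strategies:
        for drug in ("L", "S"):
            totals = {q: records[(s, q)].total_delivered(drug) for q in starts}
            mx = max(totals.values())
            if mx <= 0:
                continue  # drug unused by this strategy
            for q in starts:
                rows.append(
                    {
                        "strategy": s,
                        "start": q,
                        "drug": drug,
                        "total": totals[q],
                        "relative": totals[q] / mx,
                    }
                )
    return pd.DataFrame(rows)
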