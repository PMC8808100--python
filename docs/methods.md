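# Methods

## Model

Six dimensionless states: TGF-β inhibitor L, TGF-β G, N2 complex C,
IFN-β S, N1 complex I, tumour volume T. Time is in days.

```
dL/dt = u_L(t) − μL·L
dG/dt = GS − μG·G − γL·L·G
dC/dt = λ + λG·G + k1/(k3² + α·I²) − C
dS/dt = u_S(t) − μS·S
dI/dt = λS·S + k2/(k4² + β·C²) − μ·I
dT/dt = r·(1 + C/(K + γ1·I))·T·(1 − T/T0) − δ·I·T
```

The C and I equations form a fast mutually-inhibitory toggle (Hill-type
cross-repression), sourced by G and S respectively. The tumour grows
logistically, amplified by C and suppressed both through the growth
denominator (γ1·I) and by direct N1-mediated killing (δ·I·T). The
tumour feeds back on nothing, so the bifurcation structure of the C–I
subsystem is independent of T, δ and the growth parameters.

Default calibration (per day, dimensionless): λ=0.01, k1=k2=4, k3=k4=1,
α=1.5, β=1, μ=1, r=0.05, K=1, γ1=0.1, T0=100, GS=μG=0.826, γL=100,
μL=6.6, μS=3.96, C_th=1.81, I_th=1.29.

Three coefficients have no tabulated value and are package choices,
exposed as ordinary configurable fields:

* **λG = λS = 1** — with unit couplings the G- and S-axes of the
  bifurcation diagrams carry through to the C and I equations unchanged,
  and the computed fold points land exactly on the tabulated windows
  (below). Any other value rescales those windows, so unity is the only
  choice consistent with the calibration.
* **δ = 0.05** — same order as r, so an N1-dominant state shrinks the
  tumour; it affects only tumour read-outs, never the switch analysis.
* **T(0) = 10** — initial tumour volume for protocol runs (10% of
  carrying capacity); configurable.

## Equilibria, folds and the cusp

The I-nullcline solves exactly: `I(C) = (λS·S + k2/(k4² + β·C²))/μ`.
Substituting it reduces equilibrium finding to the scalar root problem
`F(C; G, S) = λ + λG·G + k1/(k3² + α·I(C)²) − C = 0`. Because every
root satisfies `C ≤ λ + λG·G + k1/k3²`, a scan range exceeding that
bound provably brackets all equilibria; the default scans C ∈ [0, 20]
on 2000 points and refines each bracketed root with `brentq` to
|F| ≤ 1e-12. Stability comes from the eigenvalues of the analytic 2×2
Jacobian; |max Re λ| ≤ 1e-8 is reported as "marginal" rather than
silently stable. This nullcline-substitution continuation replaces the
pseudo-arclength continuation a general-purpose package would use — the
fast subsystem is two-dimensional, so the scalar reduction is exact.

A bistability window is found by sweeping the parameter on a coarse grid
(400 points by default), detecting 1↔3 transitions in the root count and
bisecting each transition to a width of 1e-4. At the default
calibration: G-window [0.33, 0.53] at S = 0.2; S-window [0.06, 0.25] at
G = 0.45 (the level used in the IFN-β-only scenario). Near the cusp the
window is narrower than the default coarse grid; callers scanning there
pass a finer grid (the tests do).

The cusp solves F = ∂F/∂C = ∂²F/∂C² = 0. G enters F additively, so the
system splits: damped Newton on (C, S) drives the two analytic
C-derivatives to zero, then G* follows in closed form from F = 0.
Derivatives of F are analytic throughout — finite-differencing ∂²F/∂C²
is numerically hostile (cancellation) and was deliberately avoided. The
cusp's state coordinates reproduce the tabulated thresholds
(C_th, I_th) = (1.81, 1.29) to well beyond two decimals.

## Optimal control

Each subproblem minimises `J = ∫ [T + (B1/2)u_L² + (B2/2)u_S²] dt`
(B1 = B2 = 1 by default) over box-bounded controls, subject to the full
dynamics with scenario-dependent frozen states, and optionally to exact
dose budgets `∫u_i dt = A_i`. The Hamiltonian is

```
H = T + Σ_i [(B_i/2)u_i² + θ_i·u_i] + Σ_x λ_x·f_x
```

with a constant multiplier θ_i per budgeted control. Stationarity gives
the projected characterization `u_i = clip(−(λ_entry + θ_i)/B_i, 0,
u_i_max)`, where the entry costate is λ_L for u_L and λ_S for u_S. The
adjoint field is `λ̇ = −(e_T + (∂f/∂x)ᵀ λ)` with transversality
λ(t₁) = 0; frozen states contribute neither dynamics nor costates. The
analytic adjoint is locked in by a finite-difference-of-H oracle test.

**FBSM.** Forward RK4 state sweep with the current control, backward
RK4 adjoint sweep on the same grid (mid-step values interpolated),
relaxed control update `u ← (1−w)·u + w·u_char` with w = 0.5, until the
relative sup-norm change falls below 1e-6 (max 500 iterations;
non-convergence is reported, never silent). The sweep core is generic
over the dynamics/cost callables, which lets the test suite check it
against closed-form linear-quadratic solutions (Riccati, and a
Lagrange-multiplier isoperimetric problem) independent of the tumour
model.

**Isoperimetric outer loop.** The budget residual `∫u_i dt − A_i` is
monotone non-increasing in θ_i; a warm-started secant (bracketing +
`brentq` fallback) drives it below 1e-5. Zero and saturated budgets get
their multipliers in closed form. With both controls budgeted the two
multipliers relax alternately; the cross-coupling through the state is
weak and a few cycles suffice. Control bounds default to 5·A1 and 2·A2
per day — loose enough that solved schedules stay interior.

## Treatment protocols

Four strategies over a 60-day horizon, built from 1-day subproblems on
the shared 0.01-day grid:

| strategy | drug(s) | budget | frozen states |
|---|---|---|---|
| tgfb_only | L | A1 = 1/administration | S = 0.2 |
| ifnb_only | S | ladder 2 → 10, step 2 | G = 0.45, L = 0 |
| concomitant | L and S, same day | A1 = 1; S-ladder | — |
| alternating | L, then S, 2 days apart | A1 = 1; S-ladder | — |

Event loop at integer days: evaluate the N1-dominance condition
`C < C_th and I > I_th`; if treatment is indicated, solve the 1-day
isoperimetric subproblem, apply the control, then rest one day. A
treatment administration (condition failing at its start) is truncated
at the first grid point where the condition holds, with the shortfall
logged. After the condition has been restored at least once,
surveillance triggers anticipatory re-administration inside a guard band
(C ≥ C_th − ε or I ≤ I_th + ε, ε = 0.05); before any administration the
strict condition alone triggers, so a risk-free start drifts untreated
until it first fails a daily check. The IFN-β ladder escalates by 2
units per administration while an episode is unresolved (capped at 10)
and resets to the 2-unit minimum once the condition holds; alternating
administers the inhibitor first and simply skips a slot whose trigger
is absent. Initial ancillary states: L(0) = 0, S(0) = 0 (when dynamic),
G(0) = GS/μG = 1 (untreated equilibrium), T(0) = 10.

Runs are segmented into treatment (first administration → first
sustained N1-dominance at consecutive daily checks), then cancer-free /
relapse (split at the first post-treatment administration) — or
critical / maintenance for the IFN-β-only strategy. τ summaries are
time-averages of C/I per period on the fine grid.

## Synthetic cohorts

A patient is an initial (C0, I0) pair. The four canonical presets are
Q1 = (3, 2), Q2 = (1, 2), Q3 = (1, 0.5), Q4 = (4, 0.3); random cohorts
are drawn by uniform rejection sampling within each threshold-defined
risk quadrant of the box C ∈ [0, 5], I ∈ [0, 3], with a single seeded
generator owned by the cohort spec. Optional per-patient parameter
jitter is multiplicative log-normal (mean-one), preserving positivity;
jitter = 0 returns the baseline parameters identically. The generator
emulates cross-sectional diversity in the phenotype state only — it has
no longitudinal noise, no measurement error and no covariate structure,
so passing tests speak to the deterministic model under varied initial
conditions, not to fitting real patient data.

## Numerical choices

* Classical fixed-step RK4 everywhere, default step 0.01 day, chosen for
  exact reproducibility and state/adjoint grid alignment; adaptive
  integration is deliberately not used. Self-convergence tests confirm
  4th order.
* Negative undershoots below 1e-9 per step are clipped to zero and
  counted; larger undershoots raise an integration-failure error naming
  the time — the symptom of a step too coarse for the stiffest active
  rate (γL·L when L is large).
* All stated tolerances (root residual 1e-12, fold width 1e-4, cusp
  residual 1e-8, FBSM 1e-6, dose residual 1e-5) are defaults on the
  public functions.

## Known limitations

* The drug pharmacokinetics are fast (μL = 6.6/d, μS = 3.96/d) while the
  untreated environment is monostable-tumorigenic (G returns to 1 within
  ~a day of stopping the inhibitor; S < 0.06 lies below the bistable
  range at G = 0.45). Consequently every strategy settles into a
  perpetual administer/relapse cycle rather than a durable drug-free
  remission, and day-granular monitoring with a 0.05 guard band cannot
  always pre-empt a between-checks threshold crossing. Protocol
  summaries (period lengths, day-60 state, drug totals) therefore
  reflect the phase of that cycle; under these rate constants the
  inhibitor-only treatment period from the high-risk start is ~21 days
  (a pure lower bound of ~11 days holds even for uninterrupted total
  TGF-β suppression at this dose cadence).
* No Hopf or limit-cycle analysis (none occurs at this calibration), no
  delay or spatial effects, no linear (L1) cost functionals or
  bang-bang arcs, and no unit-ful pharmacokinetics.
* The every-other-day calendar is fixed by design; the package optimises
  within administrations, not the calendar itself.
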