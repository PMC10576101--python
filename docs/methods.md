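# Methods

## Model and assumptions

The package implements a one-way-coupled pair of dynamical systems on a
well-mixed population facing an emergency.

**Dependence-modified replicator dynamics.** Each opinion field is a
two-strategy game group. In a group with `n` strategies, counts grow as
`n_i' = κ_i n_i u_i` where `u_i` is the strategy's utility and `κ_i > 0` its
influence coefficient; differentiating the shares `z_i = n_i / Σ n_j` gives

```
z_i' = z_i κ_i [ u_i − ū + Σ_α (1 − κ_α/κ_i) z_α u_α ],   ū = Σ z_α u_α.
```

`general_replicator_rhs` implements exactly this; the two-field system
(`replicator_rhs`) is its two-strategy specialization with
`κ = (λ1, λ2)` for the official field and `(ρ1, ρ2)` for the public one,
parameterized only by the ratios `p21 = λ2/λ1` and `q21 = ρ2/ρ1` (`λ2`, `ρ2`
are never stored — the dynamics depend on the ratios alone). With all `κ`
equal the dependence terms cancel and the classical replicator is recovered;
the test suite asserts this reduction to 1e-12.

**Delayed SEIR contagion.** Panic spreads through S→E→I→R compartments with
constant inflow `a`, saturated (Holling type II) incidence evaluated at the
lagged infective count `I(t−τ)`, and opinion-dependent transition rates
(`m x1` S→R, `m x2` E→I, `y1` E→R, `y2` E→I and I→E). The four derivatives
sum to `a` identically, so total population grows linearly; the recovered
equation is slaved and the three-compartment decoupled form is used for all
equilibrium and stability analysis. The coupling is strictly game → SEIR:
the replicator equations contain no epidemic variables, so no feedback is
implemented and the game sub-trajectory of a coupled run is bit-identical to
a game-only run at the same step size (asserted in the tests).

## Parameters

| name | meaning | unit | baseline |
|------|---------|------|----------|
| B1…B6, C1, C11, C21 | payoff-matrix utilities | dimensionless | 15, 10, 7, 5, 3, 1, 5, 5, 4 |
| λ1, ρ1 | influence coefficients of the positive strategies | 1/time | 1, 1 |
| p21, q21 | dependence ratios within each field | dimensionless | 1, 1 |
| a | population inflow | individuals/time | 1 |
| β | transmission coefficient | 1/(individuals·time) | 0.2 |
| α | incidence saturation | 1/individuals | 1 |
| γ | recovery rate of infectives | 1/time | 0.5 |
| m | official-field authority | 1/time | 0.5 |
| τ | incubation delay | time | 1 (coupled runs); swept over 1, 2, 3 |

The `baseline` preset (initial strategies `(0.6, 0.5)`, initial compartments
`(2, 8, 10)`) is the reference parameterization of this model class; these
payoffs satisfy `B1 − C11 = B2` and `B2 + C11 = B1`, which makes both
closed-form degeneracy conditions vanish, places the scenario in the
tabulated four-sub-case regime, and leaves no interior equilibrium. Time is
reported in model units (conventionally labelled "s" in this literature).

## Equilibria and stability classification

The game's fixed points are the four corners plus, when both printed
denominators are nonzero and both coordinates strictly interior, one mixed
point with closed-form coordinates (`find_equilibria` suppresses a boundary
or out-of-range closed form with a log message and verifies every returned
point to RHS norm < 1e-12). Each fixed point is labelled from the sign
pattern of the hand-coded Jacobian's determinant and trace — ESS (`det > 0`,
`tr < 0`), unstable (`det > 0`, `tr > 0`), saddle (`det < 0`) — with an
absolute sign tolerance of 1e-9 inside which the label is `degenerate`.
Scenario-level classification evaluates the five sign conditions (`g1`,
`g0`, `g2`, `d1`, `d2` in `classify_scenario`'s docstring) against the two
tabulated regimes; parameter regions outside those tables, or conditions on
a sign boundary, fall back to numeric per-equilibrium classification, which
is attached to every report regardless.

For the epidemic side, the infection-free equilibrium `(a/(m x1), 0, 0)`
always exists (for `x1 > 0`); the endemic state is found numerically because
the printed closed form for `I*` is unreliable: the steady state reduces to
a scalar balance `φ(I)·S(I) = y1 E(I) + γ I` with `S(I) = a/(φ(I) + m x1)`
and `E(I) = (γ+y2) I/(m x2)`, bracketed on `(0, a/c2]` and solved by Brent's
method, then polished by a 3-D root find; the closed-form `E*/I*` ratio is
asserted on the result, and existence is claimed only for `R > 1`.
`basic_reproduction_number` raises (rather than returning NaN or 0/∞) at
`x1 = 0`, where the printed formula is singular.

**Spectral verification.** `stability_report` linearizes the decoupled
system at an equilibrium into `δ' = A δ(t) + B δ(t−τ)` (the lag enters only
through the incidence's dependence on `I(t−τ)`, so `B` has rank one). The
characteristic function splits as `P(λ) + Q(λ) e^{−λτ}` with
`P = det(λI − A)` and `Q` the monic-difference remainder, both obtained from
numeric characteristic polynomials — the numeric construction is
authoritative over any printed coefficient form, several of which are
internally inconsistent in this model family. A pure imaginary root exists
for *some* delay iff `|P(iω)| = |Q(iω)|` for some `ω > 0`; the report scans
`ω ∈ (0, ω_max]` (default `ω_max` = 10 × the largest model rate, 10⁴ grid
points, sign changes refined by bisection) and certifies `stable_all_tau`
only when the no-delay spectrum is strictly stable *and* the scan is empty.
At the infection-free point `−m x1` is an exact eigenvalue (the first column
of the Jacobian is `(−m x1, 0, 0)`), which the tests assert for random
draws.

**Lyapunov descent.** `lyapunov_descent` evaluates two candidates along
computed trajectories and returns finite-difference `dL/dt` samples
(tolerance +1e-8 absorbs differencing noise). The infection-free candidate
is the Volterra form `L1 = S − S⁰ − S⁰ ln(S/S⁰) + E + I + ∫_{t−τ}^t β S⁰
I/(1+αI)`, whose descent is guaranteed for `R < 1` and `γ > βa/(m x1)`; the
integral term is evaluated by the trapezoid rule with constant pre-history.
The endemic candidate `L2 = ((S−S*)+(E−E*)+(I−I*))²` is **not** pointwise
monotone along trajectories — its textbook descent bound drops cross terms
between compartments whose removal rates differ — so the tests assert
dominant descent (positive excursions below 1% of the peak descent rate)
and collapse of `L2` by more than six orders, which is the meaningful
numeric echo of global endemic stability.

## Numerical integration

Fixed-step classical RK4 throughout. For `τ > 0` the method of steps is
used: the step is shrunk so `τ = k·dt` with `k ≥ 20`, lag reads at step
endpoints land exactly on the grid, and reads at RK midpoints use cubic
Hermite interpolation of the stored solution (grid values plus stage-one
derivatives). Linear interpolation of the lag would cap global accuracy
near second order; the Hermite read keeps the scheme at RK4-class accuracy,
which the linear test equation `y'(t) = −y(t−1)` (piecewise-polynomial
exact solution) confirms to better than 1e-6 on [0, 4] at dt = 0.01.
Pre-history defaults to the constant `I(0)` — the minimal choice, and
configurable as any function on `[−τ, 0]`.

No clamping is applied to probabilities or compartments; the integrator
aborts with guidance if a compartment drops below −1e-9 or a probability
leaves [0, 1] by more than 1e-6 (interpolation of a decaying `I` may
undershoot zero by strictly less than that; the lagged value is floored at
0 before entering the incidence). Defaults: `dt = 0.01`, horizons 50 (game)
and 200 (coupled) time units — long enough for every baseline scenario to
settle while keeping a full report under a second of compute.

**Steady-state timing** uses an absolute band `eps = 0.01` with hold-to-end
semantics: the reported instant is the earliest grid time after the *last*
band exit. Under the baseline parameterization the published settling
instants (15–29 time units depending on the dependence ratios) are upper
bounds: direct integration of the stated equations settles in 0.65–3.1
units, so the acceptance checks treat those instants as bounds, not point
targets (the published time axis appears to be scaled).

**Delay sweep.** With accelerating dependence (`p21 = q21 = 0.5`) and
delays τ = 1, 2, 3 the susceptible curve dips and recovers toward
`a/(m·1) = 2`; its global maximum is delay-independent (a tiny initial
rise), so the informative per-delay summary is the transient extremum — the
trough — which deepens monotonically with τ (1.574, 1.540, 1.515), while
the exposed compartment's settling time grows (13.7, 14.7, 15.7). The sweep
summary reports `S_trough`, its time, `S_max` and `E_settle_time`.

## Design choices

- Sign tolerance 1e-9 for all case/label decisions: the tabulated analysis
  treats strict inequalities only, so anything inside the band is flagged
  degenerate and routed to the numeric fallback.
- Scenario configs are flat INI-style key=value sections interpreted as
  diffs against the `baseline` preset, keeping scenario files reviewable;
  unknown sections/keys are rejected with every offender listed, and every
  resolved parameter is echoed to the log at INFO.
- Sensitivity surfaces take the strategy probabilities as explicit
  arguments (default `(0.5, 0.5)`) and record them in the grid metadata,
  since `R` depends on them and no canonical choice exists; the surfaces
  are checked for monotonicity signs, not point values.
- Reports are computed entirely before anything is written, so a failing
  scenario leaves no partial outputs; CSVs are UTF-8 with '#'-prefixed
  metadata lines and are byte-reproducible for identical scenarios.

## Limitations

- The coupling is one-way by construction; feedback from panic prevalence
  onto payoffs is out of scope.
- Fixed-step RK4 with grid-aligned lags; no adaptive stepping or
  discontinuity tracking beyond the method-of-steps alignment, and no
  stochastic (agent-based) variant.
- The frequency scan is a grid-plus-bisection procedure: a root of even
  multiplicity (touching zero without a sign change) would be missed, and
  `stable_all_tau` is a numeric certificate, not a proof.
- Synthetic scenarios exercise smooth, well-scaled parameter regions; real
  crisis-communication data (heterogeneous mixing, time-varying inflow,
  measurement noise) lies outside what passing tests demonstrate.
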