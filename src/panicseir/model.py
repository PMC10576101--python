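"""Panic contagion and opinion-field decision making under emergencies.

This module couples two pieces of dynamics:

1. **An evolutionary game between two opinion fields.**  The *official*
   field (state media) chooses between positive and negative guidance with
   probability ``x1`` / ``1 - x1``; the *public* field (informal channels)
   chooses between positive and negative response with probability ``y1`` /
   ``1 - y1``.  Strategy shares evolve by replicator dynamics modified by
   *dependence coefficients* ``p21 = lambda2/lambda1`` and
   ``q21 = rho2/rho1`` that express how strongly the strategies inside one
   field depend on each other.  With ``p21 = q21 = 1`` the classical
   replicator equations are recovered.

2. **A delayed SEIR model of panic spread.**  A well-mixed group is split
   into susceptible, exposed, infective (panic-spreading) and recovered
   compartments.  New "infections" follow a Holling type II saturated
   incidence ``beta*S*I/(1 + alpha*I)`` evaluated at the lagged
   ``I(t - tau)``; the opinion-field strategies enter the transition rates
   through the official field's authority ``m`` (recovery of susceptibles at
   rate ``m*x1``, progression of exposed at rate ``m*x2``) and the public
   response probabilities (``y1`` moves exposed to recovered, ``y2`` shuttles
   between exposed and infective).

The coupling is one-way: the game does not see the epidemic state, so the
game subsystem can be integrated alone, and the coupled integrator feeds the
current ``(x1, y1)`` into the SEIR rates at every step.

Sections below follow the order the method runs: payoff structure ->
replicator dynamics -> game equilibria and stability -> delayed SEIR model
-> spectral / Lyapunov stability verification -> time integration ->
scenarios, sensitivity surfaces and reports.
"""

from __future__ import annotations

import configparser
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SIGN_TOL",
    "PayoffMatrix",
    "GameRates",
    "GameState",
    "StrategyPopulation",
    "EquilibriumReport",
    "GameClassification",
    "official_payoffs",
    "public_payoffs",
    "replicator_rhs",
    "general_replicator_rhs",
    "find_equilibria",
    "game_jacobian",
    "classify_equilibrium",
    "classify_scenario",
    "EpiParams",
    "EpiState",
    "SpectralReport",
    "holling_incidence",
    "seir_rhs",
    "seir3_rhs",
    "basic_reproduction_number",
    "infection_free_equilibrium",
    "positive_equilibrium",
    "stability_report",
    "lyapunov_descent",
    "Trajectory",
    "integrate_game",
    "integrate_epi",
    "integrate_coupled",
    "steady_state_time",
    "delay_sweep",
    "DelaySweep",
    "Scenario",
    "SensitivityGrid",
    "PRESETS",
    "load_scenario",
    "r_sensitivity",
    "run_report",
]

logger = logging.getLogger("panicseir")

#: Absolute tolerance inside which a sign condition (determinant, trace,
#: case discriminant) is treated as zero, i.e. "degenerate".
SIGN_TOL = 1e-9

#: Residual norm below which a point counts as a fixed point of the game.
_FIXED_POINT_TOL = 1e-12


# ---------------------------------------------------------------------------
# Payoff structure of the two opinion fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PayoffMatrix:
    """Game constants of the official/public opinion-field interaction.

    Parameters
    ----------
    b1, b2
        Official-field benefit when the public attitude is positive (b1)
        or negative (b2), independent of the official strategy.
    b3, b4, b5, b6
        Public-field benefit per strategy pair: (positive guidance,
        positive response) -> b3, (positive, negative) -> b4,
        (negative, positive) -> b5, (negative, negative) -> b6.
    c1
        Fixed cost the official field pays in an emergency.
    c11
        Additional official cost when the public responds positively.
    c21
        Additional public cost when the official field guides positively.

    All values are dimensionless utilities and must satisfy ``b1 > b2`` and
    ``b3 > b4 > b5 > b6`` with every entry strictly positive.
    """

    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    b6: float
    c1: float
    c11: float
    c21: float

    def __post_init__(self) -> None:
        problems = []
        for name in ("b1", "b2", "b3", "b4", "b5", "b6", "c1", "c11", "c21"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0 (got {getattr(self, name)})")
        if not self.b1 > self.b2:
            problems.append(f"requires b1 > b2 (got b1={self.b1}, b2={self.b2})")
        if not (self.b3 > self.b4 > self.b5 > self.b6):
            problems.append(
                "requires b3 > b4 > b5 > b6 "
                f"(got {self.b3}, {self.b4}, {self.b5}, {self.b6})"
            )
        if problems:
            raise ValueError("invalid PayoffMatrix: " + "; ".join(problems))


@dataclass(frozen=True)
class GameRates:
    """Strategy influence coefficients and intra-field dependence ratios.

    ``lambda1`` (official) and ``rho1`` (public) are the influence
    coefficients of the positive strategies, per unit time.  The dependence
    coefficients ``p21 = lambda2/lambda1`` and ``q21 = rho2/rho1`` are the
    ratios against the negative-strategy coefficients; the latter are never
    stored independently.
    """

    lambda1: float = 1.0
    rho1: float = 1.0
    p21: float = 1.0
    q21: float = 1.0

    def __post_init__(self) -> None:
        problems = []
        if not self.lambda1 > 0:
            problems.append(f"lambda1 must be > 0 (got {self.lambda1})")
        if not self.rho1 > 0:
            problems.append(f"rho1 must be > 0 (got {self.rho1})")
        if self.p21 < 0:
            problems.append(f"p21 must be >= 0 (got {self.p21})")
        if self.q21 < 0:
            problems.append(f"q21 must be >= 0 (got {self.q21})")
        if problems:
            raise ValueError("invalid GameRates: " + "; ".join(problems))

    @property
    def lambda2(self) -> float:
        return self.p21 * self.lambda1

    @property
    def rho2(self) -> float:
        return self.q21 * self.rho1


@dataclass(frozen=True)
class GameState:
    """Mixed-strategy state: probabilities of the positive strategies.

    ``x2 = 1 - x1`` and ``y2 = 1 - y1`` are derived accessors, never stored,
    so the simplex constraints hold by construction.
    """

    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x1 <= 1.0 and 0.0 <= self.y1 <= 1.0):
            raise ValueError(f"GameState out of [0,1]^2: ({self.x1}, {self.y1})")

    @property
    def x2(self) -> float:
        return 1.0 - self.x1

    @property
    def y2(self) -> float:
        return 1.0 - self.y1


def official_payoffs(
    pm: PayoffMatrix, state: GameState
) -> tuple[float, float, float]:
    """Payoffs of the official field: (positive, negative, average).

    ``u1 = y1(b1-c1-c11+c21) + y2(b2-c1+c21)`` is the expected utility of
    positive guidance, ``u2 = y1(b1-c1-c11) + y2(b2-c1)`` of negative
    guidance, and the field average is ``x1*u1 + x2*u2``.
    """
    y1, y2 = state.y1, state.y2
    u1 = y1 * (pm.b1 - pm.c1 - pm.c11 + pm.c21) + y2 * (pm.b2 - pm.c1 + pm.c21)
    u2 = y1 * (pm.b1 - pm.c1 - pm.c11) + y2 * (pm.b2 - pm.c1)
    ubar = state.x1 * u1 + state.x2 * u2
    return u1, u2, ubar


def public_payoffs(pm: PayoffMatrix, state: GameState) -> tuple[float, float, float]:
    """Payoffs of the public field: (positive, negative, average)."""
    x1, x2 = state.x1, state.x2
    u1 = x1 * (pm.b3 - pm.c21) + x2 * pm.b5
    u2 = x1 * (pm.b4 - pm.c21) + x2 * pm.b6
    ubar = state.y1 * u1 + state.y2 * u2
    return u1, u2, ubar


# ---------------------------------------------------------------------------
# Replicator dynamics with strategy dependence
# ---------------------------------------------------------------------------


def _bracket_x(pm: PayoffMatrix, rates: GameRates, y1: float) -> float:
    """Payoff-advantage bracket driving the official field's x1 dynamics."""
    return (
        (pm.b2 - pm.c1 + pm.c21)
        - rates.p21 * (pm.b2 - pm.c1)
        + (1.0 - rates.p21) * (pm.b1 - pm.c11 - pm.b2) * y1
    )


def _bracket_y(pm: PayoffMatrix, rates: GameRates, x1: float) -> float:
    """Payoff-advantage bracket driving the public field's y1 dynamics."""
    return (
        pm.b5
        - rates.q21 * pm.b6
        + (pm.b3 - pm.c21 - pm.b5 - rates.q21 * (pm.b4 - pm.c21) + rates.q21 * pm.b6)
        * x1
    )


def replicator_rhs(
    state: GameState, pm: PayoffMatrix, rates: GameRates
) -> tuple[float, float]:
    """Time derivatives (dx1/dt, dy1/dt) of the dependence-modified replicator.

    ``dx1/dt = lambda1 * x1 * (1-x1) * bracket_x(y1)`` and
    ``dy1/dt = rho1 * y1 * (1-y1) * bracket_y(x1)``, where the brackets are
    the positive-strategy payoff advantages corrected by the dependence
    coefficients.  The complements evolve antisymmetrically
    (``dx2/dt = -dx1/dt``).
    """
    dx1 = rates.lambda1 * state.x1 * (1.0 - state.x1) * _bracket_x(pm, rates, state.y1)
    dy1 = rates.rho1 * state.y1 * (1.0 - state.y1) * _bracket_y(pm, rates, state.x1)
    return dx1, dy1


@dataclass
class StrategyPopulation:
    """A game group with ``n`` strategies, counts, payoffs and influence.

    ``counts[i]`` individuals currently play strategy ``i`` with utility
    ``payoffs[i]``; ``kappa[i] > 0`` is the influence coefficient of the
    strategy.  Shares ``z = counts / counts.sum()`` are derived.
    """

    counts: np.ndarray
    payoffs: np.ndarray
    kappa: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.payoffs = np.asarray(self.payoffs, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.counts.size == 0:
            raise ValueError("empty strategy population")
        if not (self.counts.shape == self.payoffs.shape == self.kappa.shape):
            raise ValueError("counts, payoffs and kappa must share one shape")
        if np.any(self.counts < 0):
            raise ValueError("strategy counts must be >= 0")
        if not self.counts.sum() > 0:
            raise ValueError("all-zero strategy counts: shares undefined")
        if np.any(self.kappa <= 0):
            raise ValueError("influence coefficients kappa must be > 0")

    @property
    def shares(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def general_replicator_rhs(pop: StrategyPopulation) -> np.ndarray:
    """Share derivatives of the n-strategy dependence-modified replicator.

    ``z_i' = z_i * kappa_i * [u_i - ubar + sum_a (1 - kappa_a/kappa_i) z_a u_a]``
    with ``ubar = sum z_a u_a``.  Equivalent to differentiating
    ``z_i = n_i / sum n_a`` under the growth law ``n_i' = kappa_i n_i u_i``;
    with equal ``kappa`` it collapses to the classical replicator
    ``z_i' = z_i kappa (u_i - ubar)``.  The derivatives sum to zero.
    """
    z = pop.shares
    u = pop.payoffs
    k = pop.kappa
    ubar = float(z @ u)
    dz = np.empty_like(z)
    for i in range(z.size):
        dep = float(np.sum((1.0 - k / k[i]) * z * u))
        dz[i] = z[i] * k[i] * (u[i] - ubar + dep)
    return dz


# ---------------------------------------------------------------------------
# Game equilibria and det/trace stability classification
# ---------------------------------------------------------------------------

_CORNERS = ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0))


def _interior_equilibrium(
    pm: PayoffMatrix, rates: GameRates, tol: float = SIGN_TOL
) -> GameState | None:
    """Closed-form interior fixed point, or None when absent/degenerate.

    The interior point sits where both payoff brackets vanish:
    ``x1* = (b5 - q21 b6) / (b5 - b3 + c21 + q21(b4 - c21) - q21 b6)`` and
    ``y1* = (b2 - c1 + c21 - p21(b2 - c1)) / ((1 - p21)(b2 + c11 - b1))``.
    It is reported only when both denominators are nonzero and both
    coordinates are strictly inside (0, 1).
    """
    den_x = pm.b5 - pm.b3 + pm.c21 + rates.q21 * (pm.b4 - pm.c21) - rates.q21 * pm.b6
    den_y = (1.0 - rates.p21) * (pm.b2 + pm.c11 - pm.b1)
    if abs(den_x) <= tol or abs(den_y) <= tol:
        logger.debug(
            "interior equilibrium suppressed: vanishing denominator "
            "(den_x=%g, den_y=%g)", den_x, den_y,
        )
        return None
    x_star = (pm.b5 - rates.q21 * pm.b6) / den_x
    y_star = (pm.b2 - pm.c1 + pm.c21 - rates.p21 * (pm.b2 - pm.c1)) / den_y
    if not (tol < x_star < 1.0 - tol and tol < y_star < 1.0 - tol):
        logger.debug(
            "interior equilibrium suppressed: closed form (%g, %g) not "
            "strictly interior", x_star, y_star,
        )
        return None
    return GameState(x_star, y_star)


def find_equilibria(pm: PayoffMatrix, rates: GameRates) -> list[GameState]:
    """All fixed points of the replicator system.

    Always contains the four corner states; additionally contains the
    closed-form interior point when it exists strictly inside the unit
    square.  Every returned point has replicator RHS norm below 1e-12.
    """
    points = [GameState(x, y) for x, y in _CORNERS]
    interior = _interior_equilibrium(pm, rates)
    if interior is not None:
        dx, dy = replicator_rhs(interior, pm, rates)
        if math.hypot(dx, dy) < _FIXED_POINT_TOL:
            points.append(interior)
        else:  # pragma: no cover - closed form is exact up to rounding
            logger.warning(
                "interior closed form failed the fixed-point check "
                "(residual %g); omitted", math.hypot(dx, dy),
            )
    return points


def game_jacobian(
    state: GameState, pm: PayoffMatrix, rates: GameRates
) -> np.ndarray:
    """2x2 Jacobian of the replicator RHS at ``state`` (hand-coded partials)."""
    x1, y1 = state.x1, state.y1
    bx = _bracket_x(pm, rates, y1)
    by = _bracket_y(pm, rates, x1)
    j11 = rates.lambda1 * (1.0 - 2.0 * x1) * bx
    j12 = (
        rates.lambda1
        * x1
        * (1.0 - x1)
        * (1.0 - rates.p21)
        * (pm.b1 - pm.c11 - pm.b2)
    )
    j21 = (
        rates.rho1
        * y1
        * (1.0 - y1)
        * (pm.b3 - pm.c21 - pm.b5 - rates.q21 * (pm.b4 - pm.c21) + rates.q21 * pm.b6)
    )
    j22 = rates.rho1 * (1.0 - 2.0 * y1) * by
    return np.array([[j11, j12], [j21, j22]])


@dataclass(frozen=True)
class EquilibriumReport:
    """A game fixed point with its Jacobian invariants and stability label."""

    point: tuple[float, float]
    jac: np.ndarray
    det: float
    trace: float
    label: str  # one of: ESS, unstable, saddle, degenerate
    interior: bool

    def to_dict(self) -> dict:
        return {
            "point": list(self.point),
            "jacobian": self.jac.tolist(),
            "det": self.det,
            "trace": self.trace,
            "label": self.label,
            "interior": self.interior,
        }


def classify_equilibrium(
    point: GameState,
    pm: PayoffMatrix,
    rates: GameRates,
    tol: float = SIGN_TOL,
) -> EquilibriumReport:
    """Label a fixed point by the sign pattern of (det J, tr J).

    det > tol and trace < -tol -> ``ESS`` (locally attracting); det > tol
    and trace > tol -> ``unstable``; det < -tol -> ``saddle``; anything
    inside the tolerance band -> ``degenerate``.  Raises ``ValueError`` when
    ``point`` is not a fixed point of the replicator system.
    """
    dx, dy = replicator_rhs(point, pm, rates)
    residual = math.hypot(dx, dy)
    if residual > max(tol, _FIXED_POINT_TOL):
        raise ValueError(
            f"({point.x1}, {point.y1}) is not a replicator fixed point "
            f"(RHS norm {residual:g})"
        )
    jac = game_jacobian(point, pm, rates)
    det = float(np.linalg.det(jac))
    trace = float(np.trace(jac))
    if det > tol and trace < -tol:
        label = "ESS"
    elif det > tol and trace > tol:
        label = "unstable"
    elif det < -tol:
        label = "saddle"
    else:
        label = "degenerate"
    interior = tol < point.x1 < 1.0 - tol and tol < point.y1 < 1.0 - tol
    return EquilibriumReport(
        point=(point.x1, point.y1),
        jac=jac,
        det=det,
        trace=trace,
        label=label,
        interior=interior,
    )


@dataclass(frozen=True)
class GameClassification:
    """Outcome of the scenario-level sign-condition case analysis."""

    case: str  # "I.1".."I.4", "II.1".."II.8" or "numeric"
    ess: tuple[tuple[float, float], ...]
    degenerate: bool
    conditions: Mapping[str, float]
    reports: tuple[EquilibriumReport, ...]

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "ess": [list(p) for p in self.ess],
            "degenerate": self.degenerate,
            "conditions": dict(self.conditions),
            "equilibria": [r.to_dict() for r in self.reports],
        }


# ESS corner per sub-case of the two tabulated degenerate regimes.
_CASE_I_ESS = {
    ("-", "-"): ("I.1", (0.0, 0.0)),
    ("-", "+"): ("I.2", (0.0, 1.0)),
    ("+", "-"): ("I.3", (1.0, 0.0)),
    ("+", "+"): ("I.4", (1.0, 1.0)),
}
# Keyed on the signs of (g1, g0, g2); covers all eight combinations.
_CASE_II_ESS = {
    ("-", "-", "-"): ("II.1", (0.0, 0.0)),
    ("+", "-", "-"): ("II.2", (0.0, 0.0)),
    ("-", "+", "-"): ("II.3", (1.0, 0.0)),
    ("+", "-", "+"): ("II.4", (1.0, 1.0)),
    ("-", "-", "+"): ("II.5", (0.0, 1.0)),
    ("-", "+", "+"): ("II.6", (0.0, 1.0)),
    ("+", "+", "-"): ("II.7", (1.0, 0.0)),
    ("+", "+", "+"): ("II.8", (1.0, 1.0)),
}


def _sign(value: float, tol: float) -> str:
    if value > tol:
        return "+"
    if value < -tol:
        return "-"
    return "0"


def classify_scenario(
    pm: PayoffMatrix, rates: GameRates, tol: float = SIGN_TOL
) -> GameClassification:
    """Decide which tabulated sign-condition case a parameter set falls in.

    The deciding quantities are::

        g1 = (b1-c1-c11+c21) - p21*(b1-c1-c11)   # x-bracket at y1 = 1
        g0 = (b2-c1+c21)   - p21*(b2-c1)         # x-bracket at y1 = 0
        g2 = (b3-c21)      - q21*(b4-c21)        # y-bracket at x1 = 1
        d1 = b5-b3+c21 + q21*(b4-c21) - q21*b6   # y-bracket degeneracy
        d2 = (1-p21)*(b2+c11-b1)                 # x-bracket degeneracy

    ``d1 = d2 = 0`` selects the first tabulated regime (four sub-cases keyed
    on the signs of g1 and g2); ``d1 = 0, d2 != 0`` the second (eight
    sub-cases keyed on g1, g0, g2).  Any other regime — or a deciding
    quantity inside the tolerance band — falls back to numeric
    per-equilibrium classification, which is always attached.
    """
    g1 = (pm.b1 - pm.c1 - pm.c11 + pm.c21) - rates.p21 * (pm.b1 - pm.c1 - pm.c11)
    g0 = (pm.b2 - pm.c1 + pm.c21) - rates.p21 * (pm.b2 - pm.c1)
    g2 = (pm.b3 - pm.c21) - rates.q21 * (pm.b4 - pm.c21)
    d1 = pm.b5 - pm.b3 + pm.c21 + rates.q21 * (pm.b4 - pm.c21) - rates.q21 * pm.b6
    d2 = (1.0 - rates.p21) * (pm.b2 + pm.c11 - pm.b1)
    conditions = {"g1": g1, "g0": g0, "g2": g2, "d1": d1, "d2": d2}

    reports = tuple(
        classify_equilibrium(pt, pm, rates, tol) for pt in find_equilibria(pm, rates)
    )
    numeric_ess = tuple(r.point for r in reports if r.label == "ESS")

    case: str | None = None
    ess: tuple[tuple[float, float], ...] = ()
    degenerate = False
    if abs(d1) <= tol and abs(d2) <= tol:
        key = (_sign(g1, tol), _sign(g2, tol))
        if "0" in key:
            degenerate = True
        else:
            case, corner = _CASE_I_ESS[key]
            ess = (corner,)
    elif abs(d1) <= tol:
        key = (_sign(g1, tol), _sign(g0, tol), _sign(g2, tol))
        if "0" in key:
            degenerate = True
        else:
            case, corner = _CASE_II_ESS[key]
            ess = (corner,)
    if case is None:
        # Untabulated parameter region or a condition on the sign boundary:
        # report the numeric per-equilibrium classification instead.
        case = "numeric"
        ess = numeric_ess
    return GameClassification(
        case=case,
        ess=ess,
        degenerate=degenerate,
        conditions=conditions,
        reports=reports,
    )


# ---------------------------------------------------------------------------
# Delayed SEIR panic model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpiParams:
    """Rates of the delayed SEIR panic model.

    ``a`` is the population inflow (individuals per unit time), ``beta`` the
    transmission coefficient, ``alpha`` the incidence saturation (per
    individual), ``gamma`` the recovery rate of infectives, ``m`` the
    authority of the official opinion field (per unit time) and ``tau`` the
    incubation delay (time units, >= 0).
    """

    a: float = 1.0
    beta: float = 0.2
    alpha: float = 1.0
    gamma: float = 0.5
    m: float = 0.5
    tau: float = 0.0

    def __post_init__(self) -> None:
        problems = []
        for name in ("a", "beta", "alpha", "gamma", "m"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0 (got {getattr(self, name)})")
        if self.tau < 0:
            problems.append(f"tau must be >= 0 (got {self.tau})")
        if problems:
            raise ValueError("invalid EpiParams: " + "; ".join(problems))


@dataclass(frozen=True)
class EpiState:
    """Compartment sizes (individuals).  ``R`` defaults to 0 for the
    decoupled three-compartment form."""

    S: float
    E: float
    I: float
    R: float = 0.0

    def __post_init__(self) -> None:
        if min(self.S, self.E, self.I, self.R) < 0:
            raise ValueError(
                f"negative compartment in ({self.S}, {self.E}, {self.I}, {self.R})"
            )

    def as_array(self, with_r: bool = True) -> np.ndarray:
        if with_r:
            return np.array([self.S, self.E, self.I, self.R])
        return np.array([self.S, self.E, self.I])


def holling_incidence(S: float, I_lag: float, beta: float, alpha: float) -> float:
    """Saturated new-infection flux ``beta*S*I_lag / (1 + alpha*I_lag)``.

    With ``alpha = 0`` this is the mass-action limit ``beta*S*I_lag``.
    """
    if S < 0 or I_lag < 0:
        raise ValueError(f"negative input to incidence: S={S}, I_lag={I_lag}")
    return beta * S * I_lag / (1.0 + alpha * I_lag)


def _unpack3(state: EpiState | Sequence[float]) -> tuple[float, float, float]:
    if isinstance(state, EpiState):
        return state.S, state.E, state.I
    s, e, i = (float(v) for v in np.asarray(state, dtype=float)[:3])
    return s, e, i


def seir3_rhs(
    state: EpiState | Sequence[float],
    I_lag: float,
    game: GameState,
    p: EpiParams,
) -> np.ndarray:
    """Decoupled (S, E, I) derivatives of the delayed panic model.

    ``dS = a - phi - m*x1*S``; ``dE = phi - m*x2*E - y1*E + y2*I``;
    ``dI = m*x2*E - gamma*I - y2*I`` with the saturated incidence
    ``phi = beta*S*I_lag/(1 + alpha*I_lag)``.  The recovered compartment is
    slaved to these three and is omitted.
    """
    if I_lag < 0:
        raise ValueError(f"negative lagged infective count: {I_lag}")
    S, E, I = _unpack3(state)
    phi = holling_incidence(S, I_lag, p.beta, p.alpha)
    dS = p.a - phi - p.m * game.x1 * S
    dE = phi - p.m * game.x2 * E - game.y1 * E + game.y2 * I
    dI = p.m * game.x2 * E - p.gamma * I - game.y2 * I
    return np.array([dS, dE, dI])


def seir_rhs(
    state: EpiState | Sequence[float],
    I_lag: float,
    game: GameState,
    p: EpiParams,
) -> np.ndarray:
    """Full four-compartment derivatives; they sum to ``a`` identically."""
    if isinstance(state, EpiState):
        S, E, I = state.S, state.E, state.I
    else:
        S, E, I = (float(v) for v in np.asarray(state, dtype=float)[:3])
    dS, dE, dI = seir3_rhs((S, E, I), I_lag, game, p)
    dR = p.gamma * I + p.m * game.x1 * S + game.y1 * E
    return np.array([dS, dE, dI, dR])


def basic_reproduction_number(p: EpiParams, game: GameState) -> float:
    """Threshold quantity ``R = beta*a*x2 / (x1*(m*x2 + y1)*(gamma + y2))``.

    ``R < 1``: panic dies out (the infection-free equilibrium is stable);
    ``R > 1``: a persistent-panic (endemic) equilibrium exists.  Undefined
    (raises) at ``x1 = 0`` or a vanishing denominator.
    """
    if game.x1 <= 0:
        raise ValueError("basic reproduction number undefined at x1 = 0")
    den = game.x1 * (p.m * game.x2 + game.y1) * (p.gamma + game.y2)
    if den == 0:
        raise ValueError(
            f"basic reproduction number undefined: zero denominator at "
            f"(x1={game.x1}, y1={game.y1})"
        )
    return p.beta * p.a * game.x2 / den


def infection_free_equilibrium(p: EpiParams, game: GameState) -> EpiState:
    """Panic-free steady state ``(a/(m*x1), 0, 0)`` of the decoupled model."""
    if game.x1 <= 0:
        raise ValueError("infection-free equilibrium undefined at x1 = 0")
    return EpiState(S=p.a / (p.m * game.x1), E=0.0, I=0.0)


def positive_equilibrium(
    p: EpiParams, game: GameState, residual_tol: float = 1e-10
) -> EpiState | None:
    """Endemic steady state of the decoupled model, or None.

    Exists when ``R > 1``.  The infective level solves the scalar
    steady-state balance ``phi(I)*S(I) = y1*E(I) + gamma*I`` with
    ``S(I) = a/(phi(I) + m*x1)`` and ``E(I) = (gamma+y2)*I/(m*x2)``; the
    bracketed root is polished by a 3-D root find on the full RHS.  Closed
    steady-state relations are asserted on the result, not trusted as the
    solution.  Returns None (with the value of R logged) when ``R <= 1`` or
    no positive root is found.
    """
    R = basic_reproduction_number(p, game)
    if R <= 1.0 or game.x2 <= 0:
        logger.info("no endemic equilibrium: R = %.6g <= 1", R)
        return None
    mx1, mx2 = p.m * game.x1, p.m * game.x2
    c2 = (game.y1 * (p.gamma + game.y2) + p.gamma * mx2) / mx2

    def phi_rate(i: float) -> float:
        return p.beta * i / (1.0 + p.alpha * i)

    def g(i: float) -> float:
        ph = phi_rate(i)
        return ph * p.a / (ph + mx1) - c2 * i

    lo, hi = 1e-12, p.a / c2 + 1.0
    if g(lo) <= 0 or g(hi) >= 0:
        logger.info("no positive root bracketed for the endemic state (R=%g)", R)
        return None
    i_star = optimize.brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    # Initial guess from the closed steady-state relations, then polish the
    # full 3-D fixed-point residual.
    s_guess = (1.0 + p.alpha * i_star) / p.beta * (
        p.beta * p.a / (R * mx1) - game.y2
    )
    if not np.isfinite(s_guess) or s_guess <= 0:
        s_guess = p.a / (phi_rate(i_star) + mx1)
    e_guess = (p.gamma + game.y2) / mx2 * i_star
    sol = optimize.root(
        lambda v: seir3_rhs(v, v[2], game, p),
        x0=np.array([s_guess, e_guess, i_star]),
        tol=1e-13,
    )
    S, E, I = sol.x
    residual = float(np.max(np.abs(seir3_rhs(sol.x, I, game, p))))
    if not sol.success or min(S, E, I) <= 0 or residual > residual_tol:
        logger.warning(
            "endemic root-finding failed (success=%s, residual=%g, R=%g)",
            sol.success, residual, R,
        )
        return None
    if abs(E * mx2 - (p.gamma + game.y2) * I) > 1e-8 * max(1.0, abs(I)):
        raise AssertionError("endemic state violates the E/I steady-state ratio")
    return EpiState(S=S, E=E, I=I)


# ---------------------------------------------------------------------------
# Spectral and Lyapunov stability verification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralReport:
    """Numeric stability evidence for one equilibrium of the delayed model.

    ``tau0_eigenvalues`` is the spectrum of the no-delay Jacobian,
    ``routh_hurwitz_coeffs`` the monic characteristic coefficients
    (a0..a3) of that Jacobian, and ``imaginary_root_scan`` the residual
    ``|P(i w)|^2 - |Q(i w)|^2`` of the delay characteristic split
    ``P(lam) + Q(lam) e^(-lam tau)`` on a frequency grid — its positive
    zeros are frequencies at which some delay could create a pure imaginary
    characteristic root.  ``verdict = stable_all_tau`` requires all no-delay
    eigenvalues strictly in the left half plane *and* an empty root scan.
    """

    regime: str  # "infection_free" or "endemic"
    r_value: float
    equilibrium: tuple[float, float, float]
    tau0_eigenvalues: np.ndarray
    routh_hurwitz_coeffs: tuple[float, float, float, float]
    imaginary_root_scan: pd.DataFrame
    crossing_frequencies: tuple[float, ...]
    verdict: str  # "stable_all_tau", "unstable" or "inconclusive"

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "r_value": self.r_value,
            "equilibrium": list(self.equilibrium),
            "tau0_eigenvalues": [
                {"re": z.real, "im": z.imag} for z in self.tau0_eigenvalues
            ],
            "routh_hurwitz_coeffs": list(self.routh_hurwitz_coeffs),
            "crossing_frequencies": list(self.crossing_frequencies),
            "verdict": self.verdict,
        }


def _seir3_jacobian_split(
    point: Sequence[float], game: GameState, p: EpiParams
) -> tuple[np.ndarray, np.ndarray]:
    """(A, B) with d/dt delta = A*delta(t) + B*delta(t - tau) at ``point``."""
    S, E, I = (float(v) for v in point)
    phi = p.beta * I / (1.0 + p.alpha * I)  # per-susceptible incidence rate
    dphi = p.beta / (1.0 + p.alpha * I) ** 2
    mx1, mx2 = p.m * game.x1, p.m * game.x2
    A = np.array(
        [
            [-phi - mx1, 0.0, 0.0],
            [phi, -(mx2 + game.y1), game.y2],
            [0.0, mx2, -(p.gamma + game.y2)],
        ]
    )
    B = np.zeros((3, 3))
    B[0, 2] = -S * dphi
    B[1, 2] = S * dphi
    return A, B


def stability_report(
    p: EpiParams,
    game: GameState,
    regime: str = "infection_free",
    omega_max: float | None = None,
    n_grid: int = 10_000,
) -> SpectralReport:
    """Numeric stability verification of one equilibrium of the delayed model.

    Builds the no-delay Jacobian ``A + B`` at the requested equilibrium and
    reports its eigenvalues and characteristic (Routh-Hurwitz) coefficients,
    then scans frequencies for pure-imaginary characteristic roots of the
    delay system ``det(lam*I - A - B e^(-lam tau)) = 0``: such a root exists
    for some delay iff ``|P(i w)| = |Q(i w)|`` for some ``w > 0``, where
    ``P = det(lam*I - A)`` and ``Q`` is the remainder.  A no-delay stable
    spectrum plus an empty scan certifies stability for every ``tau >= 0``.
    """
    if regime == "infection_free":
        eq = infection_free_equilibrium(p, game)
    elif regime == "endemic":
        eq_opt = positive_equilibrium(p, game)
        if eq_opt is None:
            raise ValueError(
                "no endemic equilibrium for the supplied parameters "
                f"(R = {basic_reproduction_number(p, game):.6g})"
            )
        eq = eq_opt
    else:
        raise ValueError(f"unknown regime {regime!r}")
    point = eq.as_array(with_r=False)
    residual = float(np.max(np.abs(seir3_rhs(point, point[2], game, p))))
    if residual > 1e-8:
        raise ValueError(f"supplied point is not an equilibrium (residual {residual:g})")

    A, B = _seir3_jacobian_split(point, game, p)
    M0 = A + B
    eigs = np.linalg.eigvals(M0)
    coeffs = tuple(float(c) for c in np.poly(M0))  # a0=1, a1, a2, a3

    # Split characteristic function: P from the no-lag part, Q = full - P.
    pc = np.poly(A)
    qc = np.poly(M0) - pc  # degree <= 2 (rank-one lag coupling)

    if omega_max is None:
        scale = max(
            p.m, p.gamma, 1.0, float(np.max(np.abs(eigs))), p.beta * point[0]
        )
        omega_max = 10.0 * scale
    omega = np.linspace(omega_max / n_grid, omega_max, n_grid)
    pv = np.polyval(pc, 1j * omega)
    qv = np.polyval(qc, 1j * omega)
    F = np.abs(pv) ** 2 - np.abs(qv) ** 2

    def f_scalar(w: float) -> float:
        return float(
            abs(np.polyval(pc, 1j * w)) ** 2 - abs(np.polyval(qc, 1j * w)) ** 2
        )

    crossings: list[float] = []
    sign_change = np.nonzero(np.sign(F[:-1]) * np.sign(F[1:]) < 0)[0]
    for idx in sign_change:
        crossings.append(
            float(optimize.brentq(f_scalar, omega[idx], omega[idx + 1]))
        )

    max_re = float(np.max(eigs.real))
    if max_re > 1e-10:
        verdict = "unstable"
    elif max_re < -1e-10 and not crossings:
        verdict = "stable_all_tau"
    else:
        verdict = "inconclusive"

    try:
        r_value = basic_reproduction_number(p, game)
    except ValueError:
        r_value = float("nan")
    scan = pd.DataFrame({"omega": omega, "residual": F})
    return SpectralReport(
        regime=regime,
        r_value=r_value,
        equilibrium=tuple(point),
        tau0_eigenvalues=eigs,
        routh_hurwitz_coeffs=coeffs,
        imaginary_root_scan=scan,
        crossing_frequencies=tuple(crossings),
        verdict=verdict,
    )


def lyapunov_descent(
    traj: "Trajectory",
    p: EpiParams,
    game: GameState,
    which: str = "L1",
    equilibrium: EpiState | None = None,
) -> np.ndarray:
    """Sampled dL/dt of a Lyapunov candidate along a computed trajectory.

    ``which="L1"`` (infection-free regime) uses the Volterra-type candidate
    ``L1 = S - S0 - S0*ln(S/S0) + E + I + int_{t-tau}^{t} beta*S0*I/(1+alpha*I)``
    with ``S0 = a/(m*x1)``; its descent is guaranteed when ``R < 1`` and
    ``gamma > beta*a/(m*x1)``.  ``which="L2"`` (endemic regime) uses
    ``L2 = ((S-S*) + (E-E*) + (I-I*))^2``.  Returns finite-difference dL/dt
    samples on the trajectory grid; for a trajectory resting at the
    equilibrium they are identically zero.
    """
    t = traj.t
    S = traj.component("S")
    E = traj.component("E")
    I = traj.component("I")
    if which == "L1":
        s0 = p.a / (p.m * game.x1)
        L = S - s0 - s0 * np.log(S / s0) + E + I
        if p.tau > 0:
            g = p.beta * s0 * I / (1.0 + p.alpha * I)
            dt = float(t[1] - t[0])
            k = int(round(p.tau / dt))
            g_pad = np.concatenate([np.full(k, g[0]), g])  # constant pre-history
            integral = np.array(
                [np.trapezoid(g_pad[i : i + k + 1], dx=dt) for i in range(len(t))]
            )
            L = L + integral
    elif which == "L2":
        if equilibrium is None:
            equilibrium = positive_equilibrium(p, game)
            if equilibrium is None:
                raise ValueError("L2 requires an endemic equilibrium")
        L = (
            (S - equilibrium.S) + (E - equilibrium.E) + (I - equilibrium.I)
        ) ** 2
    else:
        raise ValueError(f"unknown Lyapunov candidate {which!r}")
    return np.gradient(L, t)


# ---------------------------------------------------------------------------
# Time integration: RK4 method of steps with Hermite lag interpolation
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """A simulated path: strictly increasing time grid plus named columns."""

    t: np.ndarray
    columns: tuple[str, ...]
    values: np.ndarray  # shape (len(t), len(columns))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.values.shape != (self.t.size, len(self.columns)):
            raise ValueError("trajectory values shape mismatch")

    def __len__(self) -> int:
        return self.t.size

    def component(self, name: str) -> np.ndarray:
        if name not in self.columns:
            raise KeyError(f"unknown component {name!r}; have {self.columns}")
        return self.values[:, self.columns.index(name)]

    @property
    def final(self) -> dict[str, float]:
        return {c: float(self.values[-1, i]) for i, c in enumerate(self.columns)}

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.columns))
        frame.insert(0, "time", self.t)
        return frame

    def to_csv(self, path: str | Path) -> Path:
        """Tidy CSV with '#'-prefixed metadata header lines."""
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for key in sorted(self.meta):
                fh.write(f"# {key} = {self.meta[key]}\n")
            self.to_frame().to_csv(fh, index=False)
        return path


def _hermite(y0: float, y1: float, f0: float, f1: float, h: float, th: float) -> float:
    """Cubic Hermite value at fraction ``th`` of a step of width ``h``."""
    th2 = th * th
    th3 = th2 * th
    return (
        (2 * th3 - 3 * th2 + 1) * y0
        + (th3 - 2 * th2 + th) * h * f0
        + (-2 * th3 + 3 * th2) * y1
        + (th3 - th2) * h * f1
    )


def _integrate_dde(
    f: Callable[[float, np.ndarray, float], np.ndarray],
    y0: Sequence[float],
    t_end: float,
    dt: float,
    tau: float,
    lag_index: int,
    history: Callable[[float], float] | None,
    nonneg: Sequence[int] = (),
    unit: Sequence[int] = (),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Fixed-step RK4 method of steps for one constant-lag scalar term.

    ``f(t, y, lag)`` receives the scalar lagged component value.  For
    ``tau > 0`` the step is shrunk so that ``tau`` is an integer multiple of
    ``dt`` with at least 20 steps per delay; lag reads at RK substeps use
    cubic Hermite interpolation of the stored solution (grid values plus
    stage-one derivatives), which keeps the lag read at fourth-order
    accuracy.  ``nonneg``/``unit`` index components whose admissible ranges
    are enforced with a 1e-9 / 1e-6 slack; a violation aborts with guidance.

    Returns ``(t, Y, F, dt_actual)`` with ``F`` the grid derivatives.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    y0 = np.asarray(y0, dtype=float)
    if tau > 0:
        k = max(20, int(math.ceil(tau / dt - 1e-12)))
        if abs(tau / dt - round(tau / dt)) > 1e-12 or tau / dt < 20:
            logger.debug("dt adjusted from %g to %g so that tau = k*dt", dt, tau / k)
        dt = tau / k
        if history is None:
            i0 = float(y0[lag_index])
            history = lambda s: i0  # noqa: E731 - constant pre-history
    n = int(math.ceil(t_end / dt - 1e-9))
    t = dt * np.arange(n + 1)
    Y = np.empty((n + 1, y0.size))
    F = np.empty_like(Y)
    Y[0] = y0

    def lag_at(s: float, i_done: int) -> float:
        if s <= 1e-15:
            return float(history(s))
        x = s / dt
        j = int(math.floor(x + 1e-9))
        th = x - j
        if th < 1e-9:
            return float(Y[j, lag_index])
        return _hermite(
            Y[j, lag_index], Y[j + 1, lag_index],
            F[j, lag_index], F[j + 1, lag_index],
            dt, th,
        )

    for i in range(n):
        ti = t[i]
        y = Y[i]
        if tau == 0:
            k1 = f(ti, y, float(y[lag_index]))
            y2 = y + 0.5 * dt * k1
            k2 = f(ti + 0.5 * dt, y2, float(y2[lag_index]))
            y3 = y + 0.5 * dt * k2
            k3 = f(ti + 0.5 * dt, y3, float(y3[lag_index]))
            y4 = y + dt * k3
            k4 = f(ti + dt, y4, float(y4[lag_index]))
        else:
            lag_mid = lag_at(ti + 0.5 * dt - tau, i)
            k1 = f(ti, y, lag_at(ti - tau, i))
            F[i] = k1
            k2 = f(ti + 0.5 * dt, y + 0.5 * dt * k1, lag_mid)
            k3 = f(ti + 0.5 * dt, y + 0.5 * dt * k2, lag_mid)
            k4 = f(ti + dt, y + dt * k3, lag_at(ti + dt - tau, i))
        if tau == 0:
            F[i] = k1
        ynew = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(ynew)):
            raise RuntimeError(
                f"nonfinite state at t = {ti + dt:g}: {ynew}; "
                "the step size is probably too large for these rates"
            )
        for idx in nonneg:
            if ynew[idx] < -1e-9:
                raise RuntimeError(
                    f"component {idx} went negative ({ynew[idx]:g}) at "
                    f"t = {ti + dt:g}; reduce dt"
                )
        for idx in unit:
            if ynew[idx] < -1e-6 or ynew[idx] > 1.0 + 1e-6:
                raise RuntimeError(
                    f"probability component {idx} left [0,1] "
                    f"({ynew[idx]:g}) at t = {ti + dt:g}"
                )
        Y[i + 1] = ynew
    if tau == 0:
        F[n] = f(t[n], Y[n], float(Y[n, lag_index]))
    else:
        F[n] = f(t[n], Y[n], lag_at(t[n] - tau, n - 1))
    return t, Y, F, dt


def integrate_game(
    initial: GameState,
    pm: PayoffMatrix,
    rates: GameRates,
    t_end: float = 50.0,
    dt: float = 0.01,
) -> Trajectory:
    """Fixed-step RK4 solution of the pure opinion-field game.

    No clamping is applied: trajectories started inside the unit square
    stay there up to integration tolerance because the corners absorb the
    dynamics.
    """
    def f(t: float, y: np.ndarray, _lag: float) -> np.ndarray:
        x1, y1 = y
        dx = rates.lambda1 * x1 * (1.0 - x1) * _bracket_x(pm, rates, y1)
        dy = rates.rho1 * y1 * (1.0 - y1) * _bracket_y(pm, rates, x1)
        return np.array([dx, dy])

    t, Y, _, dt_actual = _integrate_dde(
        f, (initial.x1, initial.y1), t_end, dt, 0.0, 0, None, unit=(0, 1)
    )
    return Trajectory(
        t=t,
        columns=("x1", "y1"),
        values=Y,
        meta={"dt": dt_actual, "tau": 0.0, "scheme": "rk4"},
    )


def _coupled_f(
    pm: PayoffMatrix, rates: GameRates, p: EpiParams
) -> Callable[[float, np.ndarray, float], np.ndarray]:
    def f(t: float, y: np.ndarray, i_lag: float) -> np.ndarray:
        x1, y1, S, E, I, _R = y
        dx = rates.lambda1 * x1 * (1.0 - x1) * _bracket_x(pm, rates, y1)
        dy = rates.rho1 * y1 * (1.0 - y1) * _bracket_y(pm, rates, x1)
        i_lag = max(i_lag, 0.0)  # interpolation can undershoot a decaying I
        phi = p.beta * S * i_lag / (1.0 + p.alpha * i_lag)
        x2 = 1.0 - x1
        yy2 = 1.0 - y1
        dS = p.a - phi - p.m * x1 * S
        dE = phi - p.m * x2 * E - y1 * E + yy2 * I
        dI = p.m * x2 * E - p.gamma * I - yy2 * I
        dR = p.gamma * I + p.m * x1 * S + y1 * E
        return np.array([dx, dy, dS, dE, dI, dR])

    return f


def integrate_coupled(
    initial_game: GameState,
    initial_epi: EpiState,
    pm: PayoffMatrix,
    rates: GameRates,
    p: EpiParams,
    t_end: float = 200.0,
    dt: float = 0.01,
    history: Callable[[float], float] | None = None,
) -> Trajectory:
    """Method-of-steps RK4 for the coupled game + delayed SEIR system.

    The game subsystem feeds ``(x1, y1)`` into the epidemic rates at every
    RK stage; nothing feeds back, so the game sub-trajectory is identical to
    :func:`integrate_game` at the same step size.  The lagged ``I(t - tau)``
    is read from the stored solution (cubic Hermite between grid points);
    the pre-history defaults to the constant ``I(0)`` and may be overridden
    with any nonnegative function of time on ``[-tau, 0]``.
    """
    y0 = np.array(
        [initial_game.x1, initial_game.y1,
         initial_epi.S, initial_epi.E, initial_epi.I, initial_epi.R]
    )
    t, Y, _, dt_actual = _integrate_dde(
        _coupled_f(pm, rates, p), y0, t_end, dt, p.tau, 4, history,
        nonneg=(2, 3, 4, 5), unit=(0, 1),
    )
    return Trajectory(
        t=t,
        columns=("x1", "y1", "S", "E", "I", "R"),
        values=Y,
        meta={"dt": dt_actual, "tau": p.tau, "scheme": "rk4-method-of-steps"},
    )


def integrate_epi(
    initial: EpiState,
    game: GameState,
    p: EpiParams,
    t_end: float = 200.0,
    dt: float = 0.01,
    history: Callable[[float], float] | None = None,
) -> Trajectory:
    """Delayed SEIR integration at *frozen* strategy probabilities.

    Used for equilibrium-convergence and Lyapunov-descent checks, where the
    stability statements hold the game state fixed.
    """
    def f(t: float, y: np.ndarray, i_lag: float) -> np.ndarray:
        i_lag = max(i_lag, 0.0)
        return seir_rhs(y, i_lag, game, p)

    y0 = initial.as_array()
    t, Y, _, dt_actual = _integrate_dde(
        f, y0, t_end, dt, p.tau, 2, history, nonneg=(0, 1, 2, 3)
    )
    return Trajectory(
        t=t,
        columns=("S", "E", "I", "R"),
        values=Y,
        meta={"dt": dt_actual, "tau": p.tau, "scheme": "rk4-method-of-steps",
              "x1": game.x1, "y1": game.y1},
    )


def steady_state_time(
    traj: Trajectory,
    component: str,
    target: float,
    eps: float = 0.01,
) -> float | None:
    """Earliest grid time after which ``|component - target| <= eps`` holds
    through the end of the trajectory (hold-to-end semantics), or None.

    A trajectory that leaves the band after entering it is timed from the
    *last* entry.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    inside = np.abs(traj.component(component) - target) <= eps
    outside = np.nonzero(~inside)[0]
    if outside.size == 0:
        return float(traj.t[0])
    first_held = outside[-1] + 1
    if first_held >= len(traj):
        return None
    return float(traj.t[first_held])


@dataclass
class DelaySweep:
    """Delay-sweep result: one trajectory per tau plus a summary table."""

    taus: tuple[float, ...]
    trajectories: list[Trajectory]
    summary: pd.DataFrame


def delay_sweep(
    scenario: "Scenario",
    taus: Iterable[float],
    eps: float = 0.01,
) -> DelaySweep:
    """Integrate the coupled model once per delay, all else identical.

    The summary records, per tau, the susceptible trough (the extremum of
    the dip-and-recover transient) with its time, the maximum of S, and the
    time for the exposed compartment to enter and hold the ``eps`` band
    around zero.
    """
    taus = tuple(float(x) for x in taus)
    if any(x < 0 for x in taus):
        raise ValueError("delays must be >= 0")
    trajectories = []
    rows = []
    for tau in taus:
        p = replace(scenario.epi, tau=tau)
        traj = integrate_coupled(
            scenario.game0, scenario.epi0, scenario.payoffs, scenario.rates, p,
            t_end=scenario.t_end_coupled, dt=scenario.dt,
        )
        trajectories.append(traj)
        S = traj.component("S")
        i_trough = int(np.argmin(S))
        rows.append(
            {
                "tau": tau,
                "S_trough": float(S[i_trough]),
                "S_trough_time": float(traj.t[i_trough]),
                "S_max": float(S.max()),
                "E_settle_time": steady_state_time(traj, "E", 0.0, eps),
            }
        )
    return DelaySweep(taus=taus, trajectories=trajectories,
                      summary=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Scenarios, sensitivity surfaces and reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation setup: parameters, initials, solver."""

    name: str
    payoffs: PayoffMatrix
    rates: GameRates
    epi: EpiParams
    game0: GameState
    epi0: EpiState
    dt: float = 0.01
    t_end_game: float = 50.0
    t_end_coupled: float = 200.0
    eps: float = 0.01

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end_game <= 0 or self.t_end_coupled <= 0:
            raise ValueError("dt and horizons must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def _baseline() -> Scenario:
    return Scenario(
        name="baseline",
        payoffs=PayoffMatrix(b1=15, b2=10, b3=7, b4=5, b5=3, b6=1,
                             c1=5, c11=5, c21=4),
        rates=GameRates(lambda1=1.0, rho1=1.0, p21=1.0, q21=1.0),
        epi=EpiParams(a=1.0, beta=0.2, alpha=1.0, gamma=0.5, m=0.5, tau=1.0),
        game0=GameState(x1=0.6, y1=0.5),
        epi0=EpiState(S=2.0, E=8.0, I=10.0, R=0.0),
    )


PRESETS: dict[str, Callable[[], Scenario]] = {"baseline": _baseline}

# Config schema: section -> (target dataclass keys)
_CONFIG_SCHEMA = {
    "payoffs": ("b1", "b2", "b3", "b4", "b5", "b6", "c1", "c11", "c21"),
    "rates": ("lambda1", "rho1", "p21", "q21"),
    "epi": ("a", "beta", "alpha", "gamma", "m", "tau"),
    "initial": ("x1", "y1", "s", "e", "i", "r"),
    "solver": ("dt", "t_end_game", "t_end_coupled", "eps"),
}


def load_scenario(source: str | Path) -> Scenario:
    """Resolve a preset name or parse a flat key=value scenario config.

    Config files are INI-style with sections ``[payoffs]``, ``[rates]``,
    ``[epi]``, ``[initial]`` and ``[solver]``; keys omitted fall back to the
    ``baseline`` preset, so a config is a diff against it.  Unknown sections
    or keys are rejected with every offending name listed.  Every resolved
    parameter is echoed to the log.
    """
    if isinstance(source, str) and source in PRESETS:
        scenario = PRESETS[source]()
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"{source!r} is neither a preset ({sorted(PRESETS)}) nor a file"
            )
        parser = configparser.ConfigParser()
        with open(path, encoding="utf-8") as fh:
            parser.read_file(fh)
        bad = []
        values: dict[str, dict[str, float]] = {}
        for section in parser.sections():
            if section not in _CONFIG_SCHEMA:
                bad.append(f"[{section}]")
                continue
            values[section] = {}
            for key, raw in parser.items(section):
                if key not in _CONFIG_SCHEMA[section]:
                    bad.append(f"[{section}] {key}")
                    continue
                try:
                    values[section][key] = float(raw)
                except ValueError:
                    bad.append(f"[{section}] {key} = {raw!r} (not a number)")
        if bad:
            raise ValueError("invalid scenario config: " + ", ".join(bad))
        base = _baseline()
        pv = {**{k: getattr(base.payoffs, k) for k in _CONFIG_SCHEMA["payoffs"]},
              **values.get("payoffs", {})}
        rv = {**{k: getattr(base.rates, k) for k in _CONFIG_SCHEMA["rates"]},
              **values.get("rates", {})}
        ev = {**{k: getattr(base.epi, k) for k in _CONFIG_SCHEMA["epi"]},
              **values.get("epi", {})}
        iv = {"x1": base.game0.x1, "y1": base.game0.y1, "s": base.epi0.S,
              "e": base.epi0.E, "i": base.epi0.I, "r": base.epi0.R,
              **values.get("initial", {})}
        sv = {"dt": base.dt, "t_end_game": base.t_end_game,
              "t_end_coupled": base.t_end_coupled, "eps": base.eps,
              **values.get("solver", {})}
        scenario = Scenario(
            name=path.stem,
            payoffs=PayoffMatrix(**pv),
            rates=GameRates(**rv),
            epi=EpiParams(**ev),
            game0=GameState(x1=iv["x1"], y1=iv["y1"]),
            epi0=EpiState(S=iv["s"], E=iv["e"], I=iv["i"], R=iv["r"]),
            **sv,
        )
    for label, obj in (
        ("payoffs", scenario.payoffs), ("rates", scenario.rates),
        ("epi", scenario.epi), ("initial game", scenario.game0),
        ("initial epi", scenario.epi0),
    ):
        logger.info("scenario %s %s: %s", scenario.name, label, obj)
    logger.info(
        "scenario %s solver: dt=%g t_end_game=%g t_end_coupled=%g eps=%g",
        scenario.name, scenario.dt, scenario.t_end_game,
        scenario.t_end_coupled, scenario.eps,
    )
    return scenario


_SENSITIVITY_PARAMS = ("m", "gamma", "beta")
_DEFAULT_GRIDS = {
    "m": (0.1, 1.0),
    "gamma": (0.1, 1.0),
    "beta": (0.05, 0.5),
}


@dataclass
class SensitivityGrid:
    """Basic-reproduction-number surface over two varied parameters."""

    param_names: tuple[str, str]
    grids: tuple[np.ndarray, np.ndarray]
    values: np.ndarray  # shape (len(grids[0]), len(grids[1]))
    fixed: dict
    monotonicity: dict[str, int]  # +1 increasing, -1 decreasing, 0 mixed

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = pd.DataFrame(
            self.values,
            index=pd.Index(self.grids[0], name=self.param_names[0]),
            columns=pd.Index(self.grids[1], name=self.param_names[1]),
        )
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for key in sorted(self.fixed):
                fh.write(f"# {key} = {self.fixed[key]}\n")
            fh.write(f"# monotonicity = {self.monotonicity}\n")
            frame.to_csv(fh)
        return path


def r_sensitivity(
    p: EpiParams,
    game: GameState,
    vary: tuple[str, str] = ("m", "gamma"),
    grids: tuple[Sequence[float], Sequence[float]] | None = None,
    n: int = 50,
) -> SensitivityGrid:
    """Basic reproduction number on a 2-D parameter grid.

    ``vary`` names two of ``m``, ``gamma``, ``beta``; defaults grids span
    m, gamma in [0.1, 1] and beta in [0.05, 0.5] with ``n`` points.  The
    strategy probabilities are taken from ``game`` (the surface depends on
    them) and recorded in the metadata.  A monotonicity summary holds the
    common sign of the discrete partial differences along each axis.
    """
    for name in vary:
        if name not in _SENSITIVITY_PARAMS:
            raise ValueError(
                f"can only vary {_SENSITIVITY_PARAMS}; got {name!r}"
            )
    if vary[0] == vary[1]:
        raise ValueError("the two varied parameters must differ")
    if game.x1 <= 0:
        raise ValueError("sensitivity surface undefined at x1 = 0")
    if grids is None:
        grids_arr = tuple(
            np.linspace(*_DEFAULT_GRIDS[name], n) for name in vary
        )
    else:
        grids_arr = tuple(np.asarray(g, dtype=float) for g in grids)
    for name, g in zip(vary, grids_arr):
        if np.any(g <= 0):
            raise ValueError(f"grid for {name} must be positive")
    values = np.empty((grids_arr[0].size, grids_arr[1].size))
    for i, v0 in enumerate(grids_arr[0]):
        for j, v1 in enumerate(grids_arr[1]):
            pij = replace(p, **{vary[0]: float(v0), vary[1]: float(v1)})
            values[i, j] = basic_reproduction_number(pij, game)
    mono: dict[str, int] = {}
    for axis, name in enumerate(vary):
        d = np.diff(values, axis=axis)
        if d.size == 0:
            mono[name] = 0
        elif np.all(d > 0):
            mono[name] = 1
        elif np.all(d < 0):
            mono[name] = -1
        else:
            mono[name] = 0
    fixed = {
        name: getattr(p, name)
        for name in ("a", "beta", "alpha", "gamma", "m")
        if name not in vary
    }
    fixed.update({"x1": game.x1, "y1": game.y1})
    return SensitivityGrid(
        param_names=(vary[0], vary[1]),
        grids=grids_arr,  # type: ignore[arg-type]
        values=values,
        fixed=fixed,
        monotonicity=mono,
    )


def run_report(scenario: Scenario, outdir: str | Path | None = None) -> dict:
    """End-to-end deterministic analysis of one scenario.

    Classifies the game, labels all equilibria, integrates both the pure
    game and the coupled delayed model, evaluates the basic reproduction
    number at the initial and at the game's terminal strategy state, and
    records band-entry (steady-state) times for every tracked component.
    Everything is computed before anything is written, so a failing scenario
    leaves no partial outputs.
    """
    classification = classify_scenario(scenario.payoffs, scenario.rates)
    game_traj = integrate_game(
        scenario.game0, scenario.payoffs, scenario.rates,
        t_end=scenario.t_end_game, dt=scenario.dt,
    )
    coupled_traj = integrate_coupled(
        scenario.game0, scenario.epi0, scenario.payoffs, scenario.rates,
        scenario.epi, t_end=scenario.t_end_coupled, dt=scenario.dt,
    )

    def r_or_none(state: GameState) -> float | None:
        try:
            return basic_reproduction_number(scenario.epi, state)
        except ValueError as exc:
            logger.info("R not defined: %s", exc)
            return None

    final = game_traj.final
    game_final = GameState(
        x1=min(max(final["x1"], 0.0), 1.0), y1=min(max(final["y1"], 0.0), 1.0)
    )
    steady = {
        name: steady_state_time(game_traj, name, final[name], scenario.eps)
        for name in ("x1", "y1")
    }
    steady.update(
        {
            name: steady_state_time(
                coupled_traj, name, coupled_traj.final[name], scenario.eps
            )
            for name in ("S", "E", "I")
        }
    )
    report = {
        "scenario": scenario.name,
        "classification": classification.to_dict(),
        "r_initial": r_or_none(scenario.game0),
        "r_game_steady": r_or_none(game_final),
        "game_final": final,
        "coupled_final": coupled_traj.final,
        "steady_state_times": steady,
        "infection_free": bool(
            coupled_traj.final["I"] < 1e-3 and coupled_traj.final["E"] < 1e-3
        ),
        "csv_paths": {},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        game_csv = game_traj.to_csv(outdir / f"{scenario.name}_game.csv")
        coupled_csv = coupled_traj.to_csv(outdir / f"{scenario.name}_coupled.csv")
        report["csv_paths"] = {"game": str(game_csv), "coupled": str(coupled_csv)}
        with open(outdir / f"{scenario.name}_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
    return report
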