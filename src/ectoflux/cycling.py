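"""Energetics and dynamics of the ectoine synthesis/degradation cycle.

Simultaneous synthesis (EctA/EctC) and degradation (DoeA/DoeB) of ectoine
nets acetyl-CoA into acetate; re-ligation by the AMP-forming acetate:CoA
ligase (lumped with pyrophosphatase and adenylate kinase) costs two ATP, so
the cycle drains two ATP per turn.  The payoff is responsiveness: the
turnover (response) time of a metabolite pool -- its steady-state
concentration divided by the flux through it -- sets the timescale on which
the pool can track a new setpoint, and cycling keeps that flux high.

No kinetic rate law is known for the degradation branch; the pool model here
is the minimal one that realizes the turnover-time argument, first-order
degradation d(pool)/dt = synthesis - k * pool.  It is illustrative, not
fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

from .fba import ATP_DRAIN, ECTOINE_EXPORT, GLUCOSE_UPTAKE, INF, solve_fba
from .network import StoichiometricNetwork

__all__ = [
    "CyclingState",
    "CycleBlockedError",
    "cycle_atp_cost",
    "turnover_time",
    "simulate_pool_response",
]

CYCLE_ENTRY = "DOEA"


class CycleBlockedError(RuntimeError):
    """The degradation branch cannot carry the requested cycle flux."""


@dataclass(frozen=True)
class CyclingState:
    """An ectoine pool with its synthesis flux and degradation rate constant.

    Units are arbitrary but consistent: pool in concentration units,
    synthesis_flux in concentration/time, degradation_rate_constant in 1/time.
    At steady state pool = synthesis_flux / degradation_rate_constant.
    """

    pool: float
    synthesis_flux: float
    degradation_rate_constant: float

    def __post_init__(self) -> None:
        for name in ("pool", "synthesis_flux", "degradation_rate_constant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def steady_state_pool(self) -> float:
        k = self.degradation_rate_constant
        if k <= 0:
            raise ValueError("steady-state pool undefined for zero rate constant")
        return self.synthesis_flux / k


def cycle_atp_cost(net: StoichiometricNetwork, cycle_flux: float) -> float:
    """ATP drain rate attributable to running the cycle at ``cycle_flux``.

    Fixes ectoine export and glucose uptake at 0, fixes the ectoine-hydrolase
    flux at ``cycle_flux`` and maximizes the (sign-free) ATP drain; the cost
    is the magnitude of the resulting ATP demand.  Glucose uptake is closed
    so that the LP measures the pure cycle rather than blending it with a
    glucose-to-acetate overflow.  Raises :class:`CycleBlockedError` when the
    degradation branch or re-ligation is silenced.
    """
    if cycle_flux < 0:
        raise ValueError("cycle flux must be non-negative")
    if CYCLE_ENTRY not in net:
        raise CycleBlockedError("cycle blocked: no ectoine hydrolase in the network")
    if cycle_flux == 0:
        return 0.0
    entry = net.reaction(CYCLE_ENTRY)
    if entry.disabled or entry.upper_bound < cycle_flux:
        raise CycleBlockedError("cycle blocked: ectoine hydrolase is disabled")
    fixed = {ECTOINE_EXPORT: 0.0, CYCLE_ENTRY: float(cycle_flux)}
    if GLUCOSE_UPTAKE in net:
        fixed[GLUCOSE_UPTAKE] = 0.0
    sol = solve_fba(
        net,
        objective=ATP_DRAIN,
        direction="max",
        fixed_fluxes=fixed,
        bounds_override={ATP_DRAIN: (-INF, INF)},
        parsimonious=False,
    )
    if not sol.optimal:
        raise CycleBlockedError(f"cycle blocked (status: {sol.status})")
    return -float(sol.objective_value)


def turnover_time(state: CyclingState) -> float:
    """Pool concentration divided by the steady-state flux through it."""
    if state.synthesis_flux <= 0:
        raise ValueError("undefined turnover (no flux)")
    return state.pool / state.synthesis_flux


def simulate_pool_response(
    initial: CyclingState,
    new_synthesis_flux: float,
    horizon: float,
    steps: int,
) -> list[tuple[float, float]]:
    """Trajectory of the pool after a step change of the synthesis flux.

    Integrates d(pool)/dt = synthesis - k * pool with a fixed-step classical
    Runge-Kutta scheme from t = 0 to ``horizon`` in ``steps`` steps; returns
    ``steps + 1`` (time, pool) samples.  For this linear equation the
    integrator tracks the closed form pool* + (pool0 - pool*) exp(-k t) to
    well below 1e-6 at any reasonable step count.
    """
    k = initial.degradation_rate_constant
    if k <= 0:
        raise ValueError("degradation rate constant must be positive")
    if new_synthesis_flux < 0:
        raise ValueError("synthesis flux must be non-negative")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if steps <= 0:
        raise ValueError("steps must be positive")

    def deriv(pool: float) -> float:
        return new_synthesis_flux - k * pool

    h = horizon / steps
    t, pool = 0.0, initial.pool
    out = [(t, pool)]
    for i in range(1, steps + 1):
        k1 = deriv(pool)
        k2 = deriv(pool + 0.5 * h * k1)
        k3 = deriv(pool + 0.5 * h * k2)
        k4 = deriv(pool + h * k3)
        pool = pool + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = i * h
        out.append((t, pool))
    return out


def relaxation_time(state: CyclingState) -> float:
    """Exponential relaxation time 1/k of the linear pool model.

    Equals the turnover time at steady state (pool = flux / k).
    """
    k = state.degradation_rate_constant
    if k <= 0:
        raise ValueError("undefined relaxation time (zero rate constant)")
    return 1.0 / k


def closed_form_pool(
    initial: CyclingState, new_synthesis_flux: float, t: float
) -> float:
    """Analytic solution of the step response, for validation."""
    k = initial.degradation_rate_constant
    target = new_synthesis_flux / k
    return target + (initial.pool - target) * exp(-k * t)
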