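"""Linear-programming core: FBA, flux variability, ATP balance and yields.

All optimizations are ordinary LPs over the steady-state polytope
{v : S v = 0, lb <= v <= ub} assembled in stored network order and solved
with the HiGHS solver (``scipy.optimize.linprog``), so results are
deterministic for identical input ordering.  After the primary optimization a
secondary minimization of total absolute flux picks a canonical
representative among degenerate optima; flux variability analysis remains the
authoritative description of the degeneracy itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
from scipy.optimize import linprog

from .network import INF, StoichiometricNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario

logger = logging.getLogger(__name__)

FEASIBILITY_TOL = 1e-9
ASSERT_TOL = 1e-6

GLUCOSE_UPTAKE = "EX_GLC"
ECTOINE_EXPORT = "EX_ECT"
ATP_DRAIN = "ATPDRAIN"

__all__ = [
    "FluxSolution",
    "FVAResult",
    "MaintenanceLoad",
    "ScenarioInfeasibleError",
    "solve_fba",
    "atp_balance",
    "max_yield",
    "flux_variability",
]


class ScenarioInfeasibleError(RuntimeError):
    """Raised when a scenario cannot satisfy the requested conversion."""


@dataclass(frozen=True)
class MaintenanceLoad:
    """Non-production ATP demand, in ATP per unit glucose taken up."""

    m: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("maintenance load must be non-negative")


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a fixed fraction of the optimum."""

    objective: str
    optimum: float
    fraction: float
    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]


def _assemble(
    net: StoichiometricNetwork,
    fixed_fluxes: Mapping[str, float] | None,
    bounds_override: Mapping[str, tuple[float, float]] | None,
) -> tuple[np.ndarray, list[tuple[float, float]], list[str]]:
    rids = net.reaction_ids
    known = set(rids)
    for mapping in (fixed_fluxes or {}), (bounds_override or {}):
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise KeyError(f"unknown reaction id(s): {', '.join(unknown)}")
    S = net.stoichiometric_matrix()
    bounds = []
    for r in net.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if bounds_override and r.id in bounds_override:
            lb, ub = bounds_override[r.id]
        if fixed_fluxes and r.id in fixed_fluxes:
            lb = ub = fixed_fluxes[r.id]
        bounds.append((lb, ub))
    return S, bounds, rids


def _linprog(c, S, bounds):
    return linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=[(None if lb == -INF else lb, None if ub == INF else ub) for lb, ub in bounds],
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )


def solve_fba(
    net: StoichiometricNetwork,
    objective: str,
    direction: str = "max",
    fixed_fluxes: Mapping[str, float] | None = None,
    bounds_override: Mapping[str, tuple[float, float]] | None = None,
    parsimonious: bool = True,
) -> FluxSolution:
    """Optimize one reaction's flux over the steady-state polytope.

    ``direction`` is ``"max"`` or ``"min"``.  Infeasible or unbounded
    problems are reported through ``status``, not exceptions.  With
    ``parsimonious`` (default) the total absolute flux is minimized at the
    optimal objective value to return a canonical flux vector.
    """
    if objective not in net:
        raise KeyError(f"unknown objective reaction {objective!r}")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    S, bounds, rids = _assemble(net, fixed_fluxes, bounds_override)
    j = rids.index(objective)
    sign = -1.0 if direction == "max" else 1.0
    c = np.zeros(len(rids))
    c[j] = sign
    res = _linprog(c, S, bounds)
    if res.status == 2:
        return FluxSolution("infeasible", None, {})
    if res.status == 3:
        return FluxSolution("unbounded", None, {})
    if not res.success:  # pragma: no cover - solver failure
        raise RuntimeError(f"LP solver failed: {res.message}")
    opt = float(res.x[j])

    x = res.x
    if parsimonious:
        x = _minimize_total_flux(S, bounds, j, opt, fallback=res.x)
    return FluxSolution("optimal", opt, dict(zip(rids, map(float, x))))


def _minimize_total_flux(S, bounds, j, opt, fallback):
    """min sum |v| subject to S v = 0, bounds, v_j = opt (split-variable LP)."""
    n = S.shape[1]
    bounds = list(bounds)
    bounds[j] = (opt, opt)
    # v = p - q with p, q >= 0; |v| <= p + q, so min sum(p + q) gives min sum |v|
    S2 = np.hstack([S, -S])
    c = np.ones(2 * n)
    A_ub, b_ub = [], []
    for i, (lb, ub) in enumerate(bounds):
        if ub != INF:
            row = np.zeros(2 * n)
            row[i], row[n + i] = 1.0, -1.0
            A_ub.append(row)
            b_ub.append(ub)
        if lb != -INF:
            row = np.zeros(2 * n)
            row[i], row[n + i] = -1.0, 1.0
            A_ub.append(row)
            b_ub.append(-lb)
    res = linprog(
        c,
        A_eq=S2,
        b_eq=np.zeros(S.shape[0]),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=[(0, None)] * (2 * n),
        method="highs",
    )
    if not res.success:  # pragma: no cover - degenerate cleanup failure
        return fallback
    return res.x[:n] - res.x[n:]


def atp_balance(net: StoichiometricNetwork, scenario: "Scenario | str") -> float:
    """Net ATP per ectoine at total conversion of glucose to ectoine.

    Glucose uptake and ectoine export are fixed at 1, the ATP drain is opened
    to be free in sign, and the drain flux is maximized: a positive optimum is
    ATP generated alongside synthesis, a negative one is net ATP cost.
    """
    from .scenarios import apply_scenario

    applied = apply_scenario(net, scenario)
    sol = solve_fba(
        applied,
        objective=ATP_DRAIN,
        direction="max",
        fixed_fluxes={GLUCOSE_UPTAKE: 1.0, ECTOINE_EXPORT: 1.0},
        bounds_override={ATP_DRAIN: (-INF, INF)},
        parsimonious=False,
    )
    if not sol.optimal:
        raise ScenarioInfeasibleError(
            f"scenario cannot reach total conversion (status: {sol.status})"
        )
    value = float(sol.objective_value)
    return 0.0 if value == 0 else value  # avoid reporting -0.0


def max_yield(
    net: StoichiometricNetwork,
    scenario: "Scenario | str",
    load: MaintenanceLoad | float = 0.0,
) -> float:
    """Maximum molar ectoine yield per glucose under a maintenance ATP demand.

    Glucose uptake is fixed at 1, the ATP drain is bounded below by the
    maintenance load m, and ectoine export is maximized.  Returns 0 with a
    logged diagnostic when the constraint set is infeasible.
    """
    from .scenarios import apply_scenario

    m = load.m if isinstance(load, MaintenanceLoad) else MaintenanceLoad(float(load)).m
    applied = apply_scenario(net, scenario)
    sol = solve_fba(
        applied,
        objective=ECTOINE_EXPORT,
        direction="max",
        fixed_fluxes={GLUCOSE_UPTAKE: 1.0},
        bounds_override={ATP_DRAIN: (m, INF)},
        parsimonious=False,
    )
    if not sol.optimal:
        logger.warning(
            "max_yield: no feasible flux distribution at maintenance %.6g (%s); yield 0",
            m,
            sol.status,
        )
        return 0.0
    return round(float(sol.objective_value), 6)


def flux_variability(
    net: StoichiometricNetwork,
    scenario: "Scenario | str | None" = None,
    objective: str = ECTOINE_EXPORT,
    fraction: float = 1.0,
    fixed_fluxes: Mapping[str, float] | None = None,
    bounds_override: Mapping[str, tuple[float, float]] | None = None,
    maintenance: float | None = None,
) -> FVAResult:
    """Per-reaction flux min/max at ``objective >= fraction * optimum``.

    The default setup mirrors the yield computation: glucose uptake fixed at
    1 and, if ``maintenance`` is given, the ATP drain bounded below by it.
    Raises :class:`ScenarioInfeasibleError` if the base problem is not optimal.
    """
    from .scenarios import apply_scenario

    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    applied = apply_scenario(net, scenario) if scenario is not None else net
    if fixed_fluxes is None:
        fixed_fluxes = {GLUCOSE_UPTAKE: 1.0} if GLUCOSE_UPTAKE in applied else {}
    overrides = dict(bounds_override or {})
    if maintenance is not None:
        overrides[ATP_DRAIN] = (float(maintenance), INF)

    base = solve_fba(
        applied, objective, "max", fixed_fluxes, overrides, parsimonious=False
    )
    if not base.optimal:
        raise ScenarioInfeasibleError(f"base FBA not optimal (status: {base.status})")
    opt = float(base.objective_value)

    S, bounds, rids = _assemble(applied, fixed_fluxes, overrides)
    j = rids.index(objective)
    # objective >= fraction * optimum, encoded as a bound tightening
    lb, ub = bounds[j]
    bounds[j] = (max(lb, fraction * opt), ub)

    ranges: dict[str, tuple[float, float]] = {}
    for k, rid in enumerate(rids):
        lo_hi = []
        for sign in (1.0, -1.0):
            c = np.zeros(len(rids))
            c[k] = sign
            res = _linprog(c, S, bounds)
            if not res.success:  # pragma: no cover
                raise RuntimeError(f"FVA sub-problem failed for {rid}: {res.message}")
            lo_hi.append(float(res.x[k]))
        lo, hi = lo_hi
        ranges[rid] = (min(lo, hi), max(lo, hi))
    return FVAResult(objective=objective, optimum=opt, fraction=fraction, ranges=ranges)
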