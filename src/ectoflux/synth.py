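"""Synthetic stoichiometric networks with analytically known answers.

Chain networks have a known maximum yield (1) and a known net ATP balance
(the sum of the per-step ATP coefficients); seeded random networks are sized
for the brute-force enumeration oracles; ``knockout`` produces perturbation
variants of any network.  All generators are pure functions of their spec,
seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .fba import INF, solve_fba
from .network import Metabolite, Reaction, StoichiometricNetwork

__all__ = [
    "ChainSpec",
    "RandomNetSpec",
    "generate_chain",
    "generate_random_network",
    "knockout",
]


@dataclass(frozen=True)
class ChainSpec:
    """A linear uptake -> M1 -> ... -> Mn -> export pathway with ATP coupling.

    ``atp_per_step[i]`` is the signed ATP made (+) or spent (-) by step i.
    """

    n_steps: int
    atp_per_step: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "atp_per_step", tuple(self.atp_per_step))
        if self.n_steps < 1:
            raise ValueError("chain needs at least one step")
        if len(self.atp_per_step) != self.n_steps:
            raise ValueError("atp_per_step must have one entry per step")


@dataclass(frozen=True)
class RandomNetSpec:
    """Seeded random network sized for brute-force oracle tests."""

    n_internal: int = 6
    n_reactions: int = 10
    max_coeff: int = 2
    irreversible_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_internal < 2:
            raise ValueError("need at least two internal metabolites")
        if self.n_reactions < 2:
            raise ValueError("need at least one uptake and one export reaction")
        if self.max_coeff < 1:
            raise ValueError("max_coeff must be positive")
        if not 0 <= self.irreversible_fraction <= 1:
            raise ValueError("irreversible_fraction must be in [0, 1]")


def generate_chain(spec: ChainSpec) -> StoichiometricNetwork:
    """Build the chain network for ``spec``.

    Step i converts M(i-1) to M(i); a positive ATP coefficient a couples the
    step to a ADP -> a ATP, a negative one to ATP hydrolysis.  The network
    carries a free reversible ATP drain so the engine's ATP accounting
    applies unchanged; maximum export yield per uptake is 1 and the net ATP
    per unit flux is sum(atp_per_step).
    """
    mets = [Metabolite(id=f"M{i}", name=f"intermediate {i}") for i in range(spec.n_steps + 1)]
    mets += [Metabolite(id="atp", name="ATP"), Metabolite(id="adp", name="ADP")]
    net = StoichiometricNetwork(mets)
    net.add_reaction(Reaction(id="EX_IN", stoichiometry={"M0": Fraction(1)}))
    for i, a in enumerate(spec.atp_per_step, start=1):
        stoich = {f"M{i-1}": Fraction(-1), f"M{i}": Fraction(1)}
        if a:
            stoich["atp"] = Fraction(a)
            stoich["adp"] = Fraction(-a)
        net.add_reaction(Reaction(id=f"S{i}", stoichiometry=stoich))
    net.add_reaction(
        Reaction(id="EX_OUT", stoichiometry={f"M{spec.n_steps}": Fraction(-1)})
    )
    net.add_reaction(
        Reaction(
            id="ATPDRAIN",
            stoichiometry={"atp": Fraction(-1), "adp": Fraction(1)},
            reversible=True,
            lower_bound=-INF,
        )
    )
    return net


def generate_random_network(spec: RandomNetSpec, max_retries: int = 100) -> StoichiometricNetwork:
    """A seeded random network guaranteed to carry a nonzero steady-state flux.

    Contains one uptake (into M1) and one export (out of the last
    metabolite); interior reactions draw 1-2 substrates and 1-2 products
    with integer coefficients up to ``max_coeff``.  Candidates on which the
    uptake-to-export conversion is blocked are rejected and resampled (up to
    ``max_retries``), so oracle property suites never run on a vacuously
    dead network.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_retries):
        net = _sample_network(spec, rng)
        if _has_nonzero_flux(net):
            return net
    raise RuntimeError(
        f"no feasible random network found in {max_retries} draws for {spec}"
    )


def _sample_network(spec: RandomNetSpec, rng: np.random.Generator) -> StoichiometricNetwork:
    mids = [f"M{i+1}" for i in range(spec.n_internal)]
    net = StoichiometricNetwork(Metabolite(id=m) for m in mids)
    net.add_reaction(Reaction(id="EX_IN", stoichiometry={mids[0]: Fraction(1)}))
    net.add_reaction(Reaction(id="EX_OUT", stoichiometry={mids[-1]: Fraction(-1)}))
    for k in range(spec.n_reactions - 2):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.permutation(spec.n_internal)
        subs = picks[:n_sub]
        prods = picks[n_sub : n_sub + n_prod]
        if len(prods) == 0:
            prods = picks[-1:]
        stoich: dict[str, Fraction] = {}
        for i in subs:
            stoich[mids[i]] = Fraction(-int(rng.integers(1, spec.max_coeff + 1)))
        for i in prods:
            stoich[mids[i]] = Fraction(int(rng.integers(1, spec.max_coeff + 1)))
        reversible = bool(rng.random() > spec.irreversible_fraction)
        net.add_reaction(
            Reaction(
                id=f"R{k+1}",
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=-INF if reversible else 0.0,
            )
        )
    return net


def _has_nonzero_flux(net: StoichiometricNetwork) -> bool:
    sol = solve_fba(
        net,
        objective="EX_OUT",
        direction="max",
        bounds_override={rid: _capped(net, rid) for rid in net.reaction_ids},
        parsimonious=False,
    )
    return sol.optimal and sol.objective_value is not None and sol.objective_value > 1e-6


def _capped(net: StoichiometricNetwork, rid: str, cap: float = 10.0) -> tuple[float, float]:
    r = net.reaction(rid)
    lb = max(r.lower_bound, -cap)
    ub = min(r.upper_bound, cap)
    return lb, ub


def knockout(net: StoichiometricNetwork, ids: set[str] | frozenset[str]) -> StoichiometricNetwork:
    """A copy of ``net`` with the listed reactions silenced (bounds [0, 0])."""
    missing = sorted(set(ids) - set(net.reaction_ids))
    if missing:
        raise KeyError(f"cannot knock out unknown reaction id(s): {', '.join(missing)}")
    return net.with_reaction_bounds({rid: (0.0, 0.0) for rid in ids})
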