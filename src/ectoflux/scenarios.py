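"""Named pathway scenarios for the packaged ectoine network.

A scenario is a set of reactions to silence (bounds [0, 0]) and a set to
re-open to their natural bounds; everything else keeps its current bounds.
The built-in scenarios reproduce the three glucose-to-ectoine pathway
variants that differ in ATP balance:

``oren``
    PEP-carboxylase anaplerosis with GS/GOGAT nitrogen assimilation
    (1 ATP per nitrogen) -- costs 2 ATP per ectoine.
``gdh``
    Same carbon routing, nitrogen assimilated by the NADH-dependent
    glutamate dehydrogenase -- ATP-neutral.
``malic``
    Oxaloacetate made from pyruvate via malic enzyme + malate dehydrogenase,
    so both PEP pass through pyruvate kinase -- generates 1 ATP per ectoine.
``synthesis``
    Both anaplerotic and both nitrogen routes open, degradation closed;
    the playground for exhaustive pathway enumeration.
``cycle``
    The full network with the DoeA/DoeB/DoeD/DoeC degradation branch and
    acetate re-ligation active alongside synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import NetworkValidationError, StoichiometricNetwork

__all__ = ["Scenario", "BUILTIN_SCENARIOS", "get_scenario", "apply_scenario"]

_DEGRADATION = ("DOEA", "DOEB", "DOEC", "DOED")


@dataclass(frozen=True)
class Scenario:
    """A named toggle set over reaction ids."""

    name: str
    enabled: frozenset[str] = field(default_factory=frozenset)
    disabled: frozenset[str] = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "enabled", frozenset(self.enabled))
        object.__setattr__(self, "disabled", frozenset(self.disabled))
        overlap = self.enabled & self.disabled
        if overlap:
            raise ValueError(
                f"scenario {self.name!r}: reactions both enabled and disabled: "
                f"{', '.join(sorted(overlap))}"
            )


BUILTIN_SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        Scenario(
            name="oren",
            enabled=frozenset({"PPC", "GS", "GOGAT"}),
            disabled=frozenset({"MAE", "MDH", "GDH", *_DEGRADATION, "NADHOX"}),
            description=(
                "PEP carboxylase anaplerosis, GS/GOGAT nitrogen assimilation; "
                "2 ATP cost per ectoine"
            ),
        ),
        Scenario(
            name="gdh",
            enabled=frozenset({"PPC", "GDH"}),
            disabled=frozenset({"MAE", "MDH", "GS", "GOGAT", *_DEGRADATION, "NADHOX"}),
            description=(
                "PEP carboxylase anaplerosis, glutamate dehydrogenase nitrogen "
                "assimilation; ATP-neutral"
            ),
        ),
        Scenario(
            name="malic",
            enabled=frozenset({"MAE", "MDH", "GDH"}),
            disabled=frozenset({"PPC", "GS", "GOGAT", *_DEGRADATION, "NADHOX"}),
            description=(
                "malic enzyme + malate dehydrogenase anaplerosis, GDH nitrogen "
                "assimilation; generates 1 ATP per ectoine"
            ),
        ),
        Scenario(
            name="synthesis",
            enabled=frozenset({"PPC", "MAE", "MDH", "GDH", "GS", "GOGAT"}),
            disabled=frozenset({*_DEGRADATION, "NADHOX"}),
            description="all synthesis variants open, degradation closed",
        ),
        Scenario(
            name="cycle",
            enabled=frozenset({"PPC", "MAE", "MDH", "GDH", "GS", "GOGAT", *_DEGRADATION, "ACS"}),
            disabled=frozenset({"NADHOX"}),
            description="full network with the synthesis/degradation cycle active",
        ),
    ]
}


def get_scenario(scenario: "Scenario | str") -> Scenario:
    if isinstance(scenario, Scenario):
        return scenario
    try:
        return BUILTIN_SCENARIOS[scenario]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario!r}; built-ins: {', '.join(BUILTIN_SCENARIOS)}"
        ) from None


def apply_scenario(
    net: StoichiometricNetwork, scenario: "Scenario | str"
) -> StoichiometricNetwork:
    """A copy of ``net`` with the scenario's toggles applied.

    Disabled reactions get bounds [0, 0]; enabled reactions are restored to
    the natural bounds implied by their reversibility.  Unknown reaction ids
    raise an error naming the offender; the input network is unmodified.
    """
    s = get_scenario(scenario)
    known = set(net.reaction_ids)
    unknown = sorted((s.enabled | s.disabled) - known)
    if unknown:
        raise NetworkValidationError(
            f"scenario {s.name!r} refers to unknown reaction id(s): {', '.join(unknown)}"
        )
    bounds: dict[str, tuple[float, float]] = {}
    for rid in s.disabled:
        bounds[rid] = (0.0, 0.0)
    for rid in s.enabled:
        bounds[rid] = net.reaction(rid).natural_bounds
    return net.with_reaction_bounds(bounds)
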