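"""Exhaustive enumeration of support-minimal steady-state flux patterns.

"All alternative pathways" is formalized as the network's elementary flux
modes: flux vectors v with S v = 0, non-negative flux through irreversible
reactions, and support-minimal (no other admissible steady state uses a
strict subset of their reactions).  Enumeration is exact: reversible
reactions are split into forward/backward halves and the extreme rays of the
resulting pointed cone {v >= 0, S v = 0} are computed with the double
description method in rational arithmetic, after which split halves are
re-merged and the spurious forward+backward two-cycles are discarded.

This is a desk-scale enumerator for curated subsystems, guarded at
``MAX_REACTIONS`` active reactions; restrict the network with a scenario for
anything larger.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd

from .fba import ATP_DRAIN, ECTOINE_EXPORT
from .network import StoichiometricNetwork

__all__ = ["PathwayMode", "NetworkTooLargeError", "enumerate_modes", "classify_mode"]

MAX_REACTIONS = 30


class NetworkTooLargeError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayMode:
    """An elementary flux mode with its net conversion and ATP balance.

    ``fluxes`` holds exact rational fluxes over the mode's support;
    ``net_conversion`` is the implied net production (+) / consumption (-) of
    boundary species; ``net_atp`` is the ATP-drain flux per exported ectoine
    for ectoine-producing modes and None otherwise.
    """

    support: frozenset[str]
    fluxes: dict[str, Fraction]
    net_conversion: dict[str, Fraction]
    net_atp: Fraction | None

    @property
    def produces_ectoine(self) -> bool:
        return self.net_atp is not None


def _normalize_ray(ray: list[Fraction]) -> list[Fraction]:
    """Scale to coprime integers (keeps double-description numbers small)."""
    den = 1
    for x in ray:
        den = den * x.denominator // gcd(den, x.denominator)
    ints = [int(x * den) for x in ray]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    return [Fraction(x) for x in ints]


def _extreme_rays(S: list[list[Fraction]]) -> list[list[Fraction]]:
    """Extreme rays of {v >= 0 : S v = 0} by iterative double description.

    Starts from the standard-basis rays of the positive orthant and
    intersects with one equality at a time; adjacency is decided by the
    combinatorial zero-set test, which is exact for this cone.
    """
    n = len(S[0]) if S else 0
    rays: list[list[Fraction]] = [
        [Fraction(int(i == j)) for j in range(n)] for i in range(n)
    ]
    for row in S:
        if all(x == 0 for x in row):
            continue
        dots = [sum(r * s for r, s in zip(ray, row)) for ray in rays]
        zero = [ray for ray, d in zip(rays, dots) if d == 0]
        plus = [(ray, d) for ray, d in zip(rays, dots) if d > 0]
        minus = [(ray, d) for ray, d in zip(rays, dots) if d < 0]
        new_rays = list(zero)
        zero_sets = [frozenset(j for j, x in enumerate(ray) if x == 0) for ray in rays]
        for rp, dp in plus:
            zp = frozenset(j for j, x in enumerate(rp) if x == 0)
            for rm, dm in minus:
                zm = frozenset(j for j, x in enumerate(rm) if x == 0)
                meet = zp & zm
                adjacent = True
                for ray, zs in zip(rays, zero_sets):
                    if ray is rp or ray is rm:
                        continue
                    if meet <= zs:
                        adjacent = False
                        break
                if adjacent:
                    combo = [dp * xm - dm * xp for xp, xm in zip(rp, rm)]
                    new_rays.append(_normalize_ray(combo))
        rays = new_rays
    return rays


def enumerate_modes(
    net: StoichiometricNetwork,
    max_reactions: int = MAX_REACTIONS,
    ectoine_export: str = ECTOINE_EXPORT,
    atp_drain: str = ATP_DRAIN,
) -> list[PathwayMode]:
    """All elementary flux modes of the active (non-silenced) reactions.

    Modes producing ectoine are normalized to unit ectoine export; all
    others to unit maximum |coefficient|.  Arithmetic is exact throughout.
    """
    active = [r for r in net.reactions if not r.disabled]
    if len(active) > max_reactions:
        raise NetworkTooLargeError(
            f"{len(active)} active reactions exceed the enumeration guard of "
            f"{max_reactions}; restrict the network with a scenario"
        )
    col_ids = [r.id for r in active]
    reversible = [r.reversible and r.lower_bound < 0 for r in active]
    S = net.exact_matrix(columns=col_ids)

    # split reversible columns: v_orig = v_fwd - v_bwd
    split_cols: list[tuple[int, int]] = []  # (original index, sign)
    for j, rev in enumerate(reversible):
        split_cols.append((j, +1))
        if rev:
            split_cols.append((j, -1))
    S_split = [[row[j] * sign for j, sign in split_cols] for row in S]

    modes: list[PathwayMode] = []
    seen: set[tuple] = set()
    for ray in _extreme_rays(S_split):
        v = [Fraction(0)] * len(col_ids)
        for x, (j, sign) in zip(ray, split_cols):
            v[j] += sign * x
        if all(x == 0 for x in v):
            continue  # forward+backward two-cycle from the split
        mode = _finalize(net, col_ids, reversible, v, ectoine_export, atp_drain)
        key = tuple(sorted(mode.fluxes.items()))
        if key not in seen:
            seen.add(key)
            modes.append(mode)
    return modes


def _finalize(net, col_ids, reversible, v, ectoine_export, atp_drain) -> PathwayMode:
    index = {rid: j for j, rid in enumerate(col_ids)}
    export = v[index[ectoine_export]] if ectoine_export in index else Fraction(0)
    if export < 0 and all(reversible[j] for j, x in enumerate(v) if x != 0):
        v = [-x for x in v]
        export = -export
    if export > 0:
        scale = export
    else:
        scale = max(abs(x) for x in v)
        # canonical orientation for fully reversible supports
        if all(reversible[j] for j, x in enumerate(v) if x != 0):
            first = next(x for x in v if x != 0)
            if first < 0:
                v = [-x for x in v]
    v = [x / scale for x in v]

    fluxes = {rid: x for rid, x in zip(col_ids, v) if x != 0}
    conversion = _exact_conversion(net, fluxes)
    net_atp: Fraction | None = None
    if export > 0:
        net_atp = fluxes.get(atp_drain, Fraction(0))
    return PathwayMode(
        support=frozenset(fluxes),
        fluxes=fluxes,
        net_conversion=conversion,
        net_atp=net_atp,
    )


def _exact_conversion(
    net: StoichiometricNetwork, fluxes: dict[str, Fraction]
) -> dict[str, Fraction]:
    """Rational analogue of :func:`ectoflux.network.net_conversion`."""
    out: dict[str, Fraction] = {}
    external = set(net.external_metabolite_ids)
    for rid, flux in fluxes.items():
        r = net.reaction(rid)
        for mid, coef in r.stoichiometry.items():
            if mid in external:
                out[mid] = out.get(mid, Fraction(0)) + coef * flux
        if r.boundary:
            (mid, coef), = r.stoichiometry.items()
            if mid not in external:
                out[mid] = out.get(mid, Fraction(0)) - coef * flux
    return {m: x for m, x in out.items() if x != 0}


def classify_mode(mode: PathwayMode) -> str:
    """Label an enumerated mode by its energetics.

    Ectoine-producing modes are ``cost`` (net ATP < 0), ``neutral`` (= 0) or
    ``generating`` (> 0); everything else is ``non-ectoine``.
    """
    if mode.net_atp is None:
        return "non-ectoine"
    if mode.net_atp < 0:
        return "cost"
    if mode.net_atp > 0:
        return "generating"
    return "neutral"
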