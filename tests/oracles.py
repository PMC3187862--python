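"""Independent oracles for the property suites.

Everything here re-derives results from first principles without touching the
code paths under test: elementary modes by exhaustive subset search using the
rank criterion (a support T carries an elementary mode iff rank(S_T) = |T|-1
and the one-dimensional kernel can be signed to respect irreversibility), and
flux ranges by direct pairs of LPs assembled from the reaction list by hand.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import sympy
from scipy.optimize import linprog


def _active(net):
    return [r for r in net.reactions if not (r.lower_bound == 0 and r.upper_bound == 0)]


def canonical_mode(col_ids, reversible_map, fluxes: dict[str, Fraction]) -> tuple:
    """Scale to max |coeff| = 1 and canonical orientation, as a hashable key."""
    scale = max(abs(x) for x in fluxes.values())
    v = {k: x / scale for k, x in fluxes.items()}
    if all(reversible_map[k] for k in v):
        first = next(v[rid] for rid in col_ids if rid in v and v[rid] != 0)
        if first < 0:
            v = {k: -x for k, x in v.items()}
    return tuple(sorted(v.items()))


def brute_force_efms(net) -> set[tuple]:
    """All elementary flux modes by subset enumeration (exact arithmetic)."""
    active = _active(net)
    col_ids = [r.id for r in active]
    reversible = {r.id: (r.reversible and r.lower_bound < 0) for r in active}
    rows = net.internal_metabolite_ids
    S = sympy.Matrix(
        [
            [sympy.Rational(r.stoichiometry.get(mid, 0)) for r in active]
            for mid in rows
        ]
    )
    n = len(col_ids)
    found: set[tuple] = set()
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            sub = S[:, list(subset)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            g = null[0]
            if any(g[i] == 0 for i in range(size)):
                continue  # smaller support; found at its own subset size
            vals = [Fraction(int(g[i].p), int(g[i].q)) for i in range(size)]
            for sign in (1, -1):
                cand = [sign * x for x in vals]
                ok = all(
                    cand[i] > 0 or reversible[col_ids[subset[i]]]
                    for i in range(size)
                )
                if ok:
                    fluxes = {col_ids[subset[i]]: cand[i] for i in range(size)}
                    found.add(canonical_mode(col_ids, reversible, fluxes))
                    break
    return found


def enumerated_mode_keys(net, modes) -> set[tuple]:
    """Bring enumerator output onto the oracle's canonical form."""
    active = _active(net)
    col_ids = [r.id for r in active]
    reversible = {r.id: (r.reversible and r.lower_bound < 0) for r in active}
    return {canonical_mode(col_ids, reversible, m.fluxes) for m in modes}


def assemble_lp(net, cap: float = 10.0):
    """Steady-state LP data built directly from the reaction list."""
    rids = net.reaction_ids
    rows = net.internal_metabolite_ids
    A = np.zeros((len(rows), len(rids)))
    for j, r in enumerate(net.reactions):
        for mid, coef in r.stoichiometry.items():
            if mid in rows:
                A[rows.index(mid), j] = float(coef)
    bounds = []
    for r in net.reactions:
        lb = max(r.lower_bound, -cap)
        ub = min(r.upper_bound, cap)
        bounds.append((lb, ub))
    return A, bounds, rids


def brute_force_fva(net, objective: str, fraction: float, cap: float = 10.0):
    """Per-reaction (min, max) by direct pairs of LPs."""
    A, bounds, rids = assemble_lp(net, cap)
    j = rids.index(objective)
    c = np.zeros(len(rids))
    c[j] = -1.0
    base = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds, method="highs")
    assert base.success
    opt = base.x[j]
    lb, ub = bounds[j]
    bounds = list(bounds)
    bounds[j] = (max(lb, fraction * opt), ub)
    ranges = {}
    for k, rid in enumerate(rids):
        vals = []
        for sign in (1.0, -1.0):
            c = np.zeros(len(rids))
            c[k] = sign
            res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds, method="highs")
            assert res.success
            vals.append(res.x[k])
        ranges[rid] = (min(vals), max(vals))
    return opt, ranges
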