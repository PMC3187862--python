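"""Stoichiometric network data model and the plain-text reaction-table format.

A network is an ordered collection of metabolites and reactions.  Reaction
stoichiometry is kept as exact rationals (:class:`fractions.Fraction`) so that
atom bookkeeping and elementary-mode arithmetic are exact; only the LP layer
converts to floating point.

The on-disk format is UTF-8 TSV with two sections::

    # METABOLITES
    id<TAB>name<TAB>C<TAB>N<TAB>external
    ...
    # REACTIONS
    id<TAB>equation<TAB>reversible<TAB>lb<TAB>ub<TAB>ec<TAB>gene
    ...

Equations use ``coef met + coef met -> ...`` (or ``<->`` for reversible);
coefficients may be rational literals such as ``1/2``.  A bare line
``R1: glc + 2 nad -> 2 pep + 2 nadh`` is also accepted as shorthand;
undeclared metabolites are created internal with unknown atom counts.
Element counts may be ``?`` (unknown), which exempts the metabolite from
balance checking.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

INF = math.inf

__all__ = [
    "INF",
    "Metabolite",
    "Reaction",
    "StoichiometricNetwork",
    "ReactionTableError",
    "NetworkValidationError",
    "parse_reaction_table",
    "serialize_reaction_table",
    "load_ectoine_model",
    "check_atom_balance",
    "atom_balance_report",
    "net_conversion",
]


class ReactionTableError(ValueError):
    """Malformed reaction-table document (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NetworkValidationError(ValueError):
    """A network violates a structural invariant (duplicate ids, bad bounds...)."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species.

    ``carbons``/``nitrogens`` are atom counts used for balance checking;
    ``None`` marks an unknown count.  ``external`` species are boundary pools
    exchanged with the environment and are excluded from the steady-state
    constraint.
    """

    id: str
    name: str = ""
    carbons: int | None = None
    nitrogens: int | None = None
    external: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")
        for attr in ("carbons", "nitrogens"):
            v = getattr(self, attr)
            if v is not None and (not isinstance(v, int) or v < 0):
                raise NetworkValidationError(
                    f"metabolite {self.id!r}: {attr} must be a non-negative integer or None"
                )

    def element_count(self, element: str) -> int | None:
        if element == "C":
            return self.carbons
        if element == "N":
            return self.nitrogens
        raise ValueError(f"unsupported element {element!r} (only C and N are tracked)")


@dataclass(frozen=True)
class Reaction:
    """A signed stoichiometric conversion with flux bounds.

    Coefficients are negative for consumed species.  ``lower_bound`` and
    ``upper_bound`` are the *current* flux limits; the natural bounds implied
    by ``reversible`` are ``(-inf, inf)`` / ``[0, inf)``.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = INF
    ec: str = ""
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        stoich = {m: Fraction(c) for m, c in self.stoichiometry.items()}
        if not stoich:
            raise NetworkValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if any(c == 0 for c in stoich.values()):
            raise NetworkValidationError(f"reaction {self.id!r}: zero coefficient stored")
        object.__setattr__(self, "stoichiometry", stoich)
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id!r}: lower bound exceeds upper bound"
            )
        if not self.reversible and self.lower_bound < 0:
            raise NetworkValidationError(
                f"reaction {self.id!r}: irreversible reaction with negative lower bound"
            )

    @property
    def natural_bounds(self) -> tuple[float, float]:
        return (-INF, INF) if self.reversible else (0.0, INF)

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)

    @property
    def disabled(self) -> bool:
        return self.lower_bound == 0 and self.upper_bound == 0

    @property
    def boundary(self) -> bool:
        """Single-metabolite exchange/drain reactions are exempt from balance checks."""
        return len(self.stoichiometry) == 1


class StoichiometricNetwork:
    """Ordered metabolite and reaction collections; source of the S matrix.

    Rows of S are the *internal* metabolites in insertion order, columns the
    reactions in insertion order; steady-state flux vectors satisfy S v = 0.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
    ):
        self._metabolites: dict[str, Metabolite] = {}
        self._reactions: dict[str, Reaction] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------

    def add_metabolite(self, m: Metabolite) -> None:
        if m.id in self._metabolites:
            raise NetworkValidationError(f"duplicate metabolite id {m.id!r}")
        self._metabolites[m.id] = m

    def add_reaction(self, r: Reaction) -> None:
        if r.id in self._reactions:
            raise NetworkValidationError(f"duplicate reaction id {r.id!r}")
        missing = [m for m in r.stoichiometry if m not in self._metabolites]
        if missing:
            raise NetworkValidationError(
                f"reaction {r.id!r} references unknown metabolite(s): {', '.join(missing)}"
            )
        self._reactions[r.id] = r

    def copy(self) -> "StoichiometricNetwork":
        return StoichiometricNetwork(self.metabolites, self.reactions)

    def with_reaction_bounds(
        self, bounds: Mapping[str, tuple[float, float]]
    ) -> "StoichiometricNetwork":
        """A copy with the given reactions' bounds replaced (original untouched)."""
        unknown = [r for r in bounds if r not in self._reactions]
        if unknown:
            raise NetworkValidationError(f"unknown reaction id(s): {', '.join(unknown)}")
        new = StoichiometricNetwork(self.metabolites)
        for r in self.reactions:
            if r.id in bounds:
                lb, ub = bounds[r.id]
                r = replace(r, lower_bound=lb, upper_bound=ub, reversible=r.reversible or lb < 0)
            new.add_reaction(r)
        return new

    # -- access ------------------------------------------------------------

    @property
    def metabolites(self) -> list[Metabolite]:
        return list(self._metabolites.values())

    @property
    def reactions(self) -> list[Reaction]:
        return list(self._reactions.values())

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self._metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self._reactions)

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self._metabolites.values() if not m.external]

    @property
    def external_metabolite_ids(self) -> list[str]:
        return [m.id for m in self._metabolites.values() if m.external]

    def metabolite(self, mid: str) -> Metabolite:
        return self._metabolites[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._reactions[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self._reactions

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StoichiometricNetwork):
            return NotImplemented
        return (
            self.metabolites == other.metabolites and self.reactions == other.reactions
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<StoichiometricNetwork: {len(self._metabolites)} metabolites, "
            f"{len(self._reactions)} reactions>"
        )

    # -- matrices ----------------------------------------------------------

    def stoichiometric_matrix(self, rows: Sequence[str] | None = None) -> np.ndarray:
        """S as a dense float array (rows = internal metabolites by default)."""
        row_ids = list(rows) if rows is not None else self.internal_metabolite_ids
        index = {m: i for i, m in enumerate(row_ids)}
        S = np.zeros((len(row_ids), len(self._reactions)))
        for j, r in enumerate(self._reactions.values()):
            for m, c in r.stoichiometry.items():
                i = index.get(m)
                if i is not None:
                    S[i, j] = float(c)
        return S

    def exact_matrix(
        self, rows: Sequence[str] | None = None, columns: Sequence[str] | None = None
    ) -> list[list[Fraction]]:
        """S with exact rational entries, for elementary-mode arithmetic."""
        row_ids = list(rows) if rows is not None else self.internal_metabolite_ids
        col_ids = list(columns) if columns is not None else self.reaction_ids
        index = {m: i for i, m in enumerate(row_ids)}
        S = [[Fraction(0)] * len(col_ids) for _ in row_ids]
        for j, rid in enumerate(col_ids):
            for m, c in self._reactions[rid].stoichiometry.items():
                i = index.get(m)
                if i is not None:
                    S[i][j] = c
        return S

    def flux_array(self, v: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Coerce a flux mapping or sequence to an array in stored reaction order."""
        if isinstance(v, Mapping):
            return np.array([float(v.get(r, 0.0)) for r in self._reactions], dtype=float)
        arr = np.asarray(v, dtype=float)
        if arr.shape != (len(self._reactions),):
            raise ValueError(
                f"flux vector has length {arr.shape}, expected {len(self._reactions)}"
            )
        return arr


# ---------------------------------------------------------------------------
# Reaction-table parsing / serialization
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"<->|->")
_COEF_RE = re.compile(r"^(\d+(?:/\d+)?|\d*\.\d+)$")
_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _parse_side(side: str, sign: int, stoich: dict[str, Fraction], line: int) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ReactionTableError("empty term in equation", line)
        parts = term.split()
        if len(parts) == 1:
            coef, met = Fraction(1), parts[0]
        elif len(parts) == 2 and _COEF_RE.match(parts[0]):
            coef, met = Fraction(parts[0]), parts[1]
        else:
            raise ReactionTableError(f"cannot parse equation term {term!r}", line)
        if not _ID_RE.match(met):
            raise ReactionTableError(f"invalid metabolite id {met!r}", line)
        stoich[met] = stoich.get(met, Fraction(0)) + sign * coef


def parse_equation(eq: str, line: int = 0) -> tuple[dict[str, Fraction], bool]:
    """Parse ``coef met + ... -> ...`` into (net stoichiometry, reversible-arrow)."""
    m = _ARROW_RE.search(eq)
    if not m:
        raise ReactionTableError(f"equation {eq!r} has no '->' or '<->' arrow", line)
    arrow_rev = m.group(0) == "<->"
    lhs, rhs = eq[: m.start()], eq[m.end() :]
    if _ARROW_RE.search(rhs):
        raise ReactionTableError("equation has more than one arrow", line)
    stoich: dict[str, Fraction] = {}
    _parse_side(lhs, -1, stoich, line)
    _parse_side(rhs, +1, stoich, line)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    if not stoich:
        raise ReactionTableError("equation has empty (or fully cancelling) stoichiometry", line)
    return stoich, arrow_rev


def _parse_count(tok: str, line: int) -> int | None:
    tok = tok.strip()
    if tok in ("?", "", "unknown", "NA"):
        return None
    try:
        return int(tok)
    except ValueError:
        raise ReactionTableError(f"invalid element count {tok!r}", line) from None


def _parse_bound(tok: str, line: int) -> float:
    tok = tok.strip()
    try:
        if "/" in tok:
            return float(Fraction(tok))
        return float(tok)
    except ValueError:
        raise ReactionTableError(f"invalid flux bound {tok!r}", line) from None


def _parse_flag(tok: str, line: int) -> bool:
    tok = tok.strip()
    if tok in ("0", "1"):
        return tok == "1"
    raise ReactionTableError(f"expected 0 or 1, got {tok!r}", line)


def parse_reaction_table(document: str) -> StoichiometricNetwork:
    """Parse a reaction-table document into a network.

    Raises :class:`ReactionTableError` naming the offending line on malformed
    input and :class:`NetworkValidationError` on duplicate ids.
    """
    net = StoichiometricNetwork()
    pending: list[tuple[int, Reaction]] = []
    section = "REACTIONS"  # bare documents are read as reaction shorthand
    for lineno, raw in enumerate(document.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            header = line.lstrip("#").strip().upper()
            if header in ("METABOLITES", "REACTIONS"):
                section = header
            continue
        if section == "METABOLITES":
            cols = [c.strip() for c in raw.split("\t")]
            if len(cols) < 5:
                raise ReactionTableError(
                    "metabolite row needs 5 columns: id, name, C, N, external", lineno
                )
            try:
                met = Metabolite(
                    id=cols[0],
                    name=cols[1],
                    carbons=_parse_count(cols[2], lineno),
                    nitrogens=_parse_count(cols[3], lineno),
                    external=_parse_flag(cols[4], lineno),
                )
                net.add_metabolite(met)
            except NetworkValidationError as exc:
                raise ReactionTableError(str(exc), lineno) from exc
        else:
            if "\t" in raw:
                cols = [c.strip() for c in raw.split("\t")]
                if len(cols) < 2:
                    raise ReactionTableError("reaction row needs at least id and equation", lineno)
                cols += [""] * (7 - len(cols))
                rid, eq = cols[0], cols[1]
                stoich, arrow_rev = parse_equation(eq, lineno)
                reversible = _parse_flag(cols[2], lineno) if cols[2] else arrow_rev
                if cols[2] and reversible != arrow_rev:
                    raise ReactionTableError(
                        f"reaction {rid!r}: reversible column contradicts equation arrow", lineno
                    )
                lb = _parse_bound(cols[3], lineno) if cols[3] else (-INF if reversible else 0.0)
                ub = _parse_bound(cols[4], lineno) if cols[4] else INF
                ec, gene = cols[5], cols[6]
            elif ":" in raw:
                rid, eq = raw.split(":", 1)
                rid = rid.strip()
                stoich, reversible = parse_equation(eq, lineno)
                lb, ub = (-INF, INF) if reversible else (0.0, INF)
                ec = gene = ""
            else:
                raise ReactionTableError(f"cannot parse line {raw.strip()!r}", lineno)
            if not _ID_RE.match(rid):
                raise ReactionTableError(f"invalid reaction id {rid!r}", lineno)
            try:
                rxn = Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    reversible=reversible,
                    lower_bound=lb,
                    upper_bound=ub,
                    ec=ec,
                    gene=gene,
                )
            except NetworkValidationError as exc:
                raise ReactionTableError(str(exc), lineno) from exc
            pending.append((lineno, rxn))

    for lineno, rxn in pending:
        for m in rxn.stoichiometry:
            if m not in net.metabolite_ids:
                net.add_metabolite(Metabolite(id=m))
        try:
            net.add_reaction(rxn)
        except NetworkValidationError as exc:
            raise ReactionTableError(str(exc), lineno) from exc
    return net


def _fmt_frac(x: Fraction) -> str:
    return str(x)


def _fmt_bound(x: float) -> str:
    if x == INF:
        return "inf"
    if x == -INF:
        return "-inf"
    if x == int(x):
        return str(int(x))
    return repr(x)


def format_equation(r: Reaction) -> str:
    subs, prods = [], []
    for m, c in r.stoichiometry.items():
        term = m if abs(c) == 1 else f"{_fmt_frac(abs(c))} {m}"
        (subs if c < 0 else prods).append(term)
    arrow = "<->" if r.reversible else "->"
    return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()


def serialize_reaction_table(net: StoichiometricNetwork) -> str:
    """Write a network back to the reaction-table format (parse-stable)."""
    lines = ["# METABOLITES", "# id\tname\tC\tN\texternal"]
    for m in net.metabolites:
        c = "?" if m.carbons is None else str(m.carbons)
        n = "?" if m.nitrogens is None else str(m.nitrogens)
        lines.append(f"{m.id}\t{m.name}\t{c}\t{n}\t{int(m.external)}")
    lines += ["", "# REACTIONS", "# id\tequation\treversible\tlb\tub\tec\tgene"]
    for r in net.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    format_equation(r),
                    str(int(r.reversible)),
                    _fmt_bound(r.lower_bound),
                    _fmt_bound(r.upper_bound),
                    r.ec,
                    r.gene,
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Atom balance
# ---------------------------------------------------------------------------


def atom_balance_report(
    net: StoichiometricNetwork, elements: Sequence[str] = ("C", "N")
) -> tuple[list[str], list[str]]:
    """Classify reactions as imbalanced or unchecked for the requested elements.

    Single-metabolite boundary reactions (exchanges, drains) are exempt.  A
    reaction touching a metabolite with an unknown count for some requested
    element is *unchecked* for that element, never imbalanced.
    """
    imbalanced: list[str] = []
    unchecked: list[str] = []
    for r in net.reactions:
        if r.boundary:
            continue
        bad = False
        unknown = False
        for element in elements:
            counts = [net.metabolite(m).element_count(element) for m in r.stoichiometry]
            if any(c is None for c in counts):
                unknown = True
                continue
            total = sum(
                coef * count
                for coef, count in zip(r.stoichiometry.values(), counts)
            )
            if total != 0:
                bad = True
        if bad:
            imbalanced.append(r.id)
        elif unknown:
            unchecked.append(r.id)
    return imbalanced, unchecked


def check_atom_balance(
    net: StoichiometricNetwork, elements: Sequence[str] = ("C", "N")
) -> list[str]:
    """Ids of reactions whose coefficient-weighted element sums are nonzero."""
    return atom_balance_report(net, elements)[0]


# ---------------------------------------------------------------------------
# Net external conversion
# ---------------------------------------------------------------------------


def net_conversion(
    net: StoichiometricNetwork,
    v: Mapping[str, float] | Sequence[float],
    tol: float = 1e-6,
) -> dict[str, float]:
    """Net production (+) / consumption (-) of external species implied by v.

    Requires v to be a steady state on internal metabolites within ``tol``.
    For boundary reactions on *internal* species (one-sided exchanges such as
    ``glc ->``), the exported amount is attributed to that species, so the
    result always describes the overall conversion the flux pattern performs.
    Entries with |value| <= tol are dropped (a zero flux gives an empty map).
    """
    arr = net.flux_array(v)
    S_int = net.stoichiometric_matrix()
    residual = S_int @ arr
    if residual.size and np.max(np.abs(residual)) > tol:
        raise ValueError(
            "flux vector is not a steady state on internal metabolites "
            f"(max |S v| = {np.max(np.abs(residual)):.3g})"
        )
    out: dict[str, float] = {}
    ext = net.external_metabolite_ids
    if ext:
        S_ext = net.stoichiometric_matrix(rows=ext)
        for mid, value in zip(ext, S_ext @ arr):
            if abs(value) > tol:
                out[mid] = float(value)
    # one-sided exchanges written directly on internal species
    rid_index = {rid: j for j, rid in enumerate(net.reaction_ids)}
    for r in net.reactions:
        if r.boundary:
            (mid, coef), = r.stoichiometry.items()
            if not net.metabolite(mid).external:
                value = -float(coef) * arr[rid_index[r.id]]
                if abs(value) > tol:
                    out[mid] = out.get(mid, 0.0) + value
    return {k: val for k, val in out.items() if abs(val) > tol}


# ---------------------------------------------------------------------------
# Packaged model
# ---------------------------------------------------------------------------

MODEL_RESOURCE = "h_elongata_ectoine.tsv"


def load_ectoine_model() -> StoichiometricNetwork:
    """The curated H. elongata ectoine network.

    Covers lumped glycolysis to PEP, the PEP-pyruvate-oxaloacetate node at
    single-reaction resolution (pyruvate kinase, pyruvate dehydrogenase, PEP
    carboxylase, malic enzyme, malate dehydrogenase), aspartate formation and
    activation, the EctB/EctA/EctC synthesis branch, the DoeA/DoeB/DoeD/DoeC
    degradation branch, acetate re-ligation (2 ATP per acetate, AMP-forming
    ligase lumped with pyrophosphatase and adenylate kinase), both nitrogen
    assimilation routes (GDH and GS/GOGAT), a free ATP drain and exchanges.
    Ectoine hydroxylase, the uncoupled NADH oxidase sink and the aspartate
    exchange ship disabled (bounds [0, 0]).
    """
    text = (resources.files("ectoflux.data") / MODEL_RESOURCE).read_text(encoding="utf-8")
    return parse_reaction_table(text)
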