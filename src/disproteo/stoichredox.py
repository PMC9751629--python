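"""Inorganic sulfur reaction balancing and redox feasibility.

Sulfur disproportionation splits one intermediate-oxidation-state compound
into sulfide and sulfate simultaneously, e.g. elemental sulfur::

    4 S0 + 4 H2O -> SO4^2- + 3 HS^- + 5 H^+

The balancer works over the rationals: it builds one conservation row per
element plus one for charge (product columns negated) and takes the
nullspace exactly, so the returned minimal integer coefficients carry no
floating-point error. Tetrathionate disproportionation to thiosulfate,
trithionate and sulfate is underdetermined by conservation alone; fixing
the trithionate and sulfate coefficients (``TETRATHIONATE_ANCHORS``) pins
the classical stoichiometry 4:4 -> 6:1:1:8.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import sympy

from .errors import BalanceError, FormatError

__all__ = [
    "ChemSpecies",
    "Reaction",
    "RedoxCouple",
    "parse_species",
    "parse_reaction",
    "balance",
    "product_ratio",
    "redox_feasibility",
    "TETRATHIONATE_ANCHORS",
    "FARADAY_KJ_PER_VOLT",
]

#: Faraday constant in kJ·mol⁻¹·V⁻¹.
FARADAY_KJ_PER_VOLT = 96.485

#: Named anchoring that reproduces the classical tetrathionate
#: disproportionation stoichiometry (trithionate and sulfate fixed at 1).
TETRATHIONATE_ANCHORS = {"S3O6^2-": 1, "SO4^2-": 1}

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE_RE = re.compile(r"\^(\d*)([+-])$")


@dataclass(frozen=True)
class ChemSpecies:
    """A chemical species: elemental composition plus net charge.

    Names follow a compact grammar: ``S2O3^2-``, ``H2O``, ``HS^-``, ``H^+``.
    ``S0`` is accepted as a named alias for elemental sulfur (one S atom,
    charge 0), since S⁰ has no conventional ionic formula string.
    """

    name: str
    composition: Mapping[str, int]
    charge: int

    def __str__(self) -> str:  # serialization round-trips through parse
        return self.name


def parse_species(name: str) -> ChemSpecies:
    """Parse a species name into composition and charge."""
    name = name.strip()
    if not name:
        raise FormatError("empty species name")
    if name == "S0":
        return ChemSpecies(name="S0", composition={"S": 1}, charge=0)
    charge = 0
    body = name
    m = _CHARGE_RE.search(name)
    if m:
        magnitude = int(m.group(1)) if m.group(1) else 1
        charge = magnitude if m.group(2) == "+" else -magnitude
        body = name[: m.start()]
    if not body:
        raise FormatError(f"{name!r}: no formula before charge suffix")
    comp: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _ELEMENT_RE.match(body, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormatError(f"{name!r}: parse error at position {pos}")
        count = int(m.group(2)) if m.group(2) else 1
        if count < 1:
            raise FormatError(
                f"{name!r}: element count must be positive at position {pos}"
            )
        comp[m.group(1)] = comp.get(m.group(1), 0) + count
        pos = m.end()
    return ChemSpecies(name=name, composition=comp, charge=charge)


@dataclass
class Reaction:
    """A reaction over parsed species, with coefficients once balanced.

    ``sides[i]`` is ``"reactant"`` or ``"product"`` for ``species[i]``;
    ``anchors`` optionally fixes named coefficients before solving.
    """

    species: list[ChemSpecies]
    sides: list[str]
    coefficients: list[Fraction] | None = None
    anchors: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.species) != len(self.sides):
            raise ValueError("species and sides length mismatch")
        for s in self.sides:
            if s not in {"reactant", "product"}:
                raise ValueError(f"bad side token {s!r}")

    @property
    def is_balanced(self) -> bool:
        return self.coefficients is not None

    def coefficient(self, name: str) -> Fraction:
        if self.coefficients is None:
            raise BalanceError("reaction not balanced yet")
        for sp, c in zip(self.species, self.coefficients):
            if sp.name == name:
                return c
        raise KeyError(f"species {name!r} not in reaction")

    def equation(self) -> str:
        def fmt(side: str) -> str:
            parts = []
            for sp, s, c in zip(self.species, self.sides, self.coefficients or []):
                if s != side:
                    continue
                parts.append(sp.name if c == 1 else f"{c} {sp.name}")
            return " + ".join(parts)

        if self.coefficients is None:
            lhs = " + ".join(sp.name for sp, s in zip(self.species, self.sides) if s == "reactant")
            rhs = " + ".join(sp.name for sp, s in zip(self.species, self.sides) if s == "product")
            return f"{lhs} -> {rhs}"
        return f"{fmt('reactant')} -> {fmt('product')}"


def parse_reaction(text: str, anchors: Mapping[str, int] | None = None) -> Reaction:
    """Parse ``"S0 + H2O -> SO4^2- + HS^- + H^+"`` into an unbalanced Reaction."""
    if "->" not in text:
        raise FormatError(f"{text!r}: missing '->'")
    lhs, rhs = text.split("->", 1)
    species: list[ChemSpecies] = []
    sides: list[str] = []
    for side_text, side in ((lhs, "reactant"), (rhs, "product")):
        for token in side_text.split("+"):
            # '+' also ends charge suffixes like H^+ ; re-join those fragments
            token = token.strip()
            if token.endswith("^"):
                token += "+"
            elif not token:
                continue
            species.append(parse_species(token))
            sides.append(side)
    return Reaction(species=species, sides=sides, anchors=dict(anchors or {}))


def _conservation_matrix(reaction: Reaction) -> sympy.Matrix:
    elements = sorted({e for sp in reaction.species for e in sp.composition})
    rows = []
    for e in elements:
        rows.append(
            [
                sp.composition.get(e, 0) * (1 if side == "reactant" else -1)
                for sp, side in zip(reaction.species, reaction.sides)
            ]
        )
    rows.append(
        [
            sp.charge * (1 if side == "reactant" else -1)
            for sp, side in zip(reaction.species, reaction.sides)
        ]
    )
    return sympy.Matrix(rows)


def _to_fraction(x: sympy.Rational) -> Fraction:
    return Fraction(int(x.p), int(x.q))


def balance(reaction: Reaction) -> Reaction:
    """Solve for conservation-satisfying coefficients.

    Without anchors the nullspace must be one-dimensional with a strictly
    positive representative; the minimal positive integer vector is returned
    (denominators cleared, divided by the gcd). Anchors are honored exactly:
    the anchored coefficients appear verbatim in the solution.
    """
    if len(reaction.species) < 2:
        raise BalanceError("need at least two species")
    M = _conservation_matrix(reaction)
    ns = M.nullspace()
    if not ns:
        raise BalanceError("unbalanceable: conservation admits only the zero solution")

    names = [sp.name for sp in reaction.species]
    if reaction.anchors:
        unknown = set(reaction.anchors) - set(names)
        if unknown:
            raise BalanceError(f"anchor species not in reaction: {sorted(unknown)}")
        # solve N·c with anchored entries pinned to their values
        N = sympy.Matrix.hstack(*ns)
        idx = [names.index(n) for n in reaction.anchors]
        A = N[idx, :]
        b = sympy.Matrix([reaction.anchors[n] for n in reaction.anchors])
        c = sympy.symbols(f"c0:{N.cols}")
        sols = sympy.linsolve((A, b), list(c))
        if not sols:
            raise BalanceError("anchors are inconsistent with conservation")
        sol = next(iter(sols))
        if any(s.free_symbols for s in sol):
            free = [str(s) for s in sol if s.free_symbols]
            raise BalanceError(
                f"underdetermined: supply more anchors (free directions remain: {free})"
            )
        x = N * sympy.Matrix(sol)
        coeffs = [_to_fraction(sympy.Rational(v)) for v in x]
    else:
        if len(ns) > 1:
            dirs = [[str(v) for v in vec] for vec in ns]
            raise BalanceError(
                f"underdetermined: supply anchors (free directions: {dirs})"
            )
        v = ns[0]
        denoms = [sympy.Rational(x).q for x in v]
        scale = math.lcm(*denoms)
        ints = [int(sympy.Rational(x) * scale) for x in v]
        g = math.gcd(*(abs(i) for i in ints if i != 0))
        ints = [i // g for i in ints]
        if all(i < 0 for i in ints if i != 0):
            ints = [-i for i in ints]
        coeffs = [Fraction(i) for i in ints]

    if any(c <= 0 for c in coeffs):
        raise BalanceError(
            "infeasible orientation: no strictly positive coefficient vector "
            "for the written reactant/product sides"
        )
    return Reaction(
        species=reaction.species,
        sides=reaction.sides,
        coefficients=coeffs,
        anchors=dict(reaction.anchors),
    )


def product_ratio(reaction: Reaction, a: str, b: str) -> Fraction:
    """Exact molar ratio coefficient(a)/coefficient(b) between two products."""
    if reaction.coefficients is None:
        raise BalanceError("reaction not balanced yet")
    for name in (a, b):
        found = [
            side
            for sp, side in zip(reaction.species, reaction.sides)
            if sp.name == name
        ]
        if not found:
            raise KeyError(f"species {name!r} not in reaction")
        if found[0] != "product":
            raise ValueError(f"species {name!r} is not a product")
    return reaction.coefficient(a) / reaction.coefficient(b)


@dataclass(frozen=True)
class RedoxCouple:
    """A half-reaction couple with midpoint potential Em in millivolts."""

    name: str
    em_mv: float
    role: str = "electron donor couple"


def redox_feasibility(
    donor: RedoxCouple | float,
    acceptor: RedoxCouple | float,
    n_electrons: int = 2,
) -> tuple[float, bool, float]:
    """Evaluate whether electron flow from donor to acceptor couple is downhill.

    Returns ``(delta_E in mV, favorable, delta_G in kJ/mol)`` with
    ``delta_E = Em(acceptor) − Em(donor)`` and ``delta_G = −n·F·delta_E``.
    Flow toward the higher-potential couple (delta_E > 0) is favorable.
    """
    if n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    em_d = donor.em_mv if isinstance(donor, RedoxCouple) else float(donor)
    em_a = acceptor.em_mv if isinstance(acceptor, RedoxCouple) else float(acceptor)
    delta_e = em_a - em_d
    delta_g = -n_electrons * FARADAY_KJ_PER_VOLT * (delta_e / 1000.0)
    return delta_e, delta_e > 0, delta_g
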