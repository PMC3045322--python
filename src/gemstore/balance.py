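"""Chemical-formula parsing and elemental mass-balance checking.

The balance check compares, element by element, the atoms consumed by a
reaction's substrates with the atoms produced on the product side; a curated
reaction should conserve every element.  Formulas follow the conventional
grammar: element symbols (uppercase letter plus optional lowercase letters)
each followed by an optional positive count, with parenthesized groups and
group multipliers, e.g. ``C6H12O6`` or ``Ca(OH)2``.  Counts may be decimal
to accommodate lumped biomass species.  Non-IUPAC symbols such as ``R`` or
``X`` are accepted as opaque element tokens by default, since lumped species
in published models use them; a strict mode restricts symbols to the
periodic table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .core import Model, Reaction

__all__ = [
    "ElementCounts",
    "BalanceReport",
    "FormulaParseError",
    "parse_formula",
    "format_formula",
    "balance_report",
    "BALANCE_TOLERANCE",
    "CHARGE",
    "PERIODIC_SYMBOLS",
]

#: Per-element tolerance on the net count; stoichiometries of biomass
#: equations are decimal, so exact integer arithmetic cannot be assumed.
BALANCE_TOLERANCE = 1e-9

#: Pseudo-element under which net charge is reported when every participant
#: of a reaction carries a charge value.
CHARGE = "charge"

ElementCounts = Dict[str, float]

PERIODIC_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu".split()
)


class FormulaParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(
    r"(?P<element>[A-Z][a-z]*)|(?P<count>\d+(?:\.\d+)?)|(?P<open>\()|(?P<close>\))"
)


def parse_formula(text: str, strict: bool = False) -> ElementCounts:
    """Parse a chemical formula into an element → count mapping.

    With ``strict=True`` only periodic-table symbols are accepted; otherwise
    any token matching uppercase-plus-lowercase is treated as an element,
    covering generic ``R``-group placeholders.
    """
    if not text or not text.strip():
        raise FormulaParseError("empty formula", 0)
    text = text.strip()

    pos = 0
    n = len(text)

    def parse_sequence(depth: int) -> ElementCounts:
        nonlocal pos
        counts: ElementCounts = {}
        while pos < n:
            ch = text[pos]
            if ch == ")":
                if depth == 0:
                    raise FormulaParseError("unbalanced ')'", pos)
                return counts
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                raise FormulaParseError(f"illegal character {ch!r}", pos)
            if m.group("element"):
                symbol = m.group("element")
                if strict and symbol not in PERIODIC_SYMBOLS:
                    raise FormulaParseError(f"unknown element {symbol!r}", pos)
                pos = m.end()
                count = parse_count(default=1.0)
                counts[symbol] = counts.get(symbol, 0.0) + count
            elif m.group("open"):
                open_pos = pos
                pos = m.end()
                inner = parse_sequence(depth + 1)
                if pos >= n or text[pos] != ")":
                    raise FormulaParseError("unbalanced '('", open_pos)
                if not inner:
                    raise FormulaParseError("empty group", open_pos)
                pos += 1
                mult = parse_count(default=1.0)
                for sym, c in inner.items():
                    counts[sym] = counts.get(sym, 0.0) + c * mult
            else:
                raise FormulaParseError("count without preceding element", pos)
        return counts

    def parse_count(default: float) -> float:
        nonlocal pos
        m = _TOKEN_RE.match(text, pos)
        if m is None or not m.group("count"):
            return default
        value = float(m.group("count"))
        if value == 0:
            raise FormulaParseError("zero count", pos)
        pos = m.end()
        return value

    counts = parse_sequence(0)
    if not counts:
        raise FormulaParseError("formula contains no elements", 0)
    return counts


def format_formula(counts: ElementCounts) -> str:
    """Format counts in Hill order: C first, then H, then alphabetical.

    Re-parsing the result reproduces the counts.  Integral counts print
    without a decimal point; a count of one prints as the bare symbol.
    """
    symbols = sorted(counts)
    if "C" in counts:
        symbols = ["C"] + (["H"] if "H" in counts else []) + [
            s for s in symbols if s not in ("C", "H")
        ]
    parts = []
    for sym in symbols:
        c = counts[sym]
        if c == 1:
            parts.append(sym)
        elif float(c).is_integer():
            parts.append(f"{sym}{int(c)}")
        else:
            parts.append(f"{sym}{c}")
    return "".join(parts)


@dataclass
class BalanceReport:
    """Outcome of the elemental balance check for one reaction.

    ``net`` maps each element to products-minus-substrates atoms; elements
    with negative net are missing on the product side, positive net means
    overproduction.  When any participating metabolite lacks a formula the
    status is ``undetermined`` and those metabolites are listed.
    """

    status: str  # "balanced" | "unbalanced" | "undetermined"
    net: Dict[str, float] = field(default_factory=dict)
    missing_on_product_side: frozenset = frozenset()
    overproduced_on_product_side: frozenset = frozenset()
    undetermined_metabolites: List[str] = field(default_factory=list)


def balance_report(reaction: "Reaction", model: "Model",
                   strict: bool = False) -> BalanceReport:
    """Check elemental (and, where possible, charge) balance of a reaction.

    Exchange/boundary reactions with reactants on only one side come out
    unbalanced, never as errors: they are intentionally unbalanced.  When
    every participant carries a charge value, net charge is reported as the
    pseudo-element :data:`CHARGE` alongside the elements.
    """
    from .core import PRODUCT

    undetermined: List[str] = []
    net: Dict[str, float] = {}
    all_charged = bool(reaction.reactants)

    for reactant in reaction.reactants:
        met = model.metabolite(reactant.metabolite_ref)
        sign = 1.0 if reactant.side == PRODUCT else -1.0
        if met.formula is None or not met.formula.strip():
            if met.abbreviation not in undetermined:
                undetermined.append(met.abbreviation)
        else:
            for sym, count in parse_formula(met.formula, strict=strict).items():
                net[sym] = net.get(sym, 0.0) + sign * reactant.stoichiometry * count
        if met.charge is None:
            all_charged = False
        else:
            net[CHARGE] = net.get(CHARGE, 0.0) + sign * reactant.stoichiometry * met.charge

    if not all_charged:
        net.pop(CHARGE, None)
    net = {sym: val for sym, val in net.items() if abs(val) > BALANCE_TOLERANCE}

    if undetermined:
        status = "undetermined"
    elif net:
        status = "unbalanced"
    else:
        status = "balanced"
    return BalanceReport(
        status=status,
        net=net,
        missing_on_product_side=frozenset(s for s, v in net.items() if v < 0),
        overproduced_on_product_side=frozenset(s for s, v in net.items() if v > 0),
        undetermined_metabolites=undetermined,
    )
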