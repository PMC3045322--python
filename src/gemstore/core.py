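"""In-memory data model for genome-scale metabolic models.

A model is a named container of compartments (arranged in a parent
hierarchy), metabolites, reactions, genes and subsystems.  Reactions are
built from reactants — a metabolite, a positive stoichiometric coefficient,
a compartment assignment and a side — plus reversibility, an optional
gene–protein–reaction (GPR) Boolean rule and external references in MIRIAM
notation (single-string, registry-qualified identifiers such as an EC number
or a KEGG accession).

This module also implements the GPR grammar (parse / serialize / evaluate),
MIRIAM reference resolution against a user-extensible registry of external
databases, compartment-hierarchy queries and referential-integrity
validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pyparsing as pp

__all__ = [
    "MiriamRef",
    "Compartment",
    "Metabolite",
    "Reactant",
    "Reaction",
    "Gene",
    "GeneAssociation",
    "Model",
    "Issue",
    "GprParseError",
    "LookupError_",
    "UNRESOLVED",
    "parse_gpr",
    "serialize_gpr",
    "evaluate_gpr",
    "gpr_genes",
    "load_registry",
    "miriam_to_url",
    "is_within",
    "compartment_path",
    "validate_model",
]

SUBSTRATE = "substrate"
PRODUCT = "product"


class GprParseError(ValueError):
    """Raised for malformed GPR strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class LookupError_(KeyError):
    """An entity reference that does not resolve within a model."""


# ---------------------------------------------------------------------------
# MIRIAM references
# ---------------------------------------------------------------------------

#: Marker returned for datatypes absent from the registry.
UNRESOLVED = "unresolved"

_URN_RE = re.compile(r"^urn:miriam:(?P<dt>[^:]+):(?P<id>.+)$")
_URI_RE = re.compile(r"^https?://(?:www\.)?identifiers\.org/(?P<dt>[^/]+)/(?P<id>.+)$")


@dataclass(frozen=True)
class MiriamRef:
    """A single-string reference to an entry in an external database.

    ``datatype`` is a registry key (e.g. ``ec-code``, ``kegg.reaction``),
    ``identifier`` the accession within that database, and ``qualifier`` the
    BioModels relation tag (``is`` by default).
    """

    datatype: str
    identifier: str
    qualifier: str = "is"

    def to_urn(self) -> str:
        """Serialize to the URN dialect ``urn:miriam:<datatype>:<identifier>``."""
        return f"urn:miriam:{self.datatype}:{self.identifier.replace(':', '%3A')}"

    @classmethod
    def from_string(cls, text: str, qualifier: str = "is") -> "MiriamRef":
        """Parse a URN (``urn:miriam:...``) or an identifiers.org URI."""
        m = _URN_RE.match(text.strip())
        if m:
            return cls(m.group("dt"), m.group("id").replace("%3A", ":"), qualifier)
        m = _URI_RE.match(text.strip())
        if m:
            return cls(m.group("dt"), m.group("id"), qualifier)
        raise ValueError(f"not a MIRIAM URN or identifiers.org URI: {text!r}")


def load_registry(path: Optional[str] = None) -> Dict[str, str]:
    """Load the datatype → URL-template registry.

    The registry is a flat tab-separated text file (``datatype<TAB>template``,
    ``#`` comments), with ``{id}`` marking where the identifier goes.  Without
    ``path`` the bundled registry is loaded; users point ``path`` at their own
    file to define additional external databases.
    """
    if path is None:
        text = resources.files("gemstore").joinpath("data/registry.tsv").read_text("utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    registry: Dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, template = line.partition("\t")
        if key and template:
            registry[key.strip()] = template.strip()
    return registry


def miriam_to_url(ref: MiriamRef, registry: Dict[str, str]) -> str:
    """Resolve a MIRIAM reference to a web address.

    Unknown datatypes yield the :data:`UNRESOLVED` marker rather than a
    malformed URL.
    """
    template = registry.get(ref.datatype)
    if template is None:
        return UNRESOLVED
    return template.replace("{id}", ref.identifier)


# ---------------------------------------------------------------------------
# Gene–protein–reaction Boolean rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAssociation:
    """Node of a GPR Boolean tree.

    ``op`` is one of ``"leaf"``, ``"and"``, ``"or"``.  Leaves carry a gene
    abbreviation; AND/OR nodes carry an ordered tuple of at least two
    children.
    """

    op: str
    gene: Optional[str] = None
    children: Tuple["GeneAssociation", ...] = ()

    def __post_init__(self):
        if self.op == "leaf":
            if not self.gene:
                raise ValueError("leaf node requires a gene abbreviation")
        elif self.op in ("and", "or"):
            # associative flattening: AND(a, AND(b, c)) is stored as
            # AND(a, b, c), so structurally equal rules compare equal
            flat: List[GeneAssociation] = []
            for child in self.children:
                if child.op == self.op:
                    flat.extend(child.children)
                else:
                    flat.append(child)
            object.__setattr__(self, "children", tuple(flat))
            if len(self.children) < 2:
                raise ValueError(f"{self.op.upper()} node requires arity >= 2")
        else:
            raise ValueError(f"unknown GPR node kind {self.op!r}")

    @staticmethod
    def leaf(gene: str) -> "GeneAssociation":
        return GeneAssociation("leaf", gene=gene)

    @staticmethod
    def and_(*children: "GeneAssociation") -> "GeneAssociation":
        return GeneAssociation("and", children=tuple(children))

    @staticmethod
    def or_(*children: "GeneAssociation") -> "GeneAssociation":
        return GeneAssociation("or", children=tuple(children))


def _make_grammar() -> pp.ParserElement:
    AND = pp.CaselessKeyword("AND")
    OR = pp.CaselessKeyword("OR")
    gene = ~(AND | OR) + pp.Word(pp.alphanums + "_.:-")
    gene.set_parse_action(lambda t: GeneAssociation.leaf(t[0]))

    expr = pp.Forward()
    group = (pp.Suppress("(") + expr + pp.Suppress(")")) | (
        pp.Suppress("[") + expr + pp.Suppress("]")
    )
    atom = gene | group

    def _fold(op: str):
        def action(tokens):
            items = list(tokens)
            if len(items) == 1:
                return items[0]
            flat: List[GeneAssociation] = []
            for item in items:  # flatten same-operator chains: a AND b AND c
                if item.op == op:
                    flat.extend(item.children)
                else:
                    flat.append(item)
            return GeneAssociation(op, children=tuple(flat))

        return action

    conj = atom + pp.ZeroOrMore(pp.Suppress(AND) + atom)
    conj.set_parse_action(_fold("and"))
    expr <<= conj + pp.ZeroOrMore(pp.Suppress(OR) + conj)
    expr.set_parse_action(_fold("or"))
    return expr


_GPR_GRAMMAR = _make_grammar()


def parse_gpr(text: str) -> GeneAssociation:
    """Parse a GPR string like ``gene1 AND [gene2 OR gene3]``.

    Operators are case-insensitive; both square brackets and parentheses
    group sub-expressions; without brackets AND binds tighter than OR.
    Malformed input (unbalanced brackets, dangling operator, empty group)
    raises :class:`GprParseError` naming the offending position.
    """
    if not text or not text.strip():
        raise GprParseError("empty GPR string", 0)
    try:
        result = _GPR_GRAMMAR.parse_string(text, parse_all=True)
    except pp.ParseBaseException as exc:
        raise GprParseError(exc.msg, exc.loc) from None
    return result[0]


def serialize_gpr(assoc: GeneAssociation) -> str:
    """Serialize a GPR tree; square brackets are emitted for sub-groups.

    Re-parsing the output reconstructs an identical tree.
    """
    if assoc.op == "leaf":
        return assoc.gene  # type: ignore[return-value]
    sep = f" {assoc.op.upper()} "
    parts = [
        serialize_gpr(c) if c.op == "leaf" else f"[{serialize_gpr(c)}]"
        for c in assoc.children
    ]
    return sep.join(parts)


def evaluate_gpr(assoc: GeneAssociation, present: Set[str]) -> bool:
    """Evaluate a GPR tree given the set of present (non-deleted) genes."""
    if assoc.op == "leaf":
        return assoc.gene in present
    if assoc.op == "and":
        return all(evaluate_gpr(c, present) for c in assoc.children)
    return any(evaluate_gpr(c, present) for c in assoc.children)


def gpr_genes(assoc: GeneAssociation) -> Set[str]:
    """The set of gene abbreviations referenced by a GPR tree."""
    if assoc.op == "leaf":
        return {assoc.gene}  # type: ignore[arg-type]
    out: Set[str] = set()
    for c in assoc.children:
        out |= gpr_genes(c)
    return out


# ---------------------------------------------------------------------------
# Entities
# ---------------------------------------------------------------------------


@dataclass
class Compartment:
    compartment_id: str
    name: str = ""
    parent_id: Optional[str] = None
    annotations: List[MiriamRef] = field(default_factory=list)


@dataclass
class Metabolite:
    abbreviation: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    chebi_id: Optional[str] = None
    kegg_id: Optional[str] = None
    annotations: List[MiriamRef] = field(default_factory=list)


@dataclass
class Reactant:
    """One participant of a reaction: metabolite, coefficient, compartment, side."""

    metabolite_ref: str
    stoichiometry: float
    compartment_ref: str
    side: str  # SUBSTRATE or PRODUCT

    def __post_init__(self):
        if self.stoichiometry <= 0:
            raise ValueError("stoichiometry must be positive")
        if self.side not in (SUBSTRATE, PRODUCT):
            raise ValueError(f"side must be {SUBSTRATE!r} or {PRODUCT!r}")


@dataclass
class Reaction:
    abbreviation: str
    name: str = ""
    reactants: List[Reactant] = field(default_factory=list)
    reversible: bool = False
    ec_number: Optional[str] = None
    kegg_id: Optional[str] = None
    subsystem: Optional[str] = None
    gpr: Optional[GeneAssociation] = None
    enzyme: Optional[str] = None
    orf: Optional[str] = None
    citations: List[str] = field(default_factory=list)
    annotations: List[MiriamRef] = field(default_factory=list)
    is_exchange: bool = False

    def substrates(self) -> List[Reactant]:
        return [r for r in self.reactants if r.side == SUBSTRATE]

    def products(self) -> List[Reactant]:
        return [r for r in self.reactants if r.side == PRODUCT]

    def equation_text(self, model: Optional["Model"] = None) -> str:
        """Human-readable equation, e.g. ``2 h2o[c] <=> 2 h[c] + o2[e]``."""

        def side(rs: List[Reactant]) -> str:
            terms = []
            for r in rs:
                coeff = "" if r.stoichiometry == 1 else _fmt_num(r.stoichiometry) + " "
                terms.append(f"{coeff}{r.metabolite_ref}[{r.compartment_ref}]")
            return " + ".join(terms)

        arrow = "<=>" if self.reversible else "->"
        return f"{side(self.substrates())} {arrow} {side(self.products())}"


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


@dataclass
class Gene:
    abbreviation: str
    name: str = ""
    ec_number: Optional[str] = None
    kegg_id: Optional[str] = None
    uniprot_id: Optional[str] = None
    annotations: List[MiriamRef] = field(default_factory=list)


@dataclass
class Model:
    """Named container for the full description of a metabolic model."""

    model_id: str
    name: str = ""
    organism: str = ""
    version_label: str = ""
    compartments: Dict[str, Compartment] = field(default_factory=dict)
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    genes: Dict[str, Gene] = field(default_factory=dict)
    subsystems: List[str] = field(default_factory=list)
    annotations: List[MiriamRef] = field(default_factory=list)
    notes: str = ""
    #: (kind, abbreviation) pairs recorded when add() would overwrite an
    #: existing entity; surfaced by validate_model as duplicate-id issues.
    duplicate_ids: List[Tuple[str, str]] = field(default_factory=list)

    # -- construction helpers ------------------------------------------------
    def add(self, entity) -> None:
        if isinstance(entity, Compartment):
            if entity.compartment_id in self.compartments:
                self.duplicate_ids.append(("compartment", entity.compartment_id))
            self.compartments[entity.compartment_id] = entity
        elif isinstance(entity, Metabolite):
            if entity.abbreviation in self.metabolites:
                self.duplicate_ids.append(("metabolite", entity.abbreviation))
            self.metabolites[entity.abbreviation] = entity
        elif isinstance(entity, Reaction):
            if entity.abbreviation in self.reactions:
                self.duplicate_ids.append(("reaction", entity.abbreviation))
            self.reactions[entity.abbreviation] = entity
            if entity.subsystem and entity.subsystem not in self.subsystems:
                self.subsystems.append(entity.subsystem)
        elif isinstance(entity, Gene):
            if entity.abbreviation in self.genes:
                self.duplicate_ids.append(("gene", entity.abbreviation))
            self.genes[entity.abbreviation] = entity
        else:  # pragma: no cover - defensive
            raise TypeError(f"cannot add {type(entity).__name__} to a model")

    def metabolite(self, abbreviation: str) -> Metabolite:
        try:
            return self.metabolites[abbreviation]
        except KeyError:
            raise LookupError_(f"unknown metabolite {abbreviation!r}") from None

    def compartment(self, compartment_id: str) -> Compartment:
        try:
            return self.compartments[compartment_id]
        except KeyError:
            raise LookupError_(f"unknown compartment {compartment_id!r}") from None

    def reaction(self, abbreviation: str) -> Reaction:
        try:
            return self.reactions[abbreviation]
        except KeyError:
            raise LookupError_(f"unknown reaction {abbreviation!r}") from None


# ---------------------------------------------------------------------------
# Compartment hierarchy
# ---------------------------------------------------------------------------


def compartment_path(compartment_id: str, model: Model) -> Tuple[str, ...]:
    """Root-first chain of compartment ids ending at ``compartment_id``."""
    chain: List[str] = []
    seen: Set[str] = set()
    current: Optional[str] = compartment_id
    while current is not None:
        if current in seen:
            raise ValueError(f"compartment hierarchy cycle at {current!r}")
        seen.add(current)
        chain.append(current)
        current = model.compartment(current).parent_id
    return tuple(reversed(chain))


def is_within(compartment_id: str, ancestor: str, model: Model) -> bool:
    """Ancestor-or-self test on the compartment hierarchy.

    True iff ``ancestor`` lies on the parent chain of ``compartment_id``,
    including the compartment itself (so every compartment is within itself).
    """
    model.compartment(ancestor)  # raise on unknown id
    return ancestor in compartment_path(compartment_id, model)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    entity: str
    message: str


def validate_model(model: Model) -> List[Issue]:
    """Check referential integrity and type invariants.

    Errors: dangling metabolite/compartment references, compartment cycles,
    reactions without reactants (unless flagged exchange), non-positive
    stoichiometries, undeclared subsystems, unparseable formulas.  GPR leaves
    naming genes not declared in the model are warnings only: draft models
    legitimately reference genes that are not yet annotated.
    """
    from . import balance  # local import: avoid a cycle at module load

    issues: List[Issue] = []

    for kind, abbr in model.duplicate_ids:
        issues.append(Issue("error", abbr, f"duplicate {kind} abbreviation"))

    for comp in model.compartments.values():
        if comp.parent_id is not None and comp.parent_id not in model.compartments:
            issues.append(
                Issue("error", comp.compartment_id,
                      f"parent compartment {comp.parent_id!r} not declared")
            )
    for comp_id in model.compartments:
        try:
            compartment_path(comp_id, model)
        except ValueError as exc:
            issues.append(Issue("error", comp_id, str(exc)))
        except LookupError_:
            pass  # dangling parent already reported

    for met in model.metabolites.values():
        if met.formula:
            try:
                balance.parse_formula(met.formula)
            except balance.FormulaParseError as exc:
                issues.append(Issue("error", met.abbreviation, f"bad formula: {exc}"))

    for rxn in model.reactions.values():
        if not rxn.reactants and not rxn.is_exchange:
            issues.append(
                Issue("error", rxn.abbreviation,
                      "reaction has no reactants and is not flagged as exchange")
            )
        for reactant in rxn.reactants:
            if reactant.metabolite_ref not in model.metabolites:
                issues.append(
                    Issue("error", rxn.abbreviation,
                          f"undeclared metabolite {reactant.metabolite_ref!r}")
                )
            if reactant.compartment_ref not in model.compartments:
                issues.append(
                    Issue("error", rxn.abbreviation,
                          f"undeclared compartment {reactant.compartment_ref!r}")
                )
        if rxn.subsystem and rxn.subsystem not in model.subsystems:
            issues.append(
                Issue("error", rxn.abbreviation,
                      f"undeclared subsystem {rxn.subsystem!r}")
            )
        if rxn.gpr is not None:
            for gene in sorted(gpr_genes(rxn.gpr)):
                if gene not in model.genes:
                    issues.append(
                        Issue("warning", rxn.abbreviation,
                              f"GPR references undeclared gene {gene!r}")
                    )
    return issues


def duplicate_check(abbreviations: Iterable[str]) -> List[str]:
    """Return abbreviations occurring more than once (order-preserving)."""
    seen: Set[str] = set()
    dups: List[str] = []
    for a in abbreviations:
        if a in seen and a not in dups:
            dups.append(a)
        seen.add(a)
    return dups
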