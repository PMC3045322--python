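"""Identifier-based comparison of two model snapshots with Venn summaries.

Reactions are matched on their KEGG reaction ID when both carry one;
otherwise on the canonical chemical equation (reversibility, metabolites and
stoichiometry).  Metabolites are matched on ChEBI ID, then KEGG ID, then
case-insensitive name; genes on UniProt ID, then name.  The result lists
shared and unique entities per category together with the three Venn counts
(unique to A, shared, unique to B), optionally after restricting both models
to selected compartments or subsystems.

Matching is greedy one-to-one in sorted-abbreviation order, which is
deterministic; curated models rarely contain duplicate entries, so greedy
matching coincides with an optimal assignment in practice.  When both sides
carry conflicting KEGG IDs the reactions do not match — the curated ID is
authoritative and no equation fallback applies.  Metabolites are compared at
species level, ignoring the compartment.  Reversible reactions compare equal
under a swap of sides; irreversible reactions preserve direction; no
stoichiometric rescaling is attempted (``2A -> 2B`` differs from ``A -> B``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .core import (
    Gene, Metabolite, Model, Reaction, SUBSTRATE, PRODUCT,
    compartment_path, gpr_genes,
)

__all__ = [
    "CanonicalEquation",
    "MatchResult",
    "CategoryResult",
    "ComparisonResult",
    "canonical_equation",
    "match_reaction",
    "match_metabolite",
    "match_gene",
    "compare_models",
    "comparison_table",
]

NO_MATCH = "none"

Term = Tuple[str, Tuple[str, ...], float]  # (metabolite key, compartment path, stoich)


@dataclass(frozen=True)
class CanonicalEquation:
    """Order-independent form of a chemical equation.

    Each side is a sorted tuple of (metabolite key, compartment path,
    stoichiometry) terms; for reversible reactions the two sides are oriented
    so that the lexicographically smaller side comes first, making the form
    invariant under writing the equation in either direction.
    """

    substrates: Tuple[Term, ...]
    products: Tuple[Term, ...]
    reversible: bool


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    rule: str  # "kegg" | "equation" | "chebi" | "name" | "uniprot" | "none"

    def __post_init__(self):
        if self.matched == (self.rule == NO_MATCH):
            raise ValueError("rule must be 'none' exactly when unmatched")


def _metabolite_key(met: Metabolite) -> str:
    """Identifier precedence for metabolite identity: ChEBI > KEGG > name."""
    if met.chebi_id:
        return f"chebi:{met.chebi_id}"
    if met.kegg_id:
        return f"kegg:{met.kegg_id}"
    return f"name:{met.name.lower()}"


def canonical_equation(reaction: Reaction, model: Model) -> CanonicalEquation:
    """Canonical equation of a reaction; reactant order never matters."""

    def side(side_tag: str) -> Tuple[Term, ...]:
        terms = [
            (_metabolite_key(model.metabolite(r.metabolite_ref)),
             compartment_path(r.compartment_ref, model),
             float(r.stoichiometry))
            for r in reaction.reactants if r.side == side_tag
        ]
        return tuple(sorted(terms))

    substrates, products = side(SUBSTRATE), side(PRODUCT)
    if reaction.reversible and products < substrates:
        substrates, products = products, substrates
    return CanonicalEquation(substrates, products, reaction.reversible)


def match_reaction(r1: Reaction, r2: Reaction,
                   model1: Model, model2: Model) -> MatchResult:
    """KEGG ID when available on both sides, else the chemical equation."""
    if r1.kegg_id and r2.kegg_id:
        if r1.kegg_id == r2.kegg_id:
            return MatchResult(True, "kegg")
        return MatchResult(False, NO_MATCH)
    if canonical_equation(r1, model1) == canonical_equation(r2, model2):
        return MatchResult(True, "equation")
    return MatchResult(False, NO_MATCH)


def match_metabolite(m1: Metabolite, m2: Metabolite) -> MatchResult:
    if m1.chebi_id and m2.chebi_id:
        return MatchResult(True, "chebi") if m1.chebi_id == m2.chebi_id \
            else MatchResult(False, NO_MATCH)
    if m1.kegg_id and m2.kegg_id:
        return MatchResult(True, "kegg") if m1.kegg_id == m2.kegg_id \
            else MatchResult(False, NO_MATCH)
    if m1.name and m2.name and m1.name.lower() == m2.name.lower():
        return MatchResult(True, "name")
    return MatchResult(False, NO_MATCH)


def match_gene(g1: Gene, g2: Gene) -> MatchResult:
    if g1.uniprot_id and g2.uniprot_id:
        return MatchResult(True, "uniprot") if g1.uniprot_id == g2.uniprot_id \
            else MatchResult(False, NO_MATCH)
    if g1.name and g2.name and g1.name.lower() == g2.name.lower():
        return MatchResult(True, "name")
    return MatchResult(False, NO_MATCH)


@dataclass
class CategoryResult:
    """Shared/unique lists and Venn counts for one entity category."""

    shared: List[Tuple[str, str, str]] = field(default_factory=list)  # (a, b, rule)
    unique_a: List[str] = field(default_factory=list)
    unique_b: List[str] = field(default_factory=list)

    @property
    def venn(self) -> Tuple[int, int, int]:
        """(|unique to A|, |shared|, |unique to B|)."""
        return (len(self.unique_a), len(self.shared), len(self.unique_b))


@dataclass
class ComparisonResult:
    operand_a: Tuple[str, int]  # (model_id, revision)
    operand_b: Tuple[str, int]
    reactions: CategoryResult
    metabolites: CategoryResult
    genes: CategoryResult
    restrict_compartments: Optional[Set[str]] = None
    restrict_subsystems: Optional[Set[str]] = None

    def category(self, name: str) -> CategoryResult:
        return {"reactions": self.reactions, "metabolites": self.metabolites,
                "genes": self.genes}[name]


def _greedy_match(items_a: Sequence, items_b: Sequence, key_a, key_b,
                  matcher) -> CategoryResult:
    """Greedy one-to-one matching in sorted order of the A items."""
    result = CategoryResult()
    unmatched_b = list(sorted(items_b, key=key_b))
    for a in sorted(items_a, key=key_a):
        hit = None
        for i, b in enumerate(unmatched_b):
            m = matcher(a, b)
            if m.matched:
                hit = (i, b, m.rule)
                break
        if hit is None:
            result.unique_a.append(key_a(a))
        else:
            i, b, rule = hit
            del unmatched_b[i]
            result.shared.append((key_a(a), key_b(b), rule))
    result.unique_b = [key_b(b) for b in unmatched_b]
    return result


def restrict_model(model: Model, compartments: Optional[Set[str]] = None,
                   subsystems: Optional[Set[str]] = None
                   ) -> Tuple[List[Reaction], List[Metabolite], List[Gene]]:
    """Apply compartment/subsystem restrictions.

    Reactions are filtered first (a reaction survives a compartment
    restriction when at least one reactant sits in — or below — a selected
    compartment); metabolites and genes are then restricted to those
    participating in the surviving reactions.  Without restrictions all
    entities of the model are returned.
    """
    reactions = list(model.reactions.values())
    if subsystems is not None:
        reactions = [r for r in reactions if r.subsystem in subsystems]
    if compartments is not None:
        def in_selection(rxn: Reaction) -> bool:
            for reactant in rxn.reactants:
                path = compartment_path(reactant.compartment_ref, model)
                if compartments & set(path):
                    return True
            return False
        reactions = [r for r in reactions if in_selection(r)]

    if compartments is None and subsystems is None:
        return reactions, list(model.metabolites.values()), list(model.genes.values())

    met_ids = {r.metabolite_ref for rxn in reactions for r in rxn.reactants}
    gene_ids: Set[str] = set()
    for rxn in reactions:
        if rxn.gpr is not None:
            gene_ids |= gpr_genes(rxn.gpr)
    metabolites = [m for a, m in model.metabolites.items() if a in met_ids]
    genes = [g for a, g in model.genes.items() if a in gene_ids]
    return reactions, metabolites, genes


def compare_models(model_a: Model, model_b: Model,
                   restrict_compartments: Optional[Set[str]] = None,
                   restrict_subsystems: Optional[Set[str]] = None,
                   revision_a: int = 0, revision_b: int = 0) -> ComparisonResult:
    """Compare two model snapshots category by category.

    Any two snapshots may be compared: two different models, or two versions
    of the same model to identify development changes.  Restrictions limit
    the result to selected compartments and subsystems before matching.
    """
    rxns_a, mets_a, genes_a = restrict_model(model_a, restrict_compartments,
                                             restrict_subsystems)
    rxns_b, mets_b, genes_b = restrict_model(model_b, restrict_compartments,
                                             restrict_subsystems)
    abbr = lambda e: e.abbreviation
    return ComparisonResult(
        operand_a=(model_a.model_id, revision_a),
        operand_b=(model_b.model_id, revision_b),
        reactions=_greedy_match(
            rxns_a, rxns_b, abbr, abbr,
            lambda a, b: match_reaction(a, b, model_a, model_b)),
        metabolites=_greedy_match(mets_a, mets_b, abbr, abbr, match_metabolite),
        genes=_greedy_match(genes_a, genes_b, abbr, abbr, match_gene),
        restrict_compartments=restrict_compartments,
        restrict_subsystems=restrict_subsystems,
    )


def comparison_table(result: ComparisonResult, delimiter: str = "\t") -> str:
    """Delimited report: one row per entity with its match rule and partner."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(["category", "status", "entity_a", "entity_b", "match_rule"])
    for name in ("reactions", "metabolites", "genes"):
        cat = result.category(name)
        for a, b, rule in cat.shared:
            writer.writerow([name, "shared", a, b, rule])
        for a in cat.unique_a:
            writer.writerow([name, "unique_a", a, "", NO_MATCH])
        for b in cat.unique_b:
            writer.writerow([name, "unique_b", "", b, NO_MATCH])
    return buf.getvalue()


def venn_summary(result: ComparisonResult) -> Dict[str, Tuple[int, int, int]]:
    """Three-number Venn summary (unique A, shared, unique B) per category."""
    return {name: result.category(name).venn
            for name in ("reactions", "metabolites", "genes")}
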