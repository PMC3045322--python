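"""Quick search and synthetic model fixtures.

The quick search scans several entity kinds at once with case-insensitive
substring matching over a fixed per-kind field list: reactions by
abbreviation, name, EC number, enzyme, ORF and KEGG ID; metabolites by
abbreviation, name, formula, ChEBI ID and KEGG ID; genes by abbreviation,
name, EC number, KEGG ID and UniProt ID; organisms by name.  Reaction hits
honour the caller's model selection.

The synthetic-model generator builds fully valid, annotated models for
tests and demonstrations.  Reactions are condensations ``k a + k b -> k ab``
whose product metabolite's formula is the exact elemental sum of the
substrates, plus transport reactions moving one metabolite between
compartments — both conserve every element, so generated models are
balanced by construction.  A companion pair generator builds two models
with a known per-category overlap (shared entities carry matching
identifiers, unique entities are guaranteed unmatched), providing exact
ground truth for the comparison machinery.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import store as store_mod
from .balance import format_formula, parse_formula
from .core import (
    Compartment, Gene, GeneAssociation, Metabolite, Model, Reactant, Reaction,
    SUBSTRATE, PRODUCT,
)

__all__ = [
    "SearchHit",
    "SearchResult",
    "FixtureParams",
    "PairGroundTruth",
    "quick_search",
    "generate_model",
    "generate_model_pair",
    "perturb_reaction_formula",
    "REACTION_SEARCH_FIELDS",
    "METABOLITE_SEARCH_FIELDS",
    "GENE_SEARCH_FIELDS",
]

REACTION_SEARCH_FIELDS = ("abbreviation", "name", "ec_number", "enzyme", "orf", "kegg_id")
METABOLITE_SEARCH_FIELDS = ("abbreviation", "name", "formula", "chebi_id", "kegg_id")
GENE_SEARCH_FIELDS = ("abbreviation", "name", "ec_number", "kegg_id", "uniprot_id")


@dataclass(frozen=True)
class SearchHit:
    entity_id: str
    matched_field: str
    matched_text: str
    model_id: str


@dataclass
class SearchResult:
    reactions: List[SearchHit] = field(default_factory=list)
    metabolites: List[SearchHit] = field(default_factory=list)
    genes: List[SearchHit] = field(default_factory=list)
    organisms: List[SearchHit] = field(default_factory=list)


def _scan(entity, abbr: str, fields: Sequence[str], needle: str,
          model_id: str) -> List[SearchHit]:
    hits = []
    for f in fields:
        value = getattr(entity, f)
        if value is not None and needle in str(value).lower():
            hits.append(SearchHit(abbr, f, str(value), model_id))
    return hits


def quick_search(store: store_mod.Store, term: str,
                 selected_models: Optional[Set[str]] = None) -> SearchResult:
    """Search all models in the store for a term.

    ``selected_models`` restricts the reaction hits (the model selection
    applies to all reaction queries); metabolites, genes and organisms are
    searched across every model.  Only accepted (approved) entity states are
    searched — pending changes are invisible here.
    """
    if not term:
        raise ValueError("search term must be non-empty")
    needle = term.lower()
    result = SearchResult()
    for model_id in store.model_ids():
        model = store_mod.model_at_revision(store, model_id)
        if model.organism and needle in model.organism.lower():
            result.organisms.append(
                SearchHit(model_id, "organism", model.organism, model_id))
        if selected_models is None or model_id in selected_models:
            for abbr in sorted(model.reactions):
                result.reactions.extend(
                    _scan(model.reactions[abbr], abbr, REACTION_SEARCH_FIELDS,
                          needle, model_id))
        for abbr in sorted(model.metabolites):
            result.metabolites.extend(
                _scan(model.metabolites[abbr], abbr, METABOLITE_SEARCH_FIELDS,
                      needle, model_id))
        for abbr in sorted(model.genes):
            result.genes.extend(
                _scan(model.genes[abbr], abbr, GENE_SEARCH_FIELDS, needle, model_id))
    return result


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------

#: organelles placed inside the cytoplasm, in allocation order
_ORGANELLES = ("peroxisome", "nucleus", "mitochondrion", "golgi",
               "endoplasmic_reticulum", "vacuole", "lysosome", "chloroplast")
_SUBSYSTEMS = ("Glycolysis", "TCA cycle", "Pentose phosphate pathway",
               "Amino acid metabolism", "Lipid metabolism", "Transport")
_ELEMENTS = ("C", "H", "N", "O", "P", "S")


@dataclass
class FixtureParams:
    """Study conditions for one synthetic model.

    Defaults describe a small but structurally complete microbial model:
    a four-level compartment tree (extracellular > cytoplasm > organelles),
    forty metabolites, sixty reactions of which a tenth are transports, and
    thirty genes; external identifiers cover the majority of entities, as
    in well-annotated published models.
    """

    n_compartments: int = 4
    hierarchy_depth: int = 3
    n_metabolites: int = 40
    n_reactions: int = 60
    n_genes: int = 30
    kegg_fraction: float = 0.7
    chebi_fraction: float = 0.6
    uniprot_fraction: float = 0.7
    transport_fraction: float = 0.1
    balanced: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_compartments", "n_metabolites", "n_reactions", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("kegg_fraction", "chebi_fraction", "uniprot_fraction",
                     "transport_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _random_formula(rng: random.Random) -> Dict[str, float]:
    counts: Dict[str, float] = {}
    for element in rng.sample(_ELEMENTS, rng.randint(2, 4)):
        counts[element] = float(rng.randint(1, 12))
    return counts


def _sum_formulas(a: Dict[str, float], b: Dict[str, float]) -> Dict[str, float]:
    out = dict(a)
    for sym, c in b.items():
        out[sym] = out.get(sym, 0.0) + c
    return out


def _build_compartments(model: Model, n: int) -> List[str]:
    ids: List[str] = []
    if n >= 1:
        model.add(Compartment("c", "cytoplasm",
                              parent_id="e" if n >= 2 else None))
        ids.append("c")
    if n >= 2:
        model.add(Compartment("e", "extracellular"))
        ids.append("e")
    for organelle in _ORGANELLES[: max(0, n - 2)]:
        model.add(Compartment(organelle, organelle.replace("_", " "), parent_id="c"))
        ids.append(organelle)
    return ids


def generate_model(params: FixtureParams, model_id: str = "fixture") -> Model:
    """Build a deterministic synthetic model with exact entity counts.

    With ``balanced=True`` (the default) every reaction conserves all
    elements by construction.  With ``balanced=False`` a random subset of
    metabolite formulas is perturbed afterwards, so some reactions become
    unbalanced — useful for exercising failure paths.
    """
    rng = random.Random(params.seed)
    if params.n_reactions > 0 and params.n_metabolites < 3:
        raise ValueError("reactions require at least 3 metabolites (a + b -> ab)")
    if params.n_reactions > 0 and params.n_compartments < 1:
        raise ValueError("reactions require at least one compartment")

    model = Model(model_id=model_id, name=f"synthetic model {model_id}",
                  organism="Synthetica exemplaris")
    comp_ids = _build_compartments(model, params.n_compartments)

    # genes
    genes: List[Gene] = []
    for i in range(params.n_genes):
        gene = Gene(
            abbreviation=f"g{i:03d}", name=f"gene {i}",
            ec_number=f"{rng.randint(1, 6)}.{rng.randint(1, 9)}."
                      f"{rng.randint(1, 9)}.{rng.randint(1, 99)}",
            kegg_id=f"K{rng.randint(0, 99999):05d}",
            uniprot_id=(f"P{10000 + i:05d}"
                        if rng.random() < params.uniprot_fraction else None),
        )
        genes.append(gene)
        model.add(gene)

    # metabolites: bases first, then composites summing two bases
    n_composite = min(max(1, params.n_metabolites // 3),
                      params.n_metabolites - 2) if params.n_reactions else 0
    n_base = params.n_metabolites - n_composite
    bases: List[Metabolite] = []
    formulas: Dict[str, Dict[str, float]] = {}
    for i in range(n_base):
        counts = _random_formula(rng)
        met = Metabolite(
            abbreviation=f"m{i:03d}", name=f"metabolite {i}",
            formula=format_formula(counts),
            charge=rng.choice((-2, -1, 0, 0, 1)),
            chebi_id=(str(rng.randint(10000, 99999))
                      if rng.random() < params.chebi_fraction else None),
            kegg_id=(f"C{rng.randint(0, 99999):05d}"
                     if rng.random() < params.kegg_fraction else None),
        )
        formulas[met.abbreviation] = counts
        bases.append(met)
        model.add(met)
    composites: List[Tuple[str, str, str]] = []  # (ab, a, b)
    for i in range(n_composite):
        a, b = rng.sample(bases, 2)
        counts = _sum_formulas(formulas[a.abbreviation], formulas[b.abbreviation])
        abbr = f"x{i:03d}"
        met = Metabolite(
            abbreviation=abbr, name=f"conjugate {i}",
            formula=format_formula(counts),
            charge=(a.charge or 0) + (b.charge or 0),
            chebi_id=(str(rng.randint(10000, 99999))
                      if rng.random() < params.chebi_fraction else None),
            kegg_id=(f"C{rng.randint(0, 99999):05d}"
                     if rng.random() < params.kegg_fraction else None),
        )
        formulas[abbr] = counts
        composites.append((abbr, a.abbreviation, b.abbreviation))
        model.add(met)

    # reactions: transports first, then condensations a + b -> ab
    n_transport = (round(params.transport_fraction * params.n_reactions)
                   if len(comp_ids) >= 2 else 0)
    for j in range(params.n_reactions):
        abbr = f"r{j:03d}"
        gpr = None
        if genes:
            chosen = rng.sample(genes, min(len(genes), rng.randint(1, 3)))
            if len(chosen) == 1:
                gpr = GeneAssociation.leaf(chosen[0].abbreviation)
            else:
                op = rng.choice((GeneAssociation.and_, GeneAssociation.or_))
                gpr = op(*(GeneAssociation.leaf(g.abbreviation) for g in chosen))
        if j < n_transport:
            met = rng.choice(bases)
            src, dst = rng.sample(comp_ids, 2)
            rxn = Reaction(
                abbreviation=abbr, name=f"{met.name} transport",
                reactants=[
                    Reactant(met.abbreviation, 1.0, src, SUBSTRATE),
                    Reactant(met.abbreviation, 1.0, dst, PRODUCT),
                ],
                reversible=rng.random() < 0.7,
                subsystem="Transport", gpr=gpr,
            )
        else:
            ab, a, b = composites[(j - n_transport) % len(composites)]
            k = float(1 + (j - n_transport) // len(composites) % 3)
            comp = rng.choice(comp_ids)
            rxn = Reaction(
                abbreviation=abbr, name=f"synthesis of {ab}",
                reactants=[
                    Reactant(a, k, comp, SUBSTRATE),
                    Reactant(b, k, comp, SUBSTRATE),
                    Reactant(ab, k, comp, PRODUCT),
                ],
                reversible=rng.random() < 0.3,
                ec_number=f"{rng.randint(1, 6)}.{rng.randint(1, 9)}."
                          f"{rng.randint(1, 9)}.{rng.randint(1, 99)}",
                kegg_id=(f"R{rng.randint(0, 99999):05d}"
                         if rng.random() < params.kegg_fraction else None),
                subsystem=rng.choice(_SUBSYSTEMS[:-1]),
                gpr=gpr,
                citations=[f"PMID:{rng.randint(10000000, 29999999)}"],
            )
        if gpr is not None:
            first = sorted(g.abbreviation for g in chosen)[0]
            rxn.enzyme = model.genes[first].name
            rxn.orf = first.upper()
        model.add(rxn)

    if not params.balanced and model.metabolites:
        for met in rng.sample(sorted(model.metabolites), max(1, len(model.metabolites) // 5)):
            _bump_formula(model.metabolites[met], rng)
    return model


def _bump_formula(met: Metabolite, rng: random.Random) -> str:
    counts = parse_formula(met.formula) if met.formula else {}
    element = rng.choice(sorted(counts) or ["C"])
    counts[element] = counts.get(element, 0.0) + 1.0
    met.formula = format_formula(counts)
    return element


def perturb_reaction_formula(model: Model, reaction: Reaction,
                             rng: random.Random) -> Tuple[str, str, Optional[str]]:
    """Alter one participating metabolite's formula by one atom.

    Picks a metabolite whose net stoichiometry in the reaction is nonzero
    (so the alteration cannot cancel between the two sides) and increments
    one of its element counts.  Returns (metabolite abbreviation, perturbed
    element, previous formula) so the caller can restore the model.
    """
    net: Dict[str, float] = {}
    for r in reaction.reactants:
        sign = 1.0 if r.side == PRODUCT else -1.0
        net[r.metabolite_ref] = net.get(r.metabolite_ref, 0.0) + sign * r.stoichiometry
    candidates = sorted(abbr for abbr, v in net.items() if v != 0)
    if not candidates:
        raise ValueError(f"reaction {reaction.abbreviation} has no one-sided metabolite")
    abbr = rng.choice(candidates)
    met = model.metabolite(abbr)
    old = met.formula
    element = _bump_formula(met, rng)
    return abbr, element, old


# ---------------------------------------------------------------------------
# Model-pair generator with known overlap
# ---------------------------------------------------------------------------


@dataclass
class PairGroundTruth:
    """Intended comparison outcome for a generated model pair."""

    shared: Dict[str, List[Tuple[str, str, str]]]  # category -> (a, b, rule)
    unique_a: Dict[str, List[str]]
    unique_b: Dict[str, List[str]]

    def venn(self, category: str) -> Tuple[int, int, int]:
        return (len(self.unique_a[category]), len(self.shared[category]),
                len(self.unique_b[category]))


def generate_model_pair(
    overlap: Dict[str, Tuple[int, int, int]],
    seed: int = 0,
    kegg_match_fraction: float = 0.5,
) -> Tuple[Model, Model, PairGroundTruth]:
    """Build two models with exactly known shared/unique entities.

    ``overlap`` maps each category (``reactions``, ``metabolites``,
    ``genes``) to ``(n_shared, n_unique_a, n_unique_b)``.  Shared reactions
    are split between KEGG-identified pairs and pairs that match only by
    their identical chemical equation (``kegg_match_fraction`` controls the
    mix); every unique reaction carries a globally unique KEGG ID and a
    globally unique equation, so it can match nothing on the other side.
    Matching is unambiguous by construction: greedy one-to-one matching and
    exhaustive matching find the same pairs.
    """
    rng = random.Random(seed)
    s_r, ua_r, ub_r = overlap.get("reactions", (0, 0, 0))
    s_m, ua_m, ub_m = overlap.get("metabolites", (0, 0, 0))
    s_g, ua_g, ub_g = overlap.get("genes", (0, 0, 0))
    for name, (s, ua, ub) in (("reactions", (s_r, ua_r, ub_r)),
                              ("metabolites", (s_m, ua_m, ub_m)),
                              ("genes", (s_g, ua_g, ub_g))):
        if min(s, ua, ub) < 0:
            raise ValueError(f"negative overlap counts for {name}")
    n_reactions_total = s_r + ua_r + ub_r
    if n_reactions_total > 0 and s_m < 3:
        raise ValueError(
            "reaction overlaps require at least 3 shared metabolites "
            "(two substrates and their conjugate)")

    model_a = Model("pair_A", name="pair fixture A", organism="Synthetica exemplaris")
    model_b = Model("pair_B", name="pair fixture B", organism="Synthetica altera")
    for model in (model_a, model_b):
        model.add(Compartment("e", "extracellular"))
        model.add(Compartment("c", "cytoplasm", parent_id="e"))

    truth = PairGroundTruth(
        shared={"reactions": [], "metabolites": [], "genes": []},
        unique_a={"reactions": [], "metabolites": [], "genes": []},
        unique_b={"reactions": [], "metabolites": [], "genes": []},
    )

    # --- metabolites -------------------------------------------------------
    n_base = max(2, s_m - max(1, s_m // 3)) if n_reactions_total else s_m
    n_base = min(n_base, s_m)
    bases: List[str] = []
    composites: List[Tuple[str, str, str]] = []
    formulas: Dict[str, Dict[str, float]] = {}

    def shared_metabolite(i: int, abbr: str, counts: Dict[str, float],
                          name: str) -> None:
        id_mode = rng.random()
        chebi = str(20000 + i) if id_mode < 0.4 else None
        kegg = f"C{40000 + i:05d}" if 0.4 <= id_mode < 0.8 else None
        rule = "chebi" if chebi else ("kegg" if kegg else "name")
        for model in (model_a, model_b):
            model.add(Metabolite(abbr, name, format_formula(counts),
                                 charge=0, chebi_id=chebi, kegg_id=kegg))
        truth.shared["metabolites"].append((abbr, abbr, rule))

    for i in range(s_m):
        if i < n_base:
            counts = _random_formula(rng)
            abbr = f"sm{i:03d}"
            bases.append(abbr)
            shared_metabolite(i, abbr, counts, f"shared metabolite {i}")
        else:
            a, b = rng.sample(bases, 2)
            counts = _sum_formulas(formulas[a], formulas[b])
            abbr = f"sx{i:03d}"
            composites.append((abbr, a, b))
            shared_metabolite(i, abbr, counts, f"shared conjugate {i}")
        formulas[abbr] = counts
    assert not n_reactions_total or composites, "s_m >= 3 guarantees a conjugate"

    for i in range(ua_m):
        model_a.add(Metabolite(f"uam{i:03d}", f"A-only metabolite {i}",
                               format_formula(_random_formula(rng)),
                               chebi_id=str(60000 + i)))
        truth.unique_a["metabolites"].append(f"uam{i:03d}")
    for i in range(ub_m):
        model_b.add(Metabolite(f"ubm{i:03d}", f"B-only metabolite {i}",
                               format_formula(_random_formula(rng)),
                               chebi_id=str(70000 + i)))
        truth.unique_b["metabolites"].append(f"ubm{i:03d}")

    # --- genes -------------------------------------------------------------
    for i in range(s_g):
        uniprot = f"P{50000 + i:05d}" if rng.random() < 0.6 else None
        rule = "uniprot" if uniprot else "name"
        for model, abbr in ((model_a, f"sga{i:03d}"), (model_b, f"sgb{i:03d}")):
            model.add(Gene(abbr, name=f"shared gene {i}", uniprot_id=uniprot))
        truth.shared["genes"].append((f"sga{i:03d}", f"sgb{i:03d}", rule))
    for i in range(ua_g):
        model_a.add(Gene(f"uag{i:03d}", name=f"A-only gene {i}",
                         uniprot_id=f"P{80000 + i:05d}"))
        truth.unique_a["genes"].append(f"uag{i:03d}")
    for i in range(ub_g):
        model_b.add(Gene(f"ubg{i:03d}", name=f"B-only gene {i}",
                         uniprot_id=f"P{90000 + i:05d}"))
        truth.unique_b["genes"].append(f"ubg{i:03d}")

    # --- reactions ---------------------------------------------------------
    # a global stoichiometric multiplier makes every equation unique
    next_k = 1.0

    def condensation(abbr: str, kegg: Optional[str], k: float) -> Reaction:
        ab, a, b = composites[int(k) % len(composites)]
        return Reaction(
            abbreviation=abbr, name=f"synthesis {abbr}",
            reactants=[
                Reactant(a, k, "c", SUBSTRATE),
                Reactant(b, k, "c", SUBSTRATE),
                Reactant(ab, k, "c", PRODUCT),
            ],
            reversible=False, kegg_id=kegg, subsystem="Biosynthesis",
        )

    n_kegg_shared = round(kegg_match_fraction * s_r)
    for i in range(s_r):
        k, next_k = next_k, next_k + 1
        kegg = f"R{30000 + i:05d}" if i < n_kegg_shared else None
        rule = "kegg" if kegg else "equation"
        ra, rb = f"sra{i:03d}", f"srb{i:03d}"
        model_a.add(condensation(ra, kegg, k))
        model_b.add(condensation(rb, kegg, k))
        truth.shared["reactions"].append((ra, rb, rule))
    for i in range(ua_r):
        k, next_k = next_k, next_k + 1
        abbr = f"uar{i:03d}"
        model_a.add(condensation(abbr, f"R{60000 + i:05d}", k))
        truth.unique_a["reactions"].append(abbr)
    for i in range(ub_r):
        k, next_k = next_k, next_k + 1
        abbr = f"ubr{i:03d}"
        model_b.add(condensation(abbr, f"R{70000 + i:05d}", k))
        truth.unique_b["reactions"].append(abbr)

    return model_a, model_b, truth
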