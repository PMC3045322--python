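"""SBML import/export with MIRIAM annotations and compartmentalization modes.

Models are written as SBML Level 2 Version 4 — the dialect with the widest
support among constraint-based analysis tools — and read back from any
Level 2 version or Level 3 core document.  Two profiles are available:

* ``full`` carries everything the store knows about a model, using MIRIAM
  annotations (RDF CV terms) for external references and structured notes
  lines for fields SBML core cannot express (formula, charge, gene records,
  subsystem, GPR, citations, organism).
* ``cobra`` is optimized for the COBRA toolbox: GPRs and subsystems in the
  conventional ``GENE_ASSOCIATION`` / ``SUBSYSTEM`` notes, formulas in
  ``FORMULA`` notes, and flux bounds derived from reversibility carried both
  as kinetic-law parameters and as notes lines.

Export can restrict the emitted reactions to selected subsystems and/or an
explicit reaction set (e.g. the result of a query), and can re-assign
compartments in three modes: ``complete`` (as stored), ``partial_decomp``
(everything inside the cytoplasm is merged into the cytoplasm) and
``full_decomp`` (a single unsegregated compartment; transport reactions that
cancel to nothing are dropped and reported).

Every species reference is written with an explicit stoichiometry value,
including the default of one, so that downstream parsers never have to rely
on implicit defaults.  Entities are emitted in sorted-abbreviation order,
which makes repeated exports of the same snapshot byte-identical and
diff-able.
"""

from __future__ import annotations

import copy
import csv
import io
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple
from xml.sax.saxutils import escape, unescape

import libsbml

from . import core
from .core import (
    Compartment, Gene, GeneAssociation, Metabolite, Model, MiriamRef,
    Reactant, Reaction, SUBSTRATE, PRODUCT, is_within, validate_model,
)

__all__ = [
    "ExportOptions",
    "ImportReport",
    "ExportReport",
    "DecompReport",
    "SbmlError",
    "import_sbml",
    "export_sbml",
    "decompartmentalize",
    "export_table",
    "validate_sbml",
    "gpr_to_cobra",
]

SBML_LEVEL = 2
SBML_VERSION = 4

COBRA_LOWER_REVERSIBLE = -1000.0
COBRA_UPPER = 1000.0

#: Compartment names recognized as the cytoplasm for auto-detection.
CYTOPLASM_NAMES = frozenset({"cytoplasm", "cytosol"})

#: Single compartment used for the unsegregated (fully decompartmentalized)
#: system; SBML requires every species to live in some compartment.
UNSEGREGATED_ID = "cell"


class SbmlError(ValueError):
    pass


@dataclass
class ExportOptions:
    mode: str = "complete"  # "complete" | "partial_decomp" | "full_decomp"
    subsystems: Optional[Set[str]] = None
    reaction_filter: Optional[Set[str]] = None
    profile: str = "full"  # "full" | "cobra"
    cytoplasm_id: Optional[str] = None

    def __post_init__(self):
        if self.mode not in ("complete", "partial_decomp", "full_decomp"):
            raise ValueError(f"unknown compartmentalization mode {self.mode!r}")
        if self.profile not in ("full", "cobra"):
            raise ValueError(f"unknown export profile {self.profile!r}")


@dataclass
class ImportReport:
    counts: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    level_version: str = ""


@dataclass
class ExportReport:
    counts: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    level_version: str = f"L{SBML_LEVEL}V{SBML_VERSION}"


@dataclass
class DecompReport:
    mode: str
    reassigned_reactants: int = 0
    removed_compartments: List[str] = field(default_factory=list)
    dropped_reactions: List[str] = field(default_factory=list)
    cancelled_reactants: int = 0


# ---------------------------------------------------------------------------
# Identifier and notes helpers
# ---------------------------------------------------------------------------

_SID_RE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str, prefix: str = "") -> str:
    s = _SID_RE.sub("_", raw)
    if prefix:
        s = prefix + s
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return s


def _notes_xml(lines: Sequence[str]) -> str:
    body = "".join(f"<p>{escape(line)}</p>" for line in lines)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


_NOTE_LINE_RE = re.compile(r"<p[^>]*>\s*([^<]*?)\s*</p>", re.S)


def _parse_notes(sbase) -> Dict[str, List[str]]:
    """Collect ``KEY: value`` lines from an element's notes."""
    out: Dict[str, List[str]] = {}
    if not sbase.isSetNotes():
        return out
    for raw in _NOTE_LINE_RE.findall(sbase.getNotesString()):
        line = unescape(raw).strip()
        key, sep, value = line.partition(":")
        if sep:
            out.setdefault(key.strip().upper(), []).append(value.strip())
    return out


def _first(notes: Dict[str, List[str]], key: str) -> Optional[str]:
    values = notes.get(key)
    return values[0] if values else None


def gpr_to_cobra(assoc: GeneAssociation) -> str:
    """COBRA-style GPR text: lowercase ``and``/``or`` with parentheses."""
    if assoc.op == "leaf":
        return assoc.gene  # type: ignore[return-value]
    sep = f" {assoc.op} "
    parts = [gpr_to_cobra(c) if c.op == "leaf" else f"({gpr_to_cobra(c)})"
             for c in assoc.children]
    return sep.join(parts)


# MIRIAM qualifier <-> libsbml biology-qualifier constants
_BQB_BY_NAME = {
    "is": libsbml.BQB_IS,
    "hasPart": libsbml.BQB_HAS_PART,
    "isPartOf": libsbml.BQB_IS_PART_OF,
    "isVersionOf": libsbml.BQB_IS_VERSION_OF,
    "hasVersion": libsbml.BQB_HAS_VERSION,
    "isHomologTo": libsbml.BQB_IS_HOMOLOG_TO,
    "isDescribedBy": libsbml.BQB_IS_DESCRIBED_BY,
    "isEncodedBy": libsbml.BQB_IS_ENCODED_BY,
    "encodes": libsbml.BQB_ENCODES,
}
_NAME_BY_BQB = {v: k for k, v in _BQB_BY_NAME.items()}


def _write_cvterms(element, refs: Sequence[MiriamRef]) -> None:
    if not refs:
        return
    for ref in refs:
        term = libsbml.CVTerm()
        term.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
        term.setBiologicalQualifierType(_BQB_BY_NAME.get(ref.qualifier, libsbml.BQB_IS))
        term.addResource(ref.to_urn())
        element.addCVTerm(term)


def _read_cvterms(element) -> List[MiriamRef]:
    refs: List[MiriamRef] = []
    for i in range(element.getNumCVTerms()):
        term = element.getCVTerm(i)
        qualifier = _NAME_BY_BQB.get(term.getBiologicalQualifierType(), "is")
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            try:
                refs.append(MiriamRef.from_string(uri, qualifier))
            except ValueError:
                refs.append(MiriamRef("unknown", uri, qualifier))
    return refs


def _pop_ref(refs: List[MiriamRef], datatype: str) -> Optional[str]:
    for i, ref in enumerate(refs):
        if ref.datatype == datatype and ref.qualifier == "is":
            return refs.pop(i).identifier
    return None


# ---------------------------------------------------------------------------
# Decompartmentalization
# ---------------------------------------------------------------------------


def _find_cytoplasm(model: Model, cytoplasm_id: Optional[str]) -> str:
    if cytoplasm_id is not None:
        model.compartment(cytoplasm_id)
        return cytoplasm_id
    for comp in model.compartments.values():
        if comp.name.lower() in CYTOPLASM_NAMES or comp.compartment_id.lower() in CYTOPLASM_NAMES:
            return comp.compartment_id
    raise SbmlError(
        "no cytoplasm compartment could be auto-detected "
        f"(looked for names {sorted(CYTOPLASM_NAMES)}); pass cytoplasm_id explicitly"
    )


def decompartmentalize(model: Model, mode: str,
                       cytoplasm_id: Optional[str] = None
                       ) -> Tuple[Model, DecompReport]:
    """Re-assign reactions and metabolites to compartments.

    ``complete`` returns the model as stored.  ``partial_decomp`` re-assigns
    every reactant sitting in a compartment within the cytoplasm (e.g.
    peroxisome, nucleus) to the cytoplasm itself and removes the emptied
    sub-compartments; everything else (e.g. extracellular space) is left
    untouched, so the reaction count is preserved.  ``full_decomp`` puts all
    reactants in one unsegregated compartment, cancels reactants that then
    appear identically on both sides with equal stoichiometry, and drops —
    and reports — reactions that cancel away entirely (pure transport).
    """
    out = copy.deepcopy(model)
    report = DecompReport(mode=mode)

    if mode == "complete":
        return out, report

    if mode == "partial_decomp":
        cyto = _find_cytoplasm(out, cytoplasm_id)
        for rxn in out.reactions.values():
            for reactant in rxn.reactants:
                if reactant.compartment_ref != cyto and is_within(
                        reactant.compartment_ref, cyto, out):
                    reactant.compartment_ref = cyto
                    report.reassigned_reactants += 1
        removed = [cid for cid in out.compartments
                   if cid != cyto and is_within(cid, cyto, out)]
        for cid in removed:
            del out.compartments[cid]
        report.removed_compartments = sorted(removed)
        return out, report

    if mode != "full_decomp":
        raise ValueError(f"unknown compartmentalization mode {mode!r}")

    already_unsegregated = set(out.compartments) == {UNSEGREGATED_ID}
    out.compartments = {UNSEGREGATED_ID: Compartment(UNSEGREGATED_ID, "unsegregated cell")}
    dropped: List[str] = []
    for rxn in list(out.reactions.values()):
        sums: Dict[Tuple[str, str], float] = {}
        for reactant in rxn.reactants:
            key = (reactant.metabolite_ref, reactant.side)
            sums[key] = sums.get(key, 0.0) + reactant.stoichiometry
        new_reactants: List[Reactant] = []
        for (met, side), total in sums.items():
            other = sums.get((met, PRODUCT if side == SUBSTRATE else SUBSTRATE))
            if other is not None and other == total:
                if side == SUBSTRATE:  # count each cancelled pair once
                    report.cancelled_reactants += 1
                continue
            new_reactants.append(Reactant(met, total, UNSEGREGATED_ID, side))
        new_reactants.sort(key=lambda r: (r.side, r.metabolite_ref))
        if not new_reactants and rxn.reactants:
            dropped.append(rxn.abbreviation)
            del out.reactions[rxn.abbreviation]
        else:
            if not already_unsegregated:
                report.reassigned_reactants += len(new_reactants)
            rxn.reactants = new_reactants
    report.dropped_reactions = sorted(dropped)
    return out, report


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _filter_reactions(model: Model, options: ExportOptions) -> List[Reaction]:
    reactions = list(model.reactions.values())
    if options.subsystems is not None:
        unknown = options.subsystems - set(model.subsystems)
        if unknown:
            raise SbmlError(f"unknown subsystems in filter: {sorted(unknown)}")
        reactions = [r for r in reactions if r.subsystem in options.subsystems]
    if options.reaction_filter is not None:
        unknown = options.reaction_filter - set(model.reactions)
        if unknown:
            raise SbmlError(f"unknown reactions in filter: {sorted(unknown)}")
        reactions = [r for r in reactions if r.abbreviation in options.reaction_filter]
    return sorted(reactions, key=lambda r: r.abbreviation)


def export_sbml(model: Model, options: Optional[ExportOptions] = None
                ) -> Tuple[str, ExportReport]:
    """Serialize a model snapshot to an SBML Level 2 Version 4 document.

    The snapshot must be internally consistent (no referential-integrity
    errors).  Returns the document text and a report of emitted entity
    counts and warnings.
    """
    options = options or ExportOptions()
    errors = [i for i in validate_model(model) if i.severity == "error"]
    if errors:
        raise SbmlError(
            "snapshot is not valid: " + "; ".join(f"{i.entity}: {i.message}" for i in errors[:5])
        )

    report = ExportReport()
    if options.mode != "complete":
        model, decomp = decompartmentalize(model, options.mode, options.cytoplasm_id)
        for rxn in decomp.dropped_reactions:
            report.warnings.append(f"reaction {rxn} dropped by full decompartmentalization")
    else:
        model = model

    reactions = _filter_reactions(model, options)
    filtered = options.subsystems is not None or options.reaction_filter is not None

    # species = (metabolite, compartment) pairs in use; unused metabolites are
    # kept (in the model's first compartment) so no information is lost.
    pairs: Set[Tuple[str, str]] = set()
    for rxn in reactions:
        for reactant in rxn.reactants:
            pairs.add((reactant.metabolite_ref, reactant.compartment_ref))
    used_mets = {m for m, _ in pairs}
    default_comp = sorted(model.compartments)[0] if model.compartments else UNSEGREGATED_ID
    if not filtered:
        for met in model.metabolites.values():
            if met.abbreviation not in used_mets:
                pairs.add((met.abbreviation, default_comp))

    if filtered:
        gene_ids: Set[str] = set()
        for rxn in reactions:
            if rxn.gpr is not None:
                gene_ids |= core.gpr_genes(rxn.gpr)
        genes = sorted((g for a, g in model.genes.items() if a in gene_ids),
                       key=lambda g: g.abbreviation)
    else:
        genes = sorted(model.genes.values(), key=lambda g: g.abbreviation)

    document = libsbml.SBMLDocument(SBML_LEVEL, SBML_VERSION)
    sbml_model = document.createModel()
    sbml_model.setId(_sid(model.model_id))
    sbml_model.setMetaId("meta_" + _sid(model.model_id))
    sbml_model.setName(model.name or model.model_id)
    _write_cvterms(sbml_model, model.annotations)

    model_lines: List[str] = []
    if options.profile == "full":
        if model.organism:
            model_lines.append(f"ORGANISM: {model.organism}")
        if model.version_label:
            model_lines.append(f"VERSION: {model.version_label}")
        if model.notes:
            model_lines.append("NOTES: " + " ".join(model.notes.split()))
        for sub in model.subsystems:
            model_lines.append(f"SUBSYSTEM: {sub}")
        for gene in genes:
            model_lines.append(
                "GENE: " + "|".join(
                    part or "" for part in (
                        gene.abbreviation, gene.name, gene.ec_number,
                        gene.kegg_id, gene.uniprot_id))
            )
    if model_lines:
        sbml_model.setNotes(_notes_xml(model_lines))

    # compartments (parent relation via the L2 'outside' attribute)
    comp_count = 0
    for comp in sorted(model.compartments.values(), key=lambda c: c.compartment_id):
        sc = sbml_model.createCompartment()
        sc.setId(_sid(comp.compartment_id))
        sc.setMetaId("meta_C_" + _sid(comp.compartment_id))
        sc.setName(comp.name or comp.compartment_id)
        sc.setSize(1.0)
        if comp.parent_id:
            sc.setOutside(_sid(comp.parent_id))
        _write_cvterms(sc, comp.annotations)
        comp_count += 1

    # species
    species_count = 0
    for met_abbr, comp_id in sorted(pairs):
        met = model.metabolite(met_abbr)
        sp = sbml_model.createSpecies()
        sp.setId(_sid(f"{met_abbr}_{comp_id}", "M_"))
        sp.setMetaId("meta_" + _sid(f"{met_abbr}_{comp_id}", "M_"))
        sp.setName(met.name or met.abbreviation)
        sp.setCompartment(_sid(comp_id))
        sp.setInitialAmount(0.0)
        lines = []
        if met.formula:
            lines.append(f"FORMULA: {met.formula}")
        if met.charge is not None:
            lines.append(f"CHARGE: {met.charge}")
        if options.profile == "full":
            lines.append(f"ABBREVIATION: {met_abbr}")
        if lines:
            sp.setNotes(_notes_xml(lines))
        refs = list(met.annotations)
        if met.chebi_id:
            refs.insert(0, MiriamRef("chebi", met.chebi_id))
        if met.kegg_id:
            refs.insert(1 if met.chebi_id else 0, MiriamRef("kegg.compound", met.kegg_id))
        _write_cvterms(sp, refs)
        species_count += 1

    # reactions
    for rxn in reactions:
        sr = sbml_model.createReaction()
        sr.setId(_sid(rxn.abbreviation, "R_"))
        sr.setMetaId("meta_" + _sid(rxn.abbreviation, "R_"))
        sr.setName(rxn.name or rxn.abbreviation)
        sr.setReversible(rxn.reversible)
        for reactant in sorted(rxn.reactants,
                               key=lambda r: (r.side, r.metabolite_ref, r.compartment_ref)):
            ref = (sr.createProduct() if reactant.side == PRODUCT
                   else sr.createReactant())
            ref.setSpecies(_sid(f"{reactant.metabolite_ref}_{reactant.compartment_ref}", "M_"))
            # stoichiometry is always written explicitly, including 1
            ref.setStoichiometry(float(reactant.stoichiometry))

        lines = []
        if rxn.gpr is not None:
            lines.append(f"GENE_ASSOCIATION: {gpr_to_cobra(rxn.gpr)}")
        if rxn.subsystem:
            lines.append(f"SUBSYSTEM: {rxn.subsystem}")
        if options.profile == "full":
            lines.append(f"ABBREVIATION: {rxn.abbreviation}")
            if rxn.enzyme:
                lines.append(f"ENZYME: {rxn.enzyme}")
            if rxn.orf:
                lines.append(f"ORF: {rxn.orf}")
            if rxn.is_exchange:
                lines.append("EXCHANGE: true")
            for citation in rxn.citations:
                lines.append(f"CITATION: {citation}")
        if options.profile == "cobra":
            lower = COBRA_LOWER_REVERSIBLE if rxn.reversible else 0.0
            lines.append(f"LOWER_BOUND: {lower}")
            lines.append(f"UPPER_BOUND: {COBRA_UPPER}")
        if lines:
            sr.setNotes(_notes_xml(lines))

        if options.profile == "cobra":
            law = sr.createKineticLaw()
            law.setFormula("FLUX_VALUE")
            lower = COBRA_LOWER_REVERSIBLE if rxn.reversible else 0.0
            for pname, pvalue in (
                ("LOWER_BOUND", lower), ("UPPER_BOUND", COBRA_UPPER),
                ("OBJECTIVE_COEFFICIENT", 0.0), ("FLUX_VALUE", 0.0),
            ):
                param = law.createParameter()
                param.setId(pname)
                param.setValue(pvalue)
                param.setUnits("dimensionless")

        refs = list(rxn.annotations)
        if rxn.ec_number:
            refs.insert(0, MiriamRef("ec-code", rxn.ec_number))
        if rxn.kegg_id:
            refs.insert(1 if rxn.ec_number else 0, MiriamRef("kegg.reaction", rxn.kegg_id))
        _write_cvterms(sr, refs)

    report.counts = {
        "compartments": comp_count,
        "species": species_count,
        "metabolites": len({m for m, _ in pairs}),
        "reactions": len(reactions),
        "genes": len(genes),
    }
    writer = libsbml.SBMLWriter()
    return writer.writeSBMLToString(document), report


def validate_sbml(text: str) -> List[str]:
    """libSBML consistency check; returns messages of error severity."""
    document = libsbml.readSBMLFromString(text)
    problems = []
    for i in range(document.getNumErrors()):
        err = document.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            problems.append(err.getMessage().strip())
    document.checkConsistency()
    for i in range(document.getNumErrors()):
        err = document.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            message = err.getMessage().strip()
            if message not in problems:
                problems.append(message)
    return problems


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------


def import_sbml(text: str, model_id: Optional[str] = None
                ) -> Tuple[Model, ImportReport]:
    """Build a model from an SBML document (Level 2 any version, or Level 3).

    Compartment parent relations are read from the Level 2 ``outside``
    attribute; formulas, charges and auxiliary fields from notes lines;
    external references (ChEBI, KEGG, EC, UniProt, ...) from MIRIAM
    annotations.  ``GENE_ASSOCIATION`` and ``SUBSYSTEM`` notes are parsed in
    both the COBRA dialect and the bracketed rule form.
    """
    document = libsbml.readSBMLFromString(text)
    fatal = [document.getError(i).getMessage().strip()
             for i in range(document.getNumErrors())
             if document.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
    if fatal:
        raise SbmlError("SBML parse failed: " + "; ".join(fatal[:3]))
    sbml_model = document.getModel()
    if sbml_model is None:
        raise SbmlError("document contains no model")

    report = ImportReport(
        level_version=f"L{document.getLevel()}V{document.getVersion()}")

    model = Model(
        model_id=model_id or sbml_model.getId() or "imported",
        name=sbml_model.getName() or sbml_model.getId(),
    )
    model.annotations = _read_cvterms(sbml_model)
    model_notes = _parse_notes(sbml_model)
    model.organism = _first(model_notes, "ORGANISM") or ""
    model.version_label = _first(model_notes, "VERSION") or ""
    model.notes = _first(model_notes, "NOTES") or ""
    for sub in model_notes.get("SUBSYSTEM", []):
        if sub not in model.subsystems:
            model.subsystems.append(sub)
    for line in model_notes.get("GENE", []):
        parts = (line.split("|") + [""] * 5)[:5]
        model.add(Gene(parts[0], parts[1], parts[2] or None,
                       parts[3] or None, parts[4] or None))

    for i in range(sbml_model.getNumCompartments()):
        sc = sbml_model.getCompartment(i)
        model.add(Compartment(
            compartment_id=sc.getId(),
            name=sc.getName() or sc.getId(),
            parent_id=sc.getOutside() or None,
            annotations=_read_cvterms(sc),
        ))

    # species -> metabolites (merged across compartments by abbreviation)
    species_info: Dict[str, Tuple[str, str]] = {}  # species id -> (abbr, compartment)
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        notes = _parse_notes(sp)
        comp = sp.getCompartment()
        abbr = _first(notes, "ABBREVIATION")
        if not abbr:
            abbr = sp.getId()
            if abbr.startswith("M_"):
                abbr = abbr[2:]
            if comp and abbr.endswith("_" + comp):
                abbr = abbr[: -(len(comp) + 1)]
        species_info[sp.getId()] = (abbr, comp)
        if abbr in model.metabolites:
            continue
        refs = _read_cvterms(sp)
        chebi = _pop_ref(refs, "chebi") or _pop_ref(refs, "obo.chebi")
        kegg = _pop_ref(refs, "kegg.compound")
        charge_text = _first(notes, "CHARGE")
        if charge_text is None and sp.isSetCharge():
            charge_text = str(sp.getCharge())
        model.add(Metabolite(
            abbreviation=abbr,
            name=sp.getName() or abbr,
            formula=_first(notes, "FORMULA"),
            charge=int(charge_text) if charge_text not in (None, "") else None,
            chebi_id=chebi, kegg_id=kegg, annotations=refs,
        ))

    unknown_species: List[str] = []
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        notes = _parse_notes(sr)
        abbr = _first(notes, "ABBREVIATION")
        if not abbr:
            abbr = sr.getId()
            if abbr.startswith("R_"):
                abbr = abbr[2:]

        reactants: List[Reactant] = []
        for side, count, getter in (
            (SUBSTRATE, sr.getNumReactants(), sr.getReactant),
            (PRODUCT, sr.getNumProducts(), sr.getProduct),
        ):
            for j in range(count):
                ref = getter(j)
                info = species_info.get(ref.getSpecies())
                if info is None:
                    unknown_species.append(f"{sr.getId()}: {ref.getSpecies()}")
                    continue
                met_abbr, comp = info
                stoich = ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
                reactants.append(Reactant(met_abbr, stoich, comp, side))

        gpr_text = _first(notes, "GENE_ASSOCIATION") or _first(notes, "GENE ASSOCIATION")
        gpr = core.parse_gpr(gpr_text) if gpr_text else None
        refs = _read_cvterms(sr)
        ec = _pop_ref(refs, "ec-code")
        kegg = _pop_ref(refs, "kegg.reaction")
        rxn = Reaction(
            abbreviation=abbr,
            name=sr.getName() or abbr,
            reactants=reactants,
            reversible=sr.getReversible(),
            ec_number=ec, kegg_id=kegg,
            subsystem=_first(notes, "SUBSYSTEM"),
            gpr=gpr,
            enzyme=_first(notes, "ENZYME"),
            orf=_first(notes, "ORF"),
            citations=notes.get("CITATION", []),
            annotations=refs,
            is_exchange=(_first(notes, "EXCHANGE") == "true") or not reactants,
        )
        model.add(rxn)
        if gpr is not None:
            for gene in sorted(core.gpr_genes(gpr)):
                if gene not in model.genes:
                    model.add(Gene(gene))
                    report.warnings.append(
                        f"gene {gene} declared only via a GENE_ASSOCIATION rule")

    if unknown_species:
        raise SbmlError("reactions reference unknown species: "
                        + "; ".join(unknown_species))

    report.counts = {
        "compartments": len(model.compartments),
        "species": sbml_model.getNumSpecies(),
        "metabolites": len(model.metabolites),
        "reactions": len(model.reactions),
        "genes": len(model.genes),
    }
    return model, report


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

REACTION_COLUMNS = ("abbreviation", "name", "equation", "ec_number", "kegg_id", "subsystem")
METABOLITE_COLUMNS = ("abbreviation", "name", "formula", "chebi_id", "kegg_id")


def export_table(entities: Sequence, kind: str, delimiter: str = "\t") -> str:
    """Delimited table of a homogeneous reaction or metabolite list.

    One row per entity with a fixed column set; substitutes for
    spreadsheet/PDF list export.
    """
    if kind not in ("reaction", "metabolite"):
        raise ValueError(f"unknown table kind {kind!r}")
    expected = Reaction if kind == "reaction" else Metabolite
    for e in entities:
        if not isinstance(e, expected):
            raise ValueError(
                f"mixed entity kinds: expected {expected.__name__}, "
                f"got {type(e).__name__}")
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    if kind == "reaction":
        writer.writerow(REACTION_COLUMNS)
        for r in entities:
            writer.writerow([r.abbreviation, r.name, r.equation_text(),
                             r.ec_number or "", r.kegg_id or "", r.subsystem or ""])
    else:
        writer.writerow(METABOLITE_COLUMNS)
        for m in entities:
            writer.writerow([m.abbreviation, m.name, m.formula or "",
                             m.chebi_id or "", m.kegg_id or ""])
    return buf.getvalue()
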