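# Methods

This note documents the models, conventions and design choices behind
`gemstore`, in the spirit of the methods documentation that mature
scientific packages ship alongside their code.

## Data model and its assumptions

A model is a closed universe: every reactant must name a metabolite and a
compartment declared in the same model, and every reaction subsystem must
appear in the model's subsystem list. `validate_model` enforces exactly
these referential-integrity rules as errors. One deliberate exception:
GPR leaves naming genes absent from the model are **warnings**, because
draft reconstructions routinely reference genes that have not been
annotated yet; failing hard would make the store unusable for the very
workflow it supports.

Compartments form a forest via `parent_id` references. The containment
test `is_within` is ancestor-or-self: a compartment is within itself.
This reflexive reading is what makes partial decompartmentalization
behave sensibly — a reactant already in the cytoplasm must map to the
cytoplasm, not be treated as outside it.

### GPR rules

The grammar accepts operands and operators separated by whitespace, with
`AND`/`OR` case-insensitive and grouping by either square brackets or
parentheses; serialization emits square brackets. In unbracketed mixed
expressions **AND binds tighter than OR**, the convention used by COBRA
tooling; fully bracketed rules are unaffected by this choice. AND/OR
nodes are n-ary and associatively flattened at construction
(`AND(a, AND(b, c))` is stored as `AND(a, b, c)`), which gives the
round-trip guarantee parse∘serialize = identity on all trees, not just
parser-produced ones. The COBRA notes dialect (lowercase `and`/`or`,
parentheses) is parsed by the same grammar and emitted by
`gpr_to_cobra`.

### MIRIAM references

External references are single strings in the URN dialect
`urn:miriam:<datatype>:<identifier>` (identifiers.org URIs are accepted
on input). Resolution to web addresses goes through a flat
`datatype → URL-template` registry file bundled with the package; users
point `load_registry` at their own file to add databases. Unknown
datatypes resolve to an `unresolved` marker, never to a malformed URL.

## Balance checking

For each element *e*, net(*e*) = Σ products (stoichiometry × count) − Σ
substrates (stoichiometry × count). A reaction is balanced iff every
|net| ≤ **1e-9**; the tolerance exists because biomass and lumped
reactions carry decimal stoichiometries and exact integer arithmetic
cannot be assumed. Elements with negative net are "missing on the
product side", positive net is overproduction. If any participant lacks
a formula the status is `undetermined` and those metabolites are listed
— absence of evidence is not imbalance. Exchange/boundary reactions
(reactants on one side only) report `unbalanced`, never an error: they
are unbalanced by design.

Charge participates as a pseudo-element (`charge`) only when **every**
participant carries a charge value; a single uncharged participant
disables the charge term rather than producing a spurious imbalance.
Non-IUPAC element symbols (`R`, `X`, `Z`) are accepted as opaque tokens
by default, since lumped species in published reconstructions use them;
`strict=True` restricts symbols to the periodic table. Formula output
uses Hill order (C, H, then alphabetical).

## Version store

The store is an embedded, append-only change log serialized to a single
JSON file with a versioned header — the versioning semantics are the
contract, not the persistence technology. Every modification is first a
`PendingChange` (create/update/delete with per-field old→new deltas) and
only becomes visible when an administrator approves a batch; each
approval creates one `Revision` with number = previous max + 1, shared
by all entities, so `model_at_revision` can rebuild any model at any
point by replaying approved changes in revision order. Updates to an
entity deleted earlier in the same batch are no-ops on replay.

Design choices worth recording:

* Approval takes an arbitrary set of pending changes into one revision
  (per-change and per-batch approval are both expressible).
* The user-defined version label auto-increments `1`, `2`, … per model
  when the approver supplies none; supplied labels are free text.
* Rejected changes are retained and flagged for audit, but never apply
  and never appear in history diffs.
* Timestamps come from an injectable clock, so histories are
  reproducible in tests.
* Discussion threads are plain comment records attachable to any entity
  (create/list); file attachments live outside version control.
* Permission checks reproduce the four user classes exactly: browse and
  export decisions coincide (whoever may browse a state may export it);
  edit and import require an editor assigned to the model or an
  administrator; approval is administrator-only. Pending states are
  visible only to assigned editors and administrators.

Authentication, password management and concurrent multi-process access
are out of scope; users are declarative records.

## Comparison

Entity identity follows curated-identifier precedence. Reactions: KEGG
ID when both sides carry one — and when both are present but differ, the
reactions do **not** match, with no equation fallback (the curated ID is
authoritative); otherwise the canonical equation decides. The canonical
equation sorts each side's (metabolite key, compartment path,
stoichiometry) terms; reversible reactions are oriented so the
lexicographically smaller side comes first, making `A ⇌ B` equal
`B ⇌ A`, while irreversible direction is preserved. No stoichiometric
rescaling is attempted (`2A → 2B` ≠ `A → B`), and no tolerance for
proton/water differences is applied. Metabolite keys are ChEBI, else
KEGG, else lower-cased name — so identical names with different ChEBI
IDs are distinct species. Metabolites are compared at species level,
ignoring compartments, for the metabolite Venn; compartments enter only
through the optional restriction step, which filters reactions first and
then restricts metabolites and genes to participants of the survivors.

Many-to-many ambiguity is resolved by greedy one-to-one matching in
sorted-abbreviation order — deterministic, and equal to an optimal
assignment on curated models where duplicates are rare. The test suite
validates greedy against a maximum-bipartite-matching oracle on
generated pairs, which are constructed without matching ambiguity.

## SBML exchange

Documents are emitted as **Level 2 Version 4**, the dialect with the
broadest support among constraint-based analysis tools; Level 2 (any
version) and Level 3 core are accepted on import. Entities are emitted
in sorted-abbreviation order and species references always carry an
explicit stoichiometry attribute (including the value 1), which makes
repeated exports byte-identical and diff-able, and output robust against
parsers that mishandle defaults. Compartment parentage uses the Level 2
`outside` attribute. One SBML species is written per (metabolite,
compartment) pair in use; metabolites used by no reaction are attached
to the model's first compartment so no information is lost.

Fields SBML core cannot express travel in structured notes lines
(`FORMULA`, `CHARGE`, `GENE_ASSOCIATION`, `SUBSYSTEM`, `ABBREVIATION`,
gene records and organism at model level); external references travel as
MIRIAM RDF annotations. The COBRA profile omits the package-specific
notes and adds flux bounds derived from reversibility — reversible
(−1000, 1000), irreversible (0, 1000), objective coefficient 0 — encoded
both as kinetic-law parameters and as notes lines, so either convention
loads; the stored model itself carries no bounds, so conventional
defaults are required for the export to be usable. SBML packages (fbc,
groups) are out of scope.

### Compartmentalization modes

* **complete** — identity.
* **partial** — every reactant in a compartment within the cytoplasm is
  reassigned to the cytoplasm; emptied sub-compartments are removed;
  everything else (e.g. extracellular space) is untouched, so the
  reaction count is preserved. The cytoplasm is auto-detected by
  compartment name or id in {cytoplasm, cytosol} (case-insensitive); an
  explicit id overrides.
* **full** — all reactants move to a single compartment. SBML requires
  every species to live in some compartment, so "no compartments" is
  realized as one unsegregated compartment (`cell`). Reactants then
  identical on both sides with equal total stoichiometry cancel;
  reactions that cancel away entirely (pure transport) are dropped and
  reported rather than left as degenerate `A → A` artifacts. Cancellation
  removes equal contributions from both sides, so the elemental net of
  every surviving reaction is unchanged, and the operation is idempotent.

Tabular export is delimited text (TSV by default) with a fixed column
set; spreadsheet/PDF rendering is out of scope.

## Quick search

Case-insensitive substring match, no ranking, over exactly the
documented per-kind fields; reactions additionally honour the caller's
model selection. The `enzyme` and `ORF` fields are stored free-text
attributes on reactions (the generator populates them from the GPR's
first gene), since they are searchable but not structural. Results are
deterministic: models, entities and fields are scanned in sorted order.

## Synthetic-model generator

The generator is first-class, tested code and defines the conditions
under which the package's guarantees are demonstrated. Defaults describe
a small but structurally complete microbial model: a compartment tree
extracellular > cytoplasm > organelles (4 compartments), 40 metabolites,
60 reactions (10% transports), 30 genes, and external-identifier
coverage of 60–70% — proportions typical of well-annotated published
reconstructions. Chemistry is made balanced **by construction**:
conversion reactions are condensations `k·a + k·b → k·ab` where the
conjugate's formula is the exact elemental sum of its parts, and
transports move one metabolite between compartments; both conserve every
element trivially. `perturb_reaction_formula` adds one atom to a
participating metabolite with nonzero net stoichiometry, guaranteeing a
detectable, named imbalance (pure transports have no such metabolite and
are rejected).

The pair generator controls comparison ground truth exactly: shared
metabolites and genes carry identical curated IDs (or names) on both
sides; shared reactions are split between KEGG-identified pairs and
equation-only pairs; every reaction gets a globally unique
stoichiometric multiplier so all equations are pairwise distinct, and
every unique reaction carries a globally unique KEGG ID — together this
removes all matching ambiguity, so greedy and optimal matching coincide
and the intended Venn counts are the only correct answer.

What generated models do **not** emulate: real biochemistry (formulas
are random element vectors, not known compounds), duplicate or
conflicting annotations, near-miss equations differing only by protons
or water, exchange reactions, and models large enough to stress
performance. Tests passing on fixtures therefore demonstrate the
correctness of the mechanics — parsing, replay, matching, serialization
— not the curation quality of any real reconstruction.

## Problem sizes

The verification suite and `scripts/acceptance.py` run the checks at
these sizes, chosen to exercise every code path many times over while
keeping a full run in the order of seconds: 1000 balanced reactions plus
1000 single-atom perturbations; 10,000 random formulas against a
character-scan oracle; two 200-step random edit histories with a
deep-copy snapshot oracle at every revision; the full 110-row permission
table; 100 generated model pairs checked against ground truth and a
maximum-matching oracle; 50 SBML round trips with libSBML validation;
15 models through both decompartmentalization modes; 500 random GPR
trees against exhaustive truth tables; 33 search queries against a full
scan.

## Known limitations

* Formula grammar: no isotopes, no hydration dot notation (`·H2O`), no
  inference from SMILES/InChI (those annotations are stored, not parsed).
* Comparison tolerates no proton/water slack; models annotated at
  different protonation states will under-match.
* The store replays the full change log per snapshot query — simple and
  correct, linear in history length; fine for curation-scale histories,
  not tuned for millions of changes.
* SBML import maps Level 3 documents onto the Level 2 feature set
  (compartment hierarchy from `outside` has no Level 3 counterpart).
* UniProt sequence retrieval and rendering of metabolic maps or
  area-accurate Venn diagrams are out of scope; comparison output is
  counts and lists.
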