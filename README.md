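# gemstore

A versioned workbench for **genome-scale metabolic models** (GEMs): a
library and command-line tool for curation teams who develop, review and
exchange metabolic reconstructions.

Reconstruction is an iterative, collaborative process: editors propose
changes to reactions, metabolites, compartments and genes; a supervising
administrator reviews and approves them; every approval becomes a numbered
revision from which the complete model can be reconstructed later.
`gemstore` implements that workflow together with the quality-control and
exchange machinery around it:

* **Data model** — reactions built from reactants (metabolite,
  stoichiometric coefficient, compartment, side), reversibility,
  subsystems, citations, gene–protein–reaction (GPR) Boolean rules such as
  `gene1 AND [gene2 OR gene3]`, compartments arranged in a parent
  hierarchy, and external references in MIRIAM notation
  (`urn:miriam:ec-code:1.1.1.1`) resolved to web addresses through a
  user-extensible registry.
* **Balance check** — for a reaction with stoichiometric coefficients
  s<sub>i</sub> (negative for substrates, positive for products) and
  metabolite formulas with element counts f<sub>i,e</sub>, the net for
  element *e* is Σ<sub>i</sub> s<sub>i</sub>·f<sub>i,e</sub>; the reaction
  is balanced iff every net is zero (|net| ≤ 1e-9). Missing and
  overproduced elements are reported by name, net charge as a
  pseudo-element.
* **Version control** — pending changes, atomic approval into globally
  numbered revisions, per-entity history with field diffs, snapshot
  reconstruction at any revision, and the four user classes (unregistered,
  registered, editor, administrator) with their browse/edit/export/
  import/approve permissions.
* **Comparison** — identifier-based matching between any two snapshots:
  reactions by KEGG ID when both carry one, otherwise by canonical
  chemical equation (reversibility, metabolites, stoichiometry);
  metabolites by ChEBI > KEGG > name; genes by UniProt > name. Output is
  shared/unique lists plus the Venn counts (unique A, shared, unique B)
  per category, optionally restricted to compartments or subsystems.
* **SBML exchange** — import of Level 2 / Level 3 core documents; export
  as Level 2 Version 4 in a complete profile or a COBRA-toolbox profile
  (GPRs, subsystems, formulas in notes; flux bounds from reversibility),
  with three compartmentalization modes: complete, partially
  decompartmentalized (organelles merged into the cytoplasm) and fully
  decompartmentalized (one unsegregated system, cancelled transport
  reactions dropped and reported). Every species reference carries an
  explicit stoichiometry and all output passes libSBML validation.
* **Quick search** across reactions, metabolites, genes and organisms, and
  a **synthetic-model generator** that builds valid, elementally balanced
  fixture models and model pairs with exactly known overlap.

## Worked example

```python
from gemstore import *
from gemstore.workbench import FixtureParams

store = Store()
admin  = store.add_user(User("ada", "administrator"))
editor = store.add_user(User("ed", "editor", {"yeast_draft"}))

model = generate_model(FixtureParams(n_metabolites=12, n_reactions=8,
                                     n_genes=5, seed=4), "yeast_draft")
import_model(store, model, editor, admin=admin)
head = model_at_revision(store, "yeast_draft")
print("revision:", store.current_revision(), "version label:", head.version_label)
print("r003:", head.reaction("r003").equation_text())
print("balance:", balance_report(head.reaction("r003"), head).status)
```

prints

```
revision: 1 version label: 1
r003: m006[c] + m001[c] -> x002[c]
balance: balanced
```

Introduce a curation typo (drop one sulfur atom from the product's
formula) and the balance check pinpoints it:

```
after typo: unbalanced {'S': -1.0} missing: ['S']
```

An editor's change stays pending — invisible in every accepted view —
until an administrator approves it, which creates revision 2:

```python
ch = propose_change(store, draft_change(store, "yeast_draft", "reaction",
                    "r003", "update", {"name": "ligase reaction"}), editor)
rev = approve_changes(store, [ch.change_id], admin)
```

```
pending: c31 | head still: synthesis of x002
approved as revision 2 -> ligase reaction
```

Comparing two generated models with a known overlap of 10 shared / 5
unique-A / 7 unique-B reactions recovers exactly those Venn counts:

```python
a, b, truth = generate_model_pair({"reactions": (10, 5, 7),
                                   "metabolites": (12, 3, 4),
                                   "genes": (8, 2, 3)}, seed=5)
print(venn_summary(compare_models(a, b)))
```

```
{'reactions': (5, 10, 7), 'metabolites': (3, 12, 4), 'genes': (2, 8, 3)}
```

where each triple reads (unique to A, shared, unique to B). Finally, a
COBRA-profile export with organelles merged into the cytoplasm:

```python
text, report = export_sbml(model, ExportOptions(profile="cobra",
                                                mode="partial_decomp"))
```

```
export: {'compartments': 2, 'species': 18, 'metabolites': 12,
         'reactions': 8, 'genes': 5}  libSBML errors: 0
```

The same operations are available from the shell (`gemstore import`,
`export`, `compare`, `search`, `history`, `balance`, `propose`, `approve`,
`generate`); see `gemstore --help`.

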