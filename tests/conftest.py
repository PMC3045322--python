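"""Shared fixtures: small hand-built models and a deterministic store."""

import itertools

import pytest

from gemstore import (
    Compartment, FixtureParams, Gene, Metabolite, Model, Reactant, Reaction,
    SUBSTRATE, PRODUCT, Store, User, generate_model, import_model, parse_gpr,
)


def make_clock():
    counter = itertools.count(1)
    return lambda: float(next(counter))


@pytest.fixture
def clock():
    return make_clock()


@pytest.fixture
def water_model():
    """2 H2 + O2 -> 2 H2O in a two-compartment cell."""
    model = Model("toy", name="toy model", organism="Toyococcus")
    model.add(Compartment("e", "extracellular"))
    model.add(Compartment("c", "cytoplasm", parent_id="e"))
    model.add(Metabolite("h2", "hydrogen", "H2", charge=0))
    model.add(Metabolite("o2", "oxygen", "O2", charge=0))
    model.add(Metabolite("h2o", "water", "H2O", charge=0))
    model.add(Reaction(
        "rw", "water synthesis",
        reactants=[
            Reactant("h2", 2.0, "c", SUBSTRATE),
            Reactant("o2", 1.0, "c", SUBSTRATE),
            Reactant("h2o", 2.0, "c", PRODUCT),
        ],
        ec_number="1.1.1.1",
    ))
    return model


@pytest.fixture
def organelle_model():
    """Compartment tree e > c > {peroxisome, nucleus} with cross-compartment
    reactions, for hierarchy and decompartmentalization behaviour."""
    model = Model("org", name="organelle model", organism="Toyococcus")
    model.add(Compartment("e", "extracellular"))
    model.add(Compartment("c", "cytoplasm", parent_id="e"))
    model.add(Compartment("p", "peroxisome", parent_id="c"))
    model.add(Compartment("n", "nucleus", parent_id="c"))
    model.add(Metabolite("a", "compound a", "C3H6O3"))
    model.add(Metabolite("b", "compound b", "C2H4O2"))
    model.add(Metabolite("ab", "compound ab", "C5H10O5"))
    model.add(Reaction("r_perox", "peroxisomal synthesis", reactants=[
        Reactant("a", 1.0, "p", SUBSTRATE),
        Reactant("b", 1.0, "p", SUBSTRATE),
        Reactant("ab", 1.0, "p", PRODUCT),
    ]))
    model.add(Reaction("r_transport", "a export", reversible=True, reactants=[
        Reactant("a", 1.0, "c", SUBSTRATE),
        Reactant("a", 1.0, "e", PRODUCT),
    ]))
    model.add(Reaction("r_nuc_cyt", "nucleus to cytoplasm", reactants=[
        Reactant("b", 2.0, "n", SUBSTRATE),
        Reactant("b", 2.0, "c", PRODUCT),
    ]))
    return model


@pytest.fixture
def fixture_model():
    return generate_model(FixtureParams(seed=11), model_id="fix")


@pytest.fixture
def populated_store(clock):
    """Store with one approved model, an admin, an editor and a registered user."""
    store = Store(clock=clock)
    admin = store.add_user(User("alice", "administrator"))
    editor = store.add_user(User("bob", "editor", {"M1"}))
    store.add_user(User("carol", "registered", {"M1"}))
    model = generate_model(
        FixtureParams(n_compartments=3, n_metabolites=9, n_reactions=6,
                      n_genes=4, seed=3),
        model_id="M1",
    )
    import_model(store, model, editor, admin=admin)
    store.set_public("M1", True, admin)
    return store
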