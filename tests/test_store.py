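"""Version store: permissions, pending-change workflow, snapshots, history."""

import copy
import itertools
import random

import pytest

from gemstore import (
    FixtureParams, Model, Store, Target, User, generate_model,
    approve_changes, check_permission, draft_change, entity_history,
    import_model, model_at_revision, propose_change, reject_changes,
)
from gemstore.store import (
    NotFound, PermissionDenied, StateError, entity_to_fields,
)


# ---------------------------------------------------------------------------
# Permission matrix
# ---------------------------------------------------------------------------

def expected_permission(role, action, ownership, view):
    """Hand-coded copy of the four-user-class access table."""
    if action in ("browse", "export"):
        if role == "administrator":
            return True
        if role == "editor" and ownership == "assigned":
            return True  # all versions of assigned models
        if view != "accepted":
            return False
        if ownership == "public":
            return True
        return role == "registered" and ownership == "assigned"
    if action in ("edit", "import"):
        return role == "administrator" or (
            role == "editor" and ownership == "assigned")
    if action == "approve":
        return role == "administrator"
    raise AssertionError(action)


def test_permission_matrix_exhaustive():
    """Every combination of role x action x model state matches the table."""
    roles = ("unregistered", "registered", "editor", "administrator")
    actions = ("browse", "edit", "export", "import", "approve")
    checked = 0
    for role, action, ownership, view in itertools.product(
            roles, actions, ("public", "assigned", "other"),
            ("accepted", "pending")):
        if role == "unregistered" and ownership == "assigned":
            continue  # unregistered users cannot have assigned models
        assigned = {"M"} if ownership == "assigned" else set()
        user = User("u", role, assigned)
        target = Target("M", is_public=(ownership == "public"), view=view)
        decision = check_permission(user, action, target)
        assert decision.allowed == expected_permission(role, action, ownership, view), \
            (role, action, ownership, view)
        assert decision.reason
        checked += 1
    assert checked == (4 * 3 - 1) * 5 * 2


def test_unregistered_with_assignment_rejected():
    with pytest.raises(ValueError):
        User("ghost", "unregistered", {"M"})


# ---------------------------------------------------------------------------
# Change workflow
# ---------------------------------------------------------------------------

class TestWorkflow:
    def test_pending_change_invisible_until_approved(self, populated_store):
        store = populated_store
        editor, admin = store.users["bob"], store.users["alice"]
        old_name = model_at_revision(store, "M1").reactions["r000"].name
        change = propose_change(
            store,
            draft_change(store, "M1", "reaction", "r000", "update",
                         {"name": "renamed"}, comment="tidy up"),
            editor)
        assert change.state == "pending"
        assert model_at_revision(store, "M1").reactions["r000"].name == old_name

        revision = approve_changes(store, [change.change_id], admin)
        assert revision.revision_number == store.current_revision()
        assert model_at_revision(store, "M1").reactions["r000"].name == "renamed"

    def test_registered_user_cannot_edit(self, populated_store):
        store = populated_store
        draft = draft_change(store, "M1", "reaction", "r000", "update",
                             {"name": "x"})
        with pytest.raises(PermissionDenied):
            propose_change(store, draft, store.users["carol"])

    def test_editor_cannot_edit_unassigned_model(self, populated_store, clock):
        store = populated_store
        outsider = store.add_user(User("dave", "editor", {"OTHER"}))
        draft = draft_change(store, "M1", "reaction", "r000", "update",
                             {"name": "x"})
        with pytest.raises(PermissionDenied):
            propose_change(store, draft, outsider)

    def test_editor_cannot_approve(self, populated_store):
        store = populated_store
        change = propose_change(
            store, draft_change(store, "M1", "reaction", "r000", "update",
                                {"name": "x"}), store.users["bob"])
        with pytest.raises(PermissionDenied):
            approve_changes(store, [change.change_id], store.users["bob"])

    def test_approve_empty_set_is_argument_error(self, populated_store):
        with pytest.raises(ValueError):
            approve_changes(populated_store, [], populated_store.users["alice"])

    def test_double_approval_is_state_error(self, populated_store):
        store = populated_store
        change = propose_change(
            store, draft_change(store, "M1", "reaction", "r000", "update",
                                {"name": "x"}), store.users["bob"])
        approve_changes(store, [change.change_id], store.users["alice"])
        with pytest.raises(StateError):
            approve_changes(store, [change.change_id], store.users["alice"])

    def test_two_changes_one_revision(self, populated_store):
        store = populated_store
        editor, admin = store.users["bob"], store.users["alice"]
        before = store.current_revision()
        c1 = propose_change(store, draft_change(
            store, "M1", "reaction", "r000", "update", {"name": "first"}), editor)
        c2 = propose_change(store, draft_change(
            store, "M1", "metabolite", "m000", "update", {"charge": 2}), editor)
        revision = approve_changes(store, [c1.change_id, c2.change_id], admin)
        assert revision.revision_number == before + 1
        head = model_at_revision(store, "M1")
        assert head.reactions["r000"].name == "first"
        assert head.metabolites["m000"].charge == 2

    def test_unknown_field_rejected(self, populated_store):
        with pytest.raises(ValueError):
            draft_change(populated_store, "M1", "reaction", "r000", "update",
                         {"color": "red"})

    def test_invalid_value_rejected(self, populated_store):
        draft = draft_change(
            populated_store, "M1", "reaction", "r000", "update",
            {"reactants": [{"metabolite": "m000", "stoichiometry": -1.0,
                            "compartment": "c", "side": "substrate"}]})
        with pytest.raises(ValueError):
            propose_change(populated_store, draft, populated_store.users["bob"])

    def test_rejected_changes_never_apply_and_leave_no_history(self, populated_store):
        store = populated_store
        change = propose_change(
            store, draft_change(store, "M1", "reaction", "r000", "update",
                                {"name": "vandalism"}), store.users["bob"])
        reject_changes(store, [change.change_id], store.users["alice"])
        assert store.changes[change.change_id].state == "rejected"
        assert model_at_revision(store, "M1").reactions["r000"].name != "vandalism"
        history = entity_history(store, "M1/reaction/r000")
        assert all(e.change_kind == "create" or "vandalism" not in str(e.diffs)
                   for e in history)
        with pytest.raises(StateError):
            approve_changes(store, [change.change_id], store.users["alice"])

    def test_version_label_auto_increments(self, populated_store):
        store = populated_store
        editor, admin = store.users["bob"], store.users["alice"]
        assert model_at_revision(store, "M1").version_label == "1"
        change = propose_change(store, draft_change(
            store, "M1", "reaction", "r000", "update", {"name": "x"}), editor)
        approve_changes(store, [change.change_id], admin)
        assert model_at_revision(store, "M1").version_label == "2"
        change = propose_change(store, draft_change(
            store, "M1", "reaction", "r000", "update", {"name": "y"}), editor)
        approve_changes(store, [change.change_id], admin, version_label="1.0-final")
        assert model_at_revision(store, "M1").version_label == "1.0-final"

    def test_revision_numbers_have_no_gaps(self, populated_store):
        store = populated_store
        numbers = [r.revision_number for r in store.revisions]
        editor, admin = store.users["bob"], store.users["alice"]
        for i in range(3):
            change = propose_change(store, draft_change(
                store, "M1", "metabolite", "m000", "update",
                {"charge": i}), editor)
            approve_changes(store, [change.change_id], admin)
        numbers = [r.revision_number for r in store.revisions]
        assert numbers == list(range(1, len(numbers) + 1))


# ---------------------------------------------------------------------------
# Snapshots and history
# ---------------------------------------------------------------------------

def model_fields(model: Model) -> dict:
    """Canonical field view of a model for snapshot equality checks."""
    out = {}
    kind, local_id, fields = entity_to_fields(model)
    out[(kind, local_id)] = fields
    for collection in (model.compartments.values(), model.metabolites.values(),
                       model.genes.values(), model.reactions.values()):
        for entity in collection:
            kind, local_id, fields = entity_to_fields(entity)
            out[(kind, local_id)] = fields
    return out


def run_random_history(steps: int, seed: int, clock):
    """Drive random edits against a store while maintaining a deep-copy
    oracle of the expected field state after every revision."""
    rng = random.Random(seed)
    store = Store(clock=clock)
    admin = store.add_user(User("root", "administrator"))
    editor = store.add_user(User("ed", "editor", {"M"}))
    base = generate_model(FixtureParams(
        n_compartments=2, n_metabolites=6, n_reactions=4, n_genes=3, seed=seed), "M")
    import_model(store, base, editor, admin=admin)

    expected = model_fields(model_at_revision(store, "M"))
    snapshots = {1: copy.deepcopy(expected)}
    pending = []  # (change, oracle_action)

    def random_update():
        kind = rng.choice(["metabolite", "reaction", "gene", "model"])
        candidates = [lid for (k, lid), f in expected.items()
                      if k == kind and f is not None]
        if not candidates:
            return None
        local_id = rng.choice(candidates)
        field_name, value = {
            "metabolite": ("charge", rng.randint(-3, 3)),
            "reaction": ("name", f"renamed {rng.randrange(1000)}"),
            "gene": ("name", f"gene variant {rng.randrange(1000)}"),
            "model": ("notes", f"note {rng.randrange(1000)}"),
        }[kind]
        return kind, local_id, field_name, value

    for step in range(steps):
        op = rng.random()
        if op < 0.25:
            local_id = f"extra{step}"
            fields = {"name": f"extra metabolite {step}", "formula": "C2H6O",
                      "charge": 0, "chebi_id": None, "kegg_id": None,
                      "annotations": []}
            change = propose_change(store, draft_change(
                store, "M", "metabolite", local_id, "create", fields), editor)
            pending.append((change, ("set", ("metabolite", local_id),
                                     dict(fields))))
        elif op < 0.75:
            pick = random_update()
            if pick is None:
                continue
            kind, local_id, field_name, value = pick
            change = propose_change(store, draft_change(
                store, "M", kind, local_id, "update", {field_name: value}), editor)
            pending.append((change, ("update", (kind, local_id),
                                     {field_name: value})))
        elif op < 0.85:
            candidates = [lid for (k, lid), f in expected.items()
                          if k == "metabolite" and f is not None
                          and lid.startswith("extra")]
            if not candidates:
                continue
            local_id = rng.choice(candidates)
            change = propose_change(store, draft_change(
                store, "M", "metabolite", local_id, "delete"), editor)
            pending.append((change, ("delete", ("metabolite", local_id), None)))
        elif pending:
            take = rng.randint(1, len(pending))
            batch, pending = pending[:take], pending[take:]
            approve_changes(store, [c.change_id for c, _ in batch], admin)
            _apply_to_oracle(expected, batch)
            snapshots[store.current_revision()] = copy.deepcopy(expected)
    if pending:
        approve_changes(store, [c.change_id for c, _ in pending], admin)
        _apply_to_oracle(expected, pending)
        snapshots[store.current_revision()] = copy.deepcopy(expected)
    return store, snapshots


def _apply_to_oracle(expected, batch):
    for _, (action, key, payload) in batch:
        if action == "set":
            expected[key] = dict(payload)
        elif action == "update":
            # an update approved after a delete in the same batch is a
            # no-op, matching the store's replay semantics
            if expected[key] is not None:
                expected[key].update(payload)
        else:
            expected[key] = None


def assert_history_matches_oracle(store, snapshots):
    for revision, expected in snapshots.items():
        got = model_fields(model_at_revision(store, "M", revision))
        want = {k: f for k, f in expected.items() if f is not None}
        # labels are revision metadata, not entity fields
        assert got == want, f"snapshot mismatch at revision {revision}"


class TestSnapshotOracle:
    def test_random_history_matches_deep_copy_oracle(self, clock):
        store, snapshots = run_random_history(steps=60, seed=17, clock=clock)
        assert_history_matches_oracle(store, snapshots)

    def test_no_retroactive_leakage(self, clock):
        store, snapshots = run_random_history(steps=40, seed=23, clock=clock)
        revisions = sorted(snapshots)
        for earlier, later in zip(revisions, revisions[1:]):
            earlier_fields = model_fields(model_at_revision(store, "M", earlier))
            later_only = {k for k, f in snapshots[later].items()
                          if f is not None and snapshots[earlier].get(k) is None}
            assert not later_only & set(earlier_fields)

    def test_head_query_equals_latest(self, populated_store):
        head = model_fields(model_at_revision(populated_store, "M1"))
        explicit = model_fields(model_at_revision(
            populated_store, "M1", populated_store.current_revision()))
        assert head == explicit

    def test_future_revision_not_found(self, populated_store):
        with pytest.raises(NotFound):
            model_at_revision(populated_store, "M1",
                              populated_store.current_revision() + 1)

    def test_model_absent_before_creation(self, populated_store):
        with pytest.raises(NotFound):
            model_at_revision(populated_store, "M1", 0)


class TestHistory:
    def test_create_plus_edit_history(self, populated_store):
        store = populated_store
        change = propose_change(store, draft_change(
            store, "M1", "reaction", "r000", "update", {"name": "better name"}),
            store.users["bob"])
        approve_changes(store, [change.change_id], store.users["alice"])
        history = entity_history(store, "M1/reaction/r000")
        assert history[0].change_kind == "create"
        assert [sorted(e.diffs) for e in history[1:]] == [["name"]]
        assert history[-1].author == "bob"

    def test_untouched_entity_has_creation_only(self, populated_store):
        history = entity_history(populated_store, "M1/gene/g000")
        assert len(history) == 1
        assert history[0].change_kind == "create"

    def test_replay_reproduces_head(self, clock):
        store, _ = run_random_history(steps=50, seed=31, clock=clock)
        head = model_fields(model_at_revision(store, "M"))
        for key in head:
            kind, local_id = key
            state = None
            for entry in entity_history(store, f"M/{kind}/{local_id}"):
                if entry.change_kind == "create":
                    state = {f: new for f, (_, new) in entry.diffs.items()}
                elif entry.change_kind == "update":
                    for f, (_, new) in entry.diffs.items():
                        state[f] = new
                else:
                    state = None
            assert state == head[key]

    def test_unknown_entity_not_found(self, populated_store):
        with pytest.raises(NotFound):
            entity_history(populated_store, "M1/reaction/nonexistent")


class TestPersistence:
    def test_save_load_round_trip(self, populated_store, tmp_path, clock):
        path = tmp_path / "store.json"
        populated_store.save(str(path))
        reloaded = Store.load(str(path), clock=clock)
        assert model_fields(model_at_revision(reloaded, "M1")) == \
            model_fields(model_at_revision(populated_store, "M1"))
        assert reloaded.public_models == populated_store.public_models
        assert [r.revision_number for r in reloaded.revisions] == \
            [r.revision_number for r in populated_store.revisions]

    def test_comments_attach_to_entities(self, populated_store):
        store = populated_store
        store.add_comment("M1/reaction/r000", store.users["carol"],
                          "is this stoichiometry right?")
        store.add_comment("M1/reaction/r000", store.users["bob"],
                          "yes, checked against the primary literature")
        thread = store.list_comments("M1/reaction/r000")
        assert [c.author for c in thread] == ["carol", "bob"]
        assert store.list_comments("M1/reaction/r001") == []
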