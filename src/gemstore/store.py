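"""Append-only, revision-numbered store with pending-change approval.

Model development is iterative: every modification of an entity is first
recorded as a *pending change* and only becomes visible once an
administrator approves it.  Each approval batch creates a new globally
numbered :class:`Revision`; a single revision counter covers all entities,
so the complete state of any model can be reconstructed at any revision.
Four user classes control access: unregistered visitors browse accepted
versions of public models; registered users additionally browse accepted
versions of assigned models; editors see all versions of assigned models
and may edit and import them; administrators do everything, including
approval.

The store is an embedded single-file structure (a serialized append-only
change log, JSON on disk) rather than a client-server database: the
versioning semantics, not the persistence technology, are the contract.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from . import core
from .core import Model, Compartment, Metabolite, Reaction, Reactant, Gene, MiriamRef

__all__ = [
    "User",
    "PendingChange",
    "Revision",
    "HistoryEntry",
    "Comment",
    "Target",
    "Decision",
    "Store",
    "StoreError",
    "PermissionDenied",
    "NotFound",
    "StateError",
    "ROLES",
    "ACTIONS",
    "check_permission",
    "propose_change",
    "approve_changes",
    "reject_changes",
    "model_at_revision",
    "entity_history",
    "entity_key",
    "draft_change",
    "import_model",
    "model_to_changes",
    "entity_to_fields",
    "fields_to_entity",
]

ROLES = ("unregistered", "registered", "editor", "administrator")
ACTIONS = ("browse", "edit", "export", "import", "approve")
ENTITY_KINDS = ("model", "compartment", "metabolite", "reaction", "gene")

#: Editable fields per entity kind; the local id is fixed at creation.
FIELD_SCHEMAS: Dict[str, Tuple[str, ...]] = {
    "model": ("name", "organism", "notes", "subsystems", "annotations"),
    "compartment": ("name", "parent_id", "annotations"),
    "metabolite": ("name", "formula", "charge", "chebi_id", "kegg_id", "annotations"),
    "reaction": (
        "name", "reactants", "reversible", "ec_number", "kegg_id", "subsystem",
        "gpr", "enzyme", "orf", "citations", "annotations", "is_exchange",
    ),
    "gene": ("name", "ec_number", "kegg_id", "uniprot_id", "annotations"),
}


class StoreError(Exception):
    pass


class PermissionDenied(StoreError):
    pass


class NotFound(StoreError):
    pass


class StateError(StoreError):
    pass


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class User:
    username: str
    role: str = "registered"
    assigned_models: Set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "unregistered" and self.assigned_models:
            raise ValueError("unregistered users cannot have assigned models")


@dataclass
class PendingChange:
    change_id: str
    model_id: str
    entity_kind: str
    entity_id: str  # local id (abbreviation / compartment id / model id)
    change_kind: str  # "create" | "update" | "delete"
    deltas: Dict[str, Tuple[object, object]]  # field -> (old, new)
    author: str
    timestamp: float
    comment: str = ""
    state: str = "pending"  # "pending" | "approved" | "rejected"


@dataclass
class Revision:
    revision_number: int
    approved_changes: List[str]
    approver: str
    timestamp: float
    #: user-defined version label assigned to each affected model
    version_labels: Dict[str, str] = field(default_factory=dict)


@dataclass
class HistoryEntry:
    revision: int
    author: str
    timestamp: float
    comment: str
    change_kind: str
    diffs: Dict[str, Tuple[object, object]]


@dataclass
class Comment:
    entity: str  # "<model_id>/<kind>/<local_id>" or "" for a global thread
    author: str
    timestamp: float
    text: str


@dataclass(frozen=True)
class Target:
    """Permission-check target: which model, its visibility, which view."""

    model_id: str
    is_public: bool
    view: str = "accepted"  # "accepted" | "pending"


@dataclass(frozen=True)
class Decision:
    allowed: bool
    reason: str

    def __bool__(self) -> bool:
        return self.allowed


def entity_key(model_id: str, kind: str, local_id: str) -> str:
    return f"{model_id}/{kind}/{local_id}"


def split_entity_key(key: str) -> Tuple[str, str, str]:
    parts = key.split("/", 2)
    if len(parts) != 3 or parts[1] not in ENTITY_KINDS:
        raise ValueError(f"malformed entity key {key!r}")
    return parts[0], parts[1], parts[2]


# ---------------------------------------------------------------------------
# Permissions (the user-class decision table)
# ---------------------------------------------------------------------------


def check_permission(user: User, action: str, target: Target) -> Decision:
    """Decide an action against the four-class access table.

    Browse: unregistered and registered users see only accepted versions
    (registered also of assigned models); editors see every version of
    assigned models; administrators see everything.  Edit and import are
    editor-and-up on assigned models; approval is administrator-only.
    Export follows browse: whoever may browse a model state may export it.
    """
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    role = user.role
    assigned = target.model_id in user.assigned_models

    if action in ("browse", "export"):
        if role == "administrator":
            return Decision(True, "administrators browse all models")
        if role == "editor" and assigned:
            return Decision(True, "editors browse all versions of assigned models")
        if target.view != "accepted":
            return Decision(False, "only accepted versions are visible to this class")
        if target.is_public:
            return Decision(True, "accepted versions of public models are visible")
        if role == "registered" and assigned:
            return Decision(True, "registered users browse accepted versions of assigned models")
        return Decision(False, "model is not publicly available")

    if action in ("edit", "import"):
        if role == "administrator":
            return Decision(True, "administrators edit all models")
        if role == "editor" and assigned:
            return Decision(True, "editors edit assigned models")
        return Decision(False, f"{action} requires an editor assigned to the model")

    # approve
    if role == "administrator":
        return Decision(True, "administrators approve modifications")
    return Decision(False, "modification approval requires an administrator")


# ---------------------------------------------------------------------------
# Store
# ---------------------------------------------------------------------------

FORMAT_NAME = "gemstore-store"
FORMAT_VERSION = 1


class Store:
    """Embedded versioned store for models, users, changes and comments.

    ``clock`` is injectable so histories are reproducible in tests; it
    defaults to wall-clock time.
    """

    def __init__(self, clock: Optional[Callable[[], float]] = None):
        self.users: Dict[str, User] = {}
        self.changes: Dict[str, PendingChange] = {}
        self.change_order: List[str] = []
        self.revisions: List[Revision] = []
        self.public_models: Set[str] = set()
        self.comments: List[Comment] = []
        self.clock = clock or time.time
        self._change_counter = 0

    # -- users ---------------------------------------------------------------
    def add_user(self, user: User) -> User:
        self.users[user.username] = user
        return user

    def set_public(self, model_id: str, public: bool, admin: User) -> None:
        if admin.role != "administrator":
            raise PermissionDenied("changing public availability requires an administrator")
        if public:
            self.public_models.add(model_id)
        else:
            self.public_models.discard(model_id)

    def target(self, model_id: str, view: str = "accepted") -> Target:
        return Target(model_id, model_id in self.public_models, view)

    # -- revision bookkeeping --------------------------------------------------
    def current_revision(self) -> int:
        return len(self.revisions)

    def model_ids(self, revision: Optional[int] = None) -> List[str]:
        """Models existing (created, not deleted) at the given revision."""
        r = self.current_revision() if revision is None else revision
        alive: Dict[str, bool] = {}
        for rev in self.revisions[:r]:
            for cid in rev.approved_changes:
                ch = self.changes[cid]
                if ch.entity_kind == "model":
                    alive[ch.model_id] = ch.change_kind != "delete"
        return sorted(m for m, ok in alive.items() if ok)

    def pending_changes(self, model_id: Optional[str] = None) -> List[PendingChange]:
        return [
            self.changes[cid]
            for cid in self.change_order
            if self.changes[cid].state == "pending"
            and (model_id is None or self.changes[cid].model_id == model_id)
        ]

    # -- comments (discussion threads attachable to any entity) ---------------
    def add_comment(self, entity: str, author: User, text: str) -> Comment:
        comment = Comment(entity, author.username, self.clock(), text)
        self.comments.append(comment)
        return comment

    def list_comments(self, entity: Optional[str] = None) -> List[Comment]:
        return [c for c in self.comments if entity is None or c.entity == entity]

    # -- persistence -----------------------------------------------------------
    def save(self, path: str) -> None:
        def enc_change(ch: PendingChange) -> dict:
            d = asdict(ch)
            d["deltas"] = {k: list(v) for k, v in ch.deltas.items()}
            return d

        payload = {
            "format": FORMAT_NAME,
            "format_version": FORMAT_VERSION,
            "users": [
                {**asdict(u), "assigned_models": sorted(u.assigned_models)}
                for u in self.users.values()
            ],
            "change_order": self.change_order,
            "changes": {cid: enc_change(ch) for cid, ch in self.changes.items()},
            "revisions": [asdict(r) for r in self.revisions],
            "public_models": sorted(self.public_models),
            "comments": [asdict(c) for c in self.comments],
            "change_counter": self._change_counter,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str, clock: Optional[Callable[[], float]] = None) -> "Store":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != FORMAT_NAME:
            raise StoreError(f"{path!r} is not a {FORMAT_NAME} file")
        if payload.get("format_version", 0) > FORMAT_VERSION:
            raise StoreError("store file written by a newer format version")
        store = cls(clock=clock)
        for u in payload["users"]:
            store.add_user(User(u["username"], u["role"], set(u["assigned_models"])))
        store.change_order = list(payload["change_order"])
        for cid, d in payload["changes"].items():
            store.changes[cid] = PendingChange(
                change_id=d["change_id"], model_id=d["model_id"],
                entity_kind=d["entity_kind"], entity_id=d["entity_id"],
                change_kind=d["change_kind"],
                deltas={k: (v[0], v[1]) for k, v in d["deltas"].items()},
                author=d["author"], timestamp=d["timestamp"],
                comment=d["comment"], state=d["state"],
            )
        for r in payload["revisions"]:
            store.revisions.append(Revision(
                r["revision_number"], list(r["approved_changes"]),
                r["approver"], r["timestamp"], dict(r["version_labels"]),
            ))
        store.public_models = set(payload["public_models"])
        for c in payload["comments"]:
            store.comments.append(Comment(c["entity"], c["author"], c["timestamp"], c["text"]))
        store._change_counter = payload["change_counter"]
        return store


# ---------------------------------------------------------------------------
# Entity <-> field-dict codecs (JSON-able field values in the change log)
# ---------------------------------------------------------------------------


def _enc_annotations(annotations: List[MiriamRef]) -> List[str]:
    return [ref.to_urn() for ref in annotations]


def _dec_annotations(values: Sequence[str]) -> List[MiriamRef]:
    return [MiriamRef.from_string(v) for v in values]


def entity_to_fields(entity) -> Tuple[str, str, Dict[str, object]]:
    """Encode an entity into (kind, local_id, JSON-able field dict)."""
    if isinstance(entity, Model):
        return "model", entity.model_id, {
            "name": entity.name, "organism": entity.organism,
            "notes": entity.notes, "subsystems": list(entity.subsystems),
            "annotations": _enc_annotations(entity.annotations),
        }
    if isinstance(entity, Compartment):
        return "compartment", entity.compartment_id, {
            "name": entity.name, "parent_id": entity.parent_id,
            "annotations": _enc_annotations(entity.annotations),
        }
    if isinstance(entity, Metabolite):
        return "metabolite", entity.abbreviation, {
            "name": entity.name, "formula": entity.formula,
            "charge": entity.charge, "chebi_id": entity.chebi_id,
            "kegg_id": entity.kegg_id,
            "annotations": _enc_annotations(entity.annotations),
        }
    if isinstance(entity, Reaction):
        return "reaction", entity.abbreviation, {
            "name": entity.name,
            "reactants": [
                {"metabolite": r.metabolite_ref, "stoichiometry": r.stoichiometry,
                 "compartment": r.compartment_ref, "side": r.side}
                for r in entity.reactants
            ],
            "reversible": entity.reversible, "ec_number": entity.ec_number,
            "kegg_id": entity.kegg_id, "subsystem": entity.subsystem,
            "gpr": core.serialize_gpr(entity.gpr) if entity.gpr else None,
            "enzyme": entity.enzyme, "orf": entity.orf,
            "citations": list(entity.citations),
            "annotations": _enc_annotations(entity.annotations),
            "is_exchange": entity.is_exchange,
        }
    if isinstance(entity, Gene):
        return "gene", entity.abbreviation, {
            "name": entity.name, "ec_number": entity.ec_number,
            "kegg_id": entity.kegg_id, "uniprot_id": entity.uniprot_id,
            "annotations": _enc_annotations(entity.annotations),
        }
    raise TypeError(f"not a store entity: {type(entity).__name__}")


def fields_to_entity(kind: str, local_id: str, fields: Dict[str, object]):
    """Decode a field dict back into a typed entity."""
    ann = _dec_annotations(fields.get("annotations", []))
    if kind == "compartment":
        return Compartment(local_id, fields.get("name", ""),
                           fields.get("parent_id"), ann)
    if kind == "metabolite":
        return Metabolite(local_id, fields.get("name", ""), fields.get("formula"),
                          fields.get("charge"), fields.get("chebi_id"),
                          fields.get("kegg_id"), ann)
    if kind == "reaction":
        gpr_text = fields.get("gpr")
        return Reaction(
            abbreviation=local_id, name=fields.get("name", ""),
            reactants=[
                Reactant(r["metabolite"], r["stoichiometry"], r["compartment"], r["side"])
                for r in fields.get("reactants", [])
            ],
            reversible=fields.get("reversible", False),
            ec_number=fields.get("ec_number"), kegg_id=fields.get("kegg_id"),
            subsystem=fields.get("subsystem"),
            gpr=core.parse_gpr(gpr_text) if gpr_text else None,
            enzyme=fields.get("enzyme"), orf=fields.get("orf"),
            citations=list(fields.get("citations", [])), annotations=ann,
            is_exchange=fields.get("is_exchange", False),
        )
    if kind == "gene":
        return Gene(local_id, fields.get("name", ""), fields.get("ec_number"),
                    fields.get("kegg_id"), fields.get("uniprot_id"), ann)
    raise ValueError(f"unknown entity kind {kind!r}")


# ---------------------------------------------------------------------------
# Change workflow
# ---------------------------------------------------------------------------


def _head_fields(store: Store, model_id: str, kind: str, local_id: str,
                 revision: Optional[int] = None) -> Optional[Dict[str, object]]:
    """Entity field state at a revision (None if absent), replaying the log."""
    r = store.current_revision() if revision is None else revision
    state: Optional[Dict[str, object]] = None
    for rev in store.revisions[:r]:
        for cid in rev.approved_changes:
            ch = store.changes[cid]
            if (ch.model_id, ch.entity_kind, ch.entity_id) != (model_id, kind, local_id):
                continue
            if ch.change_kind == "create":
                state = {f: new for f, (_, new) in ch.deltas.items()}
            elif ch.change_kind == "update":
                assert state is not None
                for f, (_, new) in ch.deltas.items():
                    state[f] = new
            else:  # delete
                state = None
    return state


def draft_change(store: Store, model_id: str, entity_kind: str, entity_id: str,
                 change_kind: str, fields: Optional[Dict[str, object]] = None,
                 author: str = "", comment: str = "") -> PendingChange:
    """Build a change draft, deriving old values from the accepted head.

    ``fields`` holds the new values (full field set for a create, only the
    changed fields for an update, ignored for a delete).
    """
    if entity_kind not in ENTITY_KINDS:
        raise ValueError(f"unknown entity kind {entity_kind!r}")
    schema = FIELD_SCHEMAS[entity_kind]
    head = _head_fields(store, model_id, entity_kind, entity_id)

    if change_kind == "create":
        if head is not None:
            raise StateError(f"{entity_kind} {entity_id!r} already exists")
        fields = fields or {}
        unknown = set(fields) - set(schema)
        if unknown:
            raise ValueError(f"unknown fields {sorted(unknown)}")
        deltas = {f: (None, fields.get(f)) for f in schema}
    elif change_kind == "update":
        if head is None:
            raise NotFound(f"{entity_kind} {entity_id!r} does not exist")
        if not fields:
            raise ValueError("update requires at least one field")
        unknown = set(fields) - set(schema)
        if unknown:
            raise ValueError(f"unknown fields {sorted(unknown)}")
        deltas = {f: (head.get(f), v) for f, v in fields.items()}
    elif change_kind == "delete":
        if head is None:
            raise NotFound(f"{entity_kind} {entity_id!r} does not exist")
        deltas = {f: (head.get(f), None) for f in schema}
    else:
        raise ValueError(f"unknown change kind {change_kind!r}")

    return PendingChange(
        change_id="", model_id=model_id, entity_kind=entity_kind,
        entity_id=entity_id, change_kind=change_kind, deltas=deltas,
        author=author, timestamp=0.0, comment=comment,
    )


def propose_change(store: Store, change: PendingChange, user: User) -> PendingChange:
    """Record a modification as pending; accepted views are unaffected.

    The change only takes effect after administrator approval.
    """
    decision = check_permission(user, "edit", store.target(change.model_id))
    if not decision:
        raise PermissionDenied(decision.reason)
    _validate_draft(store, change)
    store._change_counter += 1
    change.change_id = f"c{store._change_counter}"
    change.author = user.username
    change.timestamp = store.clock()
    change.state = "pending"
    store.changes[change.change_id] = change
    store.change_order.append(change.change_id)
    return change


def _validate_draft(store: Store, change: PendingChange) -> None:
    if change.entity_kind not in ENTITY_KINDS:
        raise ValueError(f"unknown entity kind {change.entity_kind!r}")
    schema = FIELD_SCHEMAS[change.entity_kind]
    unknown = set(change.deltas) - set(schema)
    if unknown:
        raise ValueError(f"unknown fields {sorted(unknown)}")
    if change.change_kind == "create":
        if any(old is not None for old, _ in change.deltas.values()):
            raise ValueError("create changes must not carry old values")
    elif change.change_kind == "delete":
        if any(new is not None for _, new in change.deltas.values()):
            raise ValueError("delete changes must not carry new values")
    elif change.change_kind != "update":
        raise ValueError(f"unknown change kind {change.change_kind!r}")
    # value-level invariants that can be checked in isolation
    if change.entity_kind == "reaction":
        for f, (_, new) in change.deltas.items():
            if f == "reactants" and new:
                for r in new:
                    if r["stoichiometry"] <= 0:
                        raise ValueError("stoichiometry must be positive")
                    if r["side"] not in (core.SUBSTRATE, core.PRODUCT):
                        raise ValueError(f"bad reactant side {r['side']!r}")
            if f == "gpr" and new:
                core.parse_gpr(new)  # raises on malformed rules


def approve_changes(store: Store, change_ids: Sequence[str], admin: User,
                    version_label: Optional[str] = None) -> Revision:
    """Approve a set of pending changes as one new revision.

    The revision number is the previous maximum plus one; all changes apply
    atomically and each affected model receives a new user-defined version
    label (an auto-incremented numeral when none is supplied).
    """
    decision = check_permission(admin, "approve", Target("", False))
    if not decision:
        raise PermissionDenied(decision.reason)
    if not change_ids:
        raise ValueError("no changes to approve")
    changes = []
    for cid in change_ids:
        if cid not in store.changes:
            raise NotFound(f"unknown change {cid!r}")
        ch = store.changes[cid]
        if ch.state != "pending":
            raise StateError(f"change {cid!r} is {ch.state}, not pending")
        changes.append(ch)

    number = store.current_revision() + 1
    affected = sorted({ch.model_id for ch in changes})
    labels: Dict[str, str] = {}
    for model_id in affected:
        if version_label is not None:
            labels[model_id] = version_label
        else:
            prior = sum(1 for rev in store.revisions if model_id in rev.version_labels)
            labels[model_id] = str(prior + 1)

    for ch in changes:
        ch.state = "approved"
    revision = Revision(number, [ch.change_id for ch in changes],
                        admin.username, store.clock(), labels)
    store.revisions.append(revision)
    return revision


def reject_changes(store: Store, change_ids: Sequence[str], admin: User) -> List[PendingChange]:
    """Mark pending changes rejected; they are retained for audit but never
    applied and never appear in entity histories."""
    decision = check_permission(admin, "approve", Target("", False))
    if not decision:
        raise PermissionDenied(decision.reason)
    out = []
    for cid in change_ids:
        ch = store.changes.get(cid)
        if ch is None:
            raise NotFound(f"unknown change {cid!r}")
        if ch.state != "pending":
            raise StateError(f"change {cid!r} is {ch.state}, not pending")
        ch.state = "rejected"
        out.append(ch)
    return out


# ---------------------------------------------------------------------------
# Snapshot reconstruction and history
# ---------------------------------------------------------------------------


def model_at_revision(store: Store, model_id: str,
                      revision_number: Optional[int] = None) -> Model:
    """Reconstruct the complete model at a revision.

    Every entity appears in the state given by its latest approved change at
    or before the revision; entities created later are absent; pending
    changes never appear.  Without a revision number the current head is
    returned.
    """
    r = store.current_revision() if revision_number is None else revision_number
    if r > store.current_revision() or r < 0:
        raise NotFound(f"revision {r} does not exist (head is {store.current_revision()})")

    entities: Dict[Tuple[str, str], Optional[Dict[str, object]]] = {}
    label = ""
    for rev in store.revisions[:r]:
        if model_id in rev.version_labels:
            label = rev.version_labels[model_id]
        for cid in rev.approved_changes:
            ch = store.changes[cid]
            if ch.model_id != model_id:
                continue
            key = (ch.entity_kind, ch.entity_id)
            if ch.change_kind == "create":
                entities[key] = {f: new for f, (_, new) in ch.deltas.items()}
            elif ch.change_kind == "update":
                state = entities.get(key)
                if state is not None:
                    for f, (_, new) in ch.deltas.items():
                        state[f] = new
            else:
                entities[key] = None

    model_fields = entities.get(("model", model_id))
    if model_fields is None:
        raise NotFound(f"model {model_id!r} does not exist at revision {r}")

    model = Model(
        model_id=model_id,
        name=model_fields.get("name", ""),
        organism=model_fields.get("organism", ""),
        version_label=label,
        subsystems=list(model_fields.get("subsystems") or []),
        annotations=_dec_annotations(model_fields.get("annotations") or []),
        notes=model_fields.get("notes") or "",
    )
    for kind in ("compartment", "metabolite", "gene", "reaction"):
        for (k, local_id), fields in entities.items():
            if k == kind and fields is not None:
                model.add(fields_to_entity(kind, local_id, fields))
    return model


def entity_history(store: Store, entity: str) -> List[HistoryEntry]:
    """Ordered history of one entity: creation first, then each approved
    modification with the fields it changed.

    ``entity`` is a ``<model_id>/<kind>/<local_id>`` key.  Replaying the
    diffs from the creation entry reproduces the current head state.
    """
    model_id, kind, local_id = split_entity_key(entity)
    entries: List[HistoryEntry] = []
    for rev in store.revisions:
        for cid in rev.approved_changes:
            ch = store.changes[cid]
            if (ch.model_id, ch.entity_kind, ch.entity_id) != (model_id, kind, local_id):
                continue
            entries.append(HistoryEntry(
                revision=rev.revision_number, author=ch.author,
                timestamp=ch.timestamp, comment=ch.comment,
                change_kind=ch.change_kind, diffs=dict(ch.deltas),
            ))
    if not entries:
        raise NotFound(f"no history for entity {entity!r}")
    return entries


# ---------------------------------------------------------------------------
# Bulk import of a whole model
# ---------------------------------------------------------------------------


def model_to_changes(store: Store, model: Model, author: str = "",
                     comment: str = "") -> List[PendingChange]:
    """Draft create-changes for a model and all its entities."""
    drafts = []
    kind, local_id, fields = entity_to_fields(model)
    drafts.append(draft_change(store, model.model_id, kind, local_id,
                               "create", fields, author, comment))
    for collection in (model.compartments.values(), model.metabolites.values(),
                       model.genes.values(), model.reactions.values()):
        for entity in collection:
            kind, local_id, fields = entity_to_fields(entity)
            drafts.append(draft_change(store, model.model_id, kind, local_id,
                                       "create", fields, author, comment))
    return drafts


def import_model(store: Store, model: Model, user: User,
                 admin: Optional[User] = None,
                 version_label: Optional[str] = None,
                 comment: str = "imported model") -> List[PendingChange]:
    """Propose creation of a whole model; approve immediately if ``admin``
    is given.  Returns the recorded changes."""
    decision = check_permission(user, "import", store.target(model.model_id))
    if not decision:
        raise PermissionDenied(decision.reason)
    changes = [propose_change(store, d, user)
               for d in model_to_changes(store, model, comment=comment)]
    if admin is not None:
        approve_changes(store, [c.change_id for c in changes], admin, version_label)
    return changes
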