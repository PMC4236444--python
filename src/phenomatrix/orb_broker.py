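"""Ontology Request Broker: provisional-term minting, resolution, migration.

Curating a character matrix constantly surfaces anatomical concepts that the
relevant ontology does not yet contain.  Rather than pausing annotation to
shepherd a term request through community review, a curator mints a
*provisional term*: a globally unique URI usable in annotations immediately.
Later, an ontology editor either adds the concept as an official term or
recognizes it as a duplicate of an existing one, and records that term's URI
as the provisional request's *permanent id*.  The next sync then marks the
provisional term obsolete (``replaced_by`` the permanent id) in the ontology
session and rewrites every annotation in the data file to the permanent id.

The backing store is an interface contract with three capabilities: mint a
fresh unique id, list all requests by a submitter, and set a request's
permanent id (all other fields are immutable after creation).  The default
backend is a local JSON-lines file, fully offline; a REST backend would map
create to POST, list to a submitter-filtered GET, and resolution to a PATCH
of ``permanent_id``, but no network client is included.  Projects typically
share one submitter id so all curators see (and avoid duplicating) each
other's requests.
"""

from __future__ import annotations

import datetime
import json
import os
import random
import uuid
import warnings
from dataclasses import dataclass, field

from .errors import (
    AlreadyResolvedError,
    BrokerStoreError,
    BrokerValidationError,
    MissingRequestError,
)
from .matrix_model import MigrationReport, StudyDocument, apply_term_migration
from .ontology_store import OntologyGraph, TermRef, merge_provisional

DEFAULT_PROVISIONAL_NAMESPACE = "http://example.org/provisional/"


class DuplicateLabelWarning(UserWarning):
    """A request re-uses the label of an earlier request by any submitter."""


@dataclass
class ProvisionalRequest:
    """One provisional-term request.

    Status is derived: the request is *pending* while ``permanent_id`` is
    None and *resolved* once it is set.
    """

    provisional_id: str
    label: str
    definition: str = ""
    suggested_superclass: TermRef | None = None
    synonyms: list[str] = field(default_factory=list)
    submitter: str = ""
    created: str = ""
    permanent_id: str | None = None

    @property
    def is_pending(self) -> bool:
        return self.permanent_id is None

    def to_json(self) -> dict:
        return {
            "provisional_id": self.provisional_id,
            "label": self.label,
            "definition": self.definition,
            "suggested_superclass": (
                None
                if self.suggested_superclass is None
                else {
                    "id": self.suggested_superclass.id,
                    "label": self.suggested_superclass.cached_label,
                }
            ),
            "synonyms": list(self.synonyms),
            "submitter": self.submitter,
            "created": self.created,
            "permanent_id": self.permanent_id,
        }

    @classmethod
    def from_json(cls, data: dict) -> "ProvisionalRequest":
        sup = data.get("suggested_superclass")
        return cls(
            provisional_id=data["provisional_id"],
            label=data["label"],
            definition=data.get("definition", ""),
            suggested_superclass=(
                None if sup is None else TermRef(sup["id"], sup.get("label"))
            ),
            synonyms=list(data.get("synonyms", [])),
            submitter=data.get("submitter", ""),
            created=data.get("created", ""),
            permanent_id=data.get("permanent_id"),
        )


class JsonLinesBrokerStore:
    """Broker store backed by a local JSON-lines file (one record per line).

    Creation appends; resolution rewrites the file.  The store re-reads the
    file on every operation, so several sessions sharing the file (e.g. via a
    folder-sync service) observe each other's requests.

    ``rng`` may supply a seeded :class:`random.Random` so minted UUIDs are
    reproducible; by default ids come from :func:`uuid.uuid4`.
    """

    def __init__(
        self,
        path: str,
        provisional_namespace: str = DEFAULT_PROVISIONAL_NAMESPACE,
        rng: random.Random | None = None,
    ):
        self.path = path
        self.provisional_namespace = provisional_namespace
        self._rng = rng

    # -- persistence ---------------------------------------------------------

    def _read_all(self) -> list[ProvisionalRequest]:
        if not os.path.exists(self.path):
            return []
        records = []
        try:
            with open(self.path, "r", encoding="utf-8") as fh:
                for line_no, line in enumerate(fh, start=1):
                    line = line.strip()
                    if not line:
                        continue
                    try:
                        records.append(ProvisionalRequest.from_json(json.loads(line)))
                    except (json.JSONDecodeError, KeyError) as exc:
                        raise BrokerStoreError(
                            f"{self.path}:{line_no}: corrupt record: {exc}"
                        ) from exc
        except OSError as exc:
            raise BrokerStoreError(f"cannot read {self.path}: {exc}") from exc
        return records

    def _append(self, record: ProvisionalRequest) -> None:
        try:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(record.to_json(), sort_keys=True) + "\n")
        except OSError as exc:
            raise BrokerStoreError(f"cannot write {self.path}: {exc}") from exc

    def _rewrite(self, records: list[ProvisionalRequest]) -> None:
        tmp = self.path + ".tmp"
        try:
            with open(tmp, "w", encoding="utf-8") as fh:
                for rec in records:
                    fh.write(json.dumps(rec.to_json(), sort_keys=True) + "\n")
            os.replace(tmp, self.path)
        except OSError as exc:
            raise BrokerStoreError(f"cannot write {self.path}: {exc}") from exc

    # -- contract ------------------------------------------------------------

    def _mint_id(self, existing: set[str]) -> str:
        while True:
            if self._rng is not None:
                u = uuid.UUID(int=self._rng.getrandbits(128), version=4)
            else:
                u = uuid.uuid4()
            pid = f"{self.provisional_namespace}{u}"
            if pid not in existing:  # ids are never reused
                return pid

    def create(
        self,
        label: str,
        definition: str,
        suggested_superclass: TermRef | None,
        synonyms: list[str],
        submitter: str,
    ) -> ProvisionalRequest:
        existing = self._read_all()
        now = datetime.datetime.now(datetime.timezone.utc)
        if existing:
            # keep `created` strictly increasing so creation order survives
            # the (created, id) sort even under sub-microsecond bursts
            latest = max(
                datetime.datetime.fromisoformat(r.created)
                for r in existing
                if r.created
            )
            if now <= latest:
                now = latest + datetime.timedelta(microseconds=1)
        record = ProvisionalRequest(
            provisional_id=self._mint_id({r.provisional_id for r in existing}),
            label=label,
            definition=definition,
            suggested_superclass=suggested_superclass,
            synonyms=list(synonyms),
            submitter=submitter,
            created=now.isoformat(),
        )
        self._append(record)
        return record

    def list(self, submitter: str) -> list[ProvisionalRequest]:
        records = [r for r in self._read_all() if r.submitter == submitter]
        records.sort(key=lambda r: (r.created, r.provisional_id))
        return records

    def get(self, provisional_id: str) -> ProvisionalRequest:
        for rec in self._read_all():
            if rec.provisional_id == provisional_id:
                return rec
        raise MissingRequestError(f"no request with id {provisional_id}")

    def set_permanent_id(self, provisional_id: str, permanent_id: str) -> ProvisionalRequest:
        records = self._read_all()
        updated = None
        for rec in records:
            if rec.provisional_id == provisional_id:
                if rec.permanent_id is not None:
                    raise AlreadyResolvedError(
                        f"{provisional_id} is already resolved to {rec.permanent_id}"
                    )
                rec.permanent_id = permanent_id
                updated = rec
                break
        if updated is None:
            raise MissingRequestError(f"no request with id {provisional_id}")
        self._rewrite(records)
        return updated


# ---------------------------------------------------------------------------
# Broker operations
# ---------------------------------------------------------------------------

def request_term(
    store: JsonLinesBrokerStore,
    label: str,
    definition: str = "",
    superclass: TermRef | None = None,
    synonyms: list[str] | None = None,
    submitter: str = "",
) -> ProvisionalRequest:
    """Mint a provisional term; the returned request is pending.

    Duplicate labels are allowed (avoiding them is a social convention), but
    a :class:`DuplicateLabelWarning` lists existing requests with the same
    label so the curator can double-check.
    """
    if not label:
        raise BrokerValidationError("a term request needs a non-empty label")
    if not submitter:
        raise BrokerValidationError("a term request needs a non-empty submitter")
    same_label = [
        r.provisional_id for r in store._read_all() if r.label == label
    ]
    if same_label:
        warnings.warn(
            f"label {label!r} already requested as: {', '.join(same_label)}",
            DuplicateLabelWarning,
            stacklevel=2,
        )
    return store.create(label, definition, superclass, synonyms or [], submitter)


def list_requests(
    store: JsonLinesBrokerStore, submitter: str
) -> list[ProvisionalRequest]:
    """All requests ever created by ``submitter``, in creation order."""
    return store.list(submitter)


def resolve_request(
    store: JsonLinesBrokerStore, provisional_id: str, permanent_id: str
) -> ProvisionalRequest:
    """Record the permanent id for a pending request.

    The permanent id need not exist in any loaded ontology: it may name a
    pre-existing term that was simply not discovered during annotation.
    Re-resolution is forbidden.
    """
    if not permanent_id:
        raise BrokerValidationError("permanent_id must be non-empty")
    if permanent_id == provisional_id:
        raise BrokerValidationError("permanent_id must differ from the provisional id")
    return store.set_permanent_id(provisional_id, permanent_id)


def sync_and_migrate(
    store: JsonLinesBrokerStore,
    submitter: str,
    graph: OntologyGraph,
    doc: StudyDocument,
) -> tuple[OntologyGraph, StudyDocument, MigrationReport]:
    """Launch-time sync: merge the submitter's requests, migrate annotations.

    All of the submitter's provisional terms are merged into the ontology
    session (pending ones stay usable; resolved ones become obsolete with
    ``replaced_by`` the permanent id).  Every term reference in the document
    is then rewritten to its terminal replacement — following chains through
    ordinary obsolescence and provisional resolutions alike.  Ids still
    pending are reported as ``untouched_provisional``.  Idempotent: a second
    sync against the same store rewrites nothing.
    """
    requests = list_requests(store, submitter)
    merged = merge_provisional(graph, requests)

    from .ontology_store import resolve_replacement

    def resolver(term_id: str) -> str:
        if term_id not in merged.terms:
            return term_id
        return resolve_replacement(merged, term_id, allow_dangling=True)

    new_doc, report = apply_term_migration(doc, resolver)

    pending = {r.provisional_id for r in requests if r.is_pending}
    in_use: set[str] = set()
    for taxon in new_doc.taxa:
        if taxon.taxonomy_ref is not None:
            in_use.add(taxon.taxonomy_ref.id)
    for _ci, _sym, _ai, ann in new_doc.iter_annotations():
        for ref in (ann.entity, ann.quality, ann.related_entity):
            if ref is not None:
                in_use.add(ref.id)
    report.untouched_provisional = sorted(pending & in_use)
    return merged, new_doc, report
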