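"""Collaboration-safe editing sessions.

Curation teams share annotation files through folder-sync services, so an
editor must (a) never lose work — every edit is reversible and, with
autosave on, immediately persisted — and (b) never clobber or silently miss
a collaborator's changes — the bound file is monitored and any on-disk
change *not* caused by this session's own save is reported so the user can
reload.

Change detection is content-hash based rather than mtime based: sync
services may rewrite identical bytes, and clocks skew across machines.  The
session remembers the hash of the last bytes it wrote itself
(``last_self_write_token``); the classification contract is a truth table
over that token, exposed as a polling API (no background thread required):

* current bytes hash to the token, already acknowledged -> ``UNCHANGED``
* current bytes hash to the token, first sighting      -> ``SELF_SAVE``
* anything else                                         -> ``EXTERNAL_CHANGE``
  (a deleted file is an external change with ``deleted=True``)

Autosave writes are atomic (temp file + rename) so a sync service never
observes a half-written matrix.  Autosave fires after every edit, undo and
redo; a debounce interval is deliberately not built in, but callers may
batch edits before applying them.
"""

from __future__ import annotations

import copy
import enum
import hashlib
import os
import tempfile
import time
from dataclasses import dataclass
from typing import Callable, Iterator

from .errors import EditError, UnsavedChangesError
from .matrix_model import EQAnnotation, StudyDocument
from .nexml_io import CurieMap, nexml_bytes, read_nexml


class ChangeKind(enum.Enum):
    UNCHANGED = "unchanged"
    SELF_SAVE = "self_save"
    EXTERNAL_CHANGE = "external_change"


@dataclass(frozen=True)
class ChangeEvent:
    kind: ChangeKind
    deleted: bool = False


@dataclass
class Edit:
    """A reversible document transformation.

    ``inverse`` must undo ``forward`` exactly on the document the edit was
    recorded against (``inverse(forward(doc)) == doc``); the factory helpers
    below capture the prior value to guarantee this.
    """

    description: str
    forward: Callable[[StudyDocument], StudyDocument]
    inverse: Callable[[StudyDocument], StudyDocument]


def _hash(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


class EditSession:
    """An editing session over a study document, optionally bound to a file."""

    def __init__(
        self,
        document: StudyDocument,
        bound_path: str | None = None,
        autosave_enabled: bool = False,
        curie_map: CurieMap | None = None,
    ):
        self.document = document
        self.bound_path = bound_path
        self.autosave_enabled = autosave_enabled
        self.curie_map = curie_map
        self.undo_stack: list[Edit] = []
        self.redo_stack: list[Edit] = []
        self.dirty = False
        self.last_self_write_token: str | None = None
        self._token_acknowledged = True

    # -- editing -------------------------------------------------------------

    def apply_edit(self, edit: Edit) -> "EditSession":
        """Apply an edit; on failure the session is left untouched."""
        working = copy.deepcopy(self.document)
        try:
            new_doc = edit.forward(working)
        except Exception as exc:
            raise EditError(f"edit {edit.description!r} failed: {exc}") from exc
        self.document = new_doc if new_doc is not None else working
        self.undo_stack.append(edit)
        self.redo_stack.clear()
        self._after_change()
        return self

    def undo(self) -> "EditSession":
        if not self.undo_stack:
            raise EditError("nothing to undo")
        edit = self.undo_stack.pop()
        working = copy.deepcopy(self.document)
        new_doc = edit.inverse(working)
        self.document = new_doc if new_doc is not None else working
        self.redo_stack.append(edit)
        self._after_change()
        return self

    def redo(self) -> "EditSession":
        if not self.redo_stack:
            raise EditError("nothing to redo")
        edit = self.redo_stack.pop()
        working = copy.deepcopy(self.document)
        new_doc = edit.forward(working)
        self.document = new_doc if new_doc is not None else working
        self.undo_stack.append(edit)
        self._after_change()
        return self

    def _after_change(self) -> None:
        self.dirty = True
        if self.autosave_enabled and self.bound_path is not None:
            self.save()

    # -- persistence ---------------------------------------------------------

    def save(self) -> None:
        """Atomically write the document to the bound path."""
        if self.bound_path is None:
            raise EditError("session is not bound to a file")
        data = nexml_bytes(self.document, self.curie_map)
        directory = os.path.dirname(os.path.abspath(self.bound_path))
        fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
        try:
            with os.fdopen(fd, "wb") as fh:
                fh.write(data)
            os.replace(tmp, self.bound_path)
        finally:
            if os.path.exists(tmp):
                os.unlink(tmp)
        self.last_self_write_token = _hash(data)
        self._token_acknowledged = False
        self.dirty = False

    # -- change monitoring ---------------------------------------------------

    def classify_file_change(self, current_bytes: bytes | None = None) -> ChangeEvent:
        """Classify the bound file's current content against the session.

        ``current_bytes`` may be supplied directly (e.g. by a test or a
        notification callback); by default the bound file is read.  A missing
        file counts as an external change with the deletion flag set.
        """
        if self.bound_path is None:
            raise EditError("session is not bound to a file")
        if current_bytes is None:
            try:
                with open(self.bound_path, "rb") as fh:
                    current_bytes = fh.read()
            except FileNotFoundError:
                return ChangeEvent(ChangeKind.EXTERNAL_CHANGE, deleted=True)
        token = _hash(current_bytes)
        if token == self.last_self_write_token:
            if self._token_acknowledged:
                return ChangeEvent(ChangeKind.UNCHANGED)
            self._token_acknowledged = True
            return ChangeEvent(ChangeKind.SELF_SAVE)
        return ChangeEvent(ChangeKind.EXTERNAL_CHANGE)

    def reload(self, force: bool = False) -> "EditSession":
        """Replace the document with the bound file's content.

        Refused while unsaved edits exist unless ``force`` is given, since
        reloading would discard them.  (With autosave enabled this situation
        cannot arise: the session is clean after every edit.)
        """
        if self.bound_path is None:
            raise EditError("session is not bound to a file")
        if self.dirty and not force:
            raise UnsavedChangesError(
                "unsaved changes would be discarded; pass force=True to reload anyway"
            )
        with open(self.bound_path, "rb") as fh:
            data = fh.read()
        import io

        self.document = read_nexml(io.BytesIO(data))
        self.undo_stack.clear()
        self.redo_stack.clear()
        self.dirty = False
        self.last_self_write_token = _hash(data)
        self._token_acknowledged = True
        return self


def watch(
    session: EditSession,
    interval: float = 1.0,
    max_events: int | None = None,
) -> Iterator[ChangeEvent]:
    """Poll the bound file, yielding every non-UNCHANGED event.

    Generator form of the file monitor: the CLI prints the events, tests
    drive it with a small ``max_events``.
    """
    emitted = 0
    while max_events is None or emitted < max_events:
        event = session.classify_file_change()
        if event.kind is not ChangeKind.UNCHANGED:
            yield event
            emitted += 1
            if max_events is not None and emitted >= max_events:
                return
        time.sleep(interval)


# ---------------------------------------------------------------------------
# Edit factories
# ---------------------------------------------------------------------------

def set_cell_edit(
    doc: StudyDocument, taxon_index: int, character_index: int, symbols: set[str]
) -> Edit:
    """Reversible cell score; captures the prior value for the inverse."""
    key = (taxon_index, character_index)
    old = doc.cells.get(key)

    def forward(d: StudyDocument) -> StudyDocument:
        return d.set_cell(taxon_index, character_index, symbols)

    def inverse(d: StudyDocument) -> StudyDocument:
        if old is None:
            return d.clear_cell(taxon_index, character_index)
        return d.set_cell(taxon_index, character_index, old)

    return Edit(
        description=f"score taxon {taxon_index} x character {character_index}",
        forward=forward,
        inverse=inverse,
    )


def annotate_state_edit(
    doc: StudyDocument, character_index: int, state_symbol: str, ann: EQAnnotation
) -> Edit:
    """Reversible annotation append."""

    def forward(d: StudyDocument) -> StudyDocument:
        return d.annotate_state(character_index, state_symbol, copy.deepcopy(ann))

    def inverse(d: StudyDocument) -> StudyDocument:
        d.characters[character_index].state(state_symbol).annotations.pop()
        return d

    return Edit(
        description=f"annotate character {character_index} state {state_symbol!r}",
        forward=forward,
        inverse=inverse,
    )


def set_source_metadata_edit(doc: StudyDocument, key: str, value: str) -> Edit:
    """Reversible document-metadata update."""
    old = doc.source_metadata.get(key)

    def forward(d: StudyDocument) -> StudyDocument:
        d.source_metadata[key] = value
        return d

    def inverse(d: StudyDocument) -> StudyDocument:
        if old is None:
            d.source_metadata.pop(key, None)
        else:
            d.source_metadata[key] = old
        return d

    return Edit(description=f"set metadata {key!r}", forward=forward, inverse=inverse)
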