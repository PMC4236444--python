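"""In-memory model of an annotated phenotypic character matrix.

A :class:`StudyDocument` is the taxa x characters table familiar from
systematics, extended with semantic annotations:

* each character *state* may carry Entity-Quality (EQ) phenotype annotations
  — an anatomical or process entity term paired with a quality term, plus an
  optional related entity for relational qualities;
* each *taxon* may be annotated with an identifier from a taxonomy ontology.

Cells hold *sets* of state symbols so polymorphic scores ("0 and 1") are
first-class; a single score is a singleton set.  The cells map is sparse:
an absent entry means the taxon was not scored for that character.  The
symbol ``"?"`` is reserved for missing data and can never be annotated.

Annotations attach to states, not cells: a taxon-specific phenotype
assertion arises downstream by joining a cell's state symbols to the state's
annotations.
"""

from __future__ import annotations

import copy
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

from .errors import MatrixValueError
from .ontology_store import TermRef

#: Reserved missing-data symbol; never annotatable.
MISSING_SYMBOL = "?"


@dataclass
class EQAnnotation:
    """One Entity-Quality phenotype annotation on a character state."""

    entity: TermRef | None = None
    quality: TermRef | None = None
    related_entity: TermRef | None = None
    comment: str | None = None

    def __post_init__(self) -> None:
        if self.entity is None and self.quality is None:
            raise MatrixValueError(
                "an EQ annotation must carry at least an entity or a quality"
            )


@dataclass
class State:
    symbol: str
    label: str = ""
    annotations: list[EQAnnotation] = field(default_factory=list)


@dataclass
class Character:
    label: str
    states: list[State]

    def __post_init__(self) -> None:
        if not self.states:
            raise MatrixValueError(f"character {self.label!r} must have >= 1 state")
        symbols = [s.symbol for s in self.states]
        if len(set(symbols)) != len(symbols):
            raise MatrixValueError(
                f"character {self.label!r} has duplicate state symbols"
            )

    def state(self, symbol: str) -> State:
        for s in self.states:
            if s.symbol == symbol:
                return s
        raise MatrixValueError(
            f"character {self.label!r} has no state with symbol {symbol!r}"
        )

    def symbols(self) -> set[str]:
        return {s.symbol for s in self.states}


@dataclass
class Taxon:
    publication_label: str
    taxonomy_ref: TermRef | None = None

    def __post_init__(self) -> None:
        if not self.publication_label:
            raise MatrixValueError("taxon publication_label must be non-empty")


@dataclass
class StudyDocument:
    taxa: list[Taxon] = field(default_factory=list)
    characters: list[Character] = field(default_factory=list)
    #: (taxon_index, character_index) -> frozenset of state symbols; sparse.
    cells: dict[tuple[int, int], frozenset[str]] = field(default_factory=dict)
    source_metadata: dict[str, str] = field(default_factory=dict)

    # -- editing -------------------------------------------------------------

    def set_cell(
        self, taxon_index: int, character_index: int, symbols: Iterable[str]
    ) -> "StudyDocument":
        """Score a cell; ``symbols`` with more than one entry is polymorphic."""
        self._check_indices(taxon_index, character_index)
        symset = frozenset(symbols)
        if not symset:
            raise MatrixValueError("a cell must be scored with >= 1 symbol")
        char = self.characters[character_index]
        unknown = symset - char.symbols()
        if unknown:
            raise MatrixValueError(
                f"character {char.label!r} has no state(s) {sorted(unknown)}"
            )
        self.cells[(taxon_index, character_index)] = symset
        return self

    def clear_cell(self, taxon_index: int, character_index: int) -> "StudyDocument":
        self._check_indices(taxon_index, character_index)
        self.cells.pop((taxon_index, character_index), None)
        return self

    def annotate_state(
        self, character_index: int, state_symbol: str, ann: EQAnnotation
    ) -> "StudyDocument":
        """Append an EQ annotation to a state; multiple annotations stack."""
        if not 0 <= character_index < len(self.characters):
            raise MatrixValueError(f"character index {character_index} out of range")
        if state_symbol == MISSING_SYMBOL:
            raise MatrixValueError(
                f"the missing-data symbol {MISSING_SYMBOL!r} cannot be annotated"
            )
        state = self.characters[character_index].state(state_symbol)
        state.annotations.append(ann)
        return self

    def _check_indices(self, taxon_index: int, character_index: int) -> None:
        if not 0 <= taxon_index < len(self.taxa):
            raise MatrixValueError(f"taxon index {taxon_index} out of range")
        if not 0 <= character_index < len(self.characters):
            raise MatrixValueError(f"character index {character_index} out of range")

    # -- traversal -----------------------------------------------------------

    def iter_annotations(self) -> Iterator[tuple[int, str, int, EQAnnotation]]:
        """Yield (character_index, state_symbol, annotation_index, annotation)."""
        for ci, char in enumerate(self.characters):
            for state in char.states:
                for ai, ann in enumerate(state.annotations):
                    yield ci, state.symbol, ai, ann

    def term_reference_count(self) -> int:
        """Total TermRefs in the document (taxonomy + EQ positions)."""
        n = sum(1 for t in self.taxa if t.taxonomy_ref is not None)
        for _ci, _sym, _ai, ann in self.iter_annotations():
            n += sum(
                ref is not None
                for ref in (ann.entity, ann.quality, ann.related_entity)
            )
        return n

    def copy(self) -> "StudyDocument":
        return copy.deepcopy(self)


@dataclass
class MigrationReport:
    """What :func:`apply_term_migration` rewrote.

    ``replacements`` maps each retired id to its replacement and the number of
    reference positions rewritten; ``untouched_provisional`` lists provisional
    ids that remain in use because they are still pending.
    """

    replacements: dict[str, tuple[str, int]] = field(default_factory=dict)
    untouched_provisional: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for old, (new, count) in self.replacements.items():
            if old == new:
                raise MatrixValueError("migration must change the id")
            if count < 1:
                raise MatrixValueError("migration counts must be >= 1")

    @property
    def total_rewritten(self) -> int:
        return sum(count for _new, count in self.replacements.values())


def apply_term_migration(
    doc: StudyDocument, resolver: Callable[[str], str]
) -> tuple[StudyDocument, MigrationReport]:
    """Rewrite every term reference through ``resolver``.

    The resolver must be total (identity for ids it does not know).  Returns a
    new document plus a report of every changed id with its rewrite count; the
    stale cached label of a rewritten reference is dropped.  Applying the same
    resolver twice yields an empty second report (idempotence), and the total
    number of term references is preserved.
    """
    new_doc = doc.copy()
    counts: Counter[tuple[str, str]] = Counter()

    def migrate(ref: TermRef | None) -> TermRef | None:
        if ref is None:
            return None
        target = resolver(ref.id)
        if target == ref.id:
            return ref
        counts[(ref.id, target)] += 1
        return TermRef(id=target)

    for taxon in new_doc.taxa:
        taxon.taxonomy_ref = migrate(taxon.taxonomy_ref)
    for char in new_doc.characters:
        for state in char.states:
            for ann in state.annotations:
                ann.entity = migrate(ann.entity)
                ann.quality = migrate(ann.quality)
                ann.related_entity = migrate(ann.related_entity)

    report = MigrationReport(
        replacements={old: (new, n) for (old, new), n in sorted(counts.items())}
    )
    return new_doc, report
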