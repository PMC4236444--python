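"""In-memory ontology graphs parsed from a documented OBO tag subset.

The store understands just enough of the OBO flat-file format (1.2/1.4) to
support annotation work: ``[Term]`` stanzas with ``id``, ``name``, ``def``,
``synonym``, ``is_a``, ``is_obsolete``, ``replaced_by`` and ``namespace``
tags.  Unknown tags and non-Term stanzas are ignored with a logged notice.
On top of the parsed graph it answers the three queries every other module
needs: subsumption (transitive ``is_a`` closure), obsolescence, and
``replaced_by`` resolution.

Reasoning semantics
-------------------
* ``is_a`` is the only relationship type; the relation must be acyclic.
* Obsolete terms are excluded from subsumption: they never appear in
  ``descendants`` results and their outgoing ``is_a`` edges are ignored, so a
  retired branch cannot satisfy (or violate) a consistency rule.
* ``replaced_by`` chains are followed transitively to a terminal term; this
  is the substrate for migrating annotations off retired or provisional ids.

Identifiers are opaque strings: OBO-style CURIEs (``UBERON:0000001``) and
full URIs are both accepted and compared by exact string equality.  CURIE/URI
expansion is a serialization concern and lives in :mod:`phenomatrix.nexml_io`.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import (
    DanglingReplacementError,
    DuplicateTermError,
    MissingTermError,
    OboParseError,
    OntologyCycleError,
    ReplacementCycleError,
    TermCollisionError,
)

logger = logging.getLogger(__name__)

SYNONYM_SCOPES = ("EXACT", "BROAD", "NARROW", "RELATED")

#: OBO tags the parser interprets; anything else is ignored with a notice.
KNOWN_TAGS = frozenset(
    {"id", "name", "def", "synonym", "is_a", "is_obsolete", "replaced_by", "namespace"}
)


class ReplacementAmbiguityWarning(UserWarning):
    """A term lists several replaced_by targets; only the first is followed."""


@dataclass
class Term:
    """One ontology class.

    ``is_placeholder`` marks terms that were only ever seen as the parent of
    an ``is_a`` line (a dangling reference in an ontology slice); they carry
    no label or definition and are reported by
    :meth:`OntologyGraph.placeholder_ids`.
    """

    id: str
    label: str | None = None
    definition: str | None = None
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    is_obsolete: bool = False
    replaced_by: list[str] = field(default_factory=list)
    namespace: str | None = None
    is_provisional: bool = False
    is_placeholder: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Term id must be non-empty")


@dataclass(frozen=True)
class TermRef:
    """A reference to an ontology term from an annotation.

    The optional cached label is a display convenience only; identity is the
    id string.
    """

    id: str
    cached_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("TermRef id must be non-empty")


class OntologyGraph:
    """Terms plus the acyclic ``is_a`` relation over them."""

    def __init__(self) -> None:
        self.terms: dict[str, Term] = {}
        # edges run child -> parent
        self._dag: nx.DiGraph = nx.DiGraph()

    # -- construction --------------------------------------------------------

    def add_term(self, term: Term) -> None:
        existing = self.terms.get(term.id)
        if existing is not None and not existing.is_placeholder:
            raise DuplicateTermError(f"duplicate term id: {term.id}")
        self.terms[term.id] = term
        self._dag.add_node(term.id)

    def add_is_a(self, child_id: str, parent_id: str) -> None:
        """Record ``child is_a parent``; unseen parents become placeholders."""
        if child_id not in self.terms:
            raise MissingTermError(f"is_a child not in graph: {child_id}")
        if parent_id not in self.terms:
            self.terms[parent_id] = Term(id=parent_id, is_placeholder=True)
            logger.info("dangling is_a parent %s kept as placeholder", parent_id)
        self._dag.add_edge(child_id, parent_id)

    def check_acyclic(self) -> None:
        try:
            cycle = nx.find_cycle(self._dag)
        except nx.NetworkXNoCycle:
            return
        raise OntologyCycleError([edge[0] for edge in cycle] + [cycle[-1][1]])

    # -- inspection ----------------------------------------------------------

    @property
    def is_a_edges(self) -> set[tuple[str, str]]:
        return set(self._dag.edges())

    def placeholder_ids(self) -> list[str]:
        return sorted(t.id for t in self.terms.values() if t.is_placeholder)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return self.terms == other.terms and self.is_a_edges == other.is_a_edges

    def copy(self) -> "OntologyGraph":
        import copy as _copy

        g = OntologyGraph()
        g.terms = {tid: _copy.deepcopy(t) for tid, t in self.terms.items()}
        g._dag = self._dag.copy()
        return g

    # -- reasoning -----------------------------------------------------------

    def parents(self, term_id: str) -> set[str]:
        if term_id not in self.terms:
            raise MissingTermError(term_id)
        return set(self._dag.successors(term_id))

    def descendants(self, root_id: str, include_self: bool = True) -> set[str]:
        """All non-obsolete terms reachable down reversed ``is_a`` edges.

        An obsolete term contributes no edges to reasoning, so subtrees that
        hang only off an obsolete term are unreachable.
        """
        if root_id not in self.terms:
            raise MissingTermError(f"unknown term: {root_id}")
        result: set[str] = set()
        stack = [root_id]
        seen = {root_id}
        while stack:
            cur = stack.pop()
            for child in self._dag.predecessors(cur):
                if child in seen:
                    continue
                seen.add(child)
                if self.terms[child].is_obsolete:
                    continue  # obsolete edges do not participate
                result.add(child)
                stack.append(child)
        if include_self and not self.terms[root_id].is_obsolete:
            result.add(root_id)
        return result

    def is_descendant(self, term_id: str, root_id: str) -> bool:
        if term_id not in self.terms:
            raise MissingTermError(f"unknown term: {term_id}")
        return term_id in self.descendants(root_id, include_self=True)


def descendants(graph: OntologyGraph, root_id: str, include_self: bool = True) -> set[str]:
    return graph.descendants(root_id, include_self=include_self)


def is_descendant(graph: OntologyGraph, term_id: str, root_id: str) -> bool:
    return graph.is_descendant(term_id, root_id)


def resolve_replacement(
    graph: OntologyGraph, term_id: str, allow_dangling: bool = False
) -> str:
    """Follow ``replaced_by`` links transitively to the terminal id.

    Returns ``term_id`` unchanged when it carries no replacement.  When a term
    lists several replacements the first is followed and a
    :class:`ReplacementAmbiguityWarning` is emitted — the curation workflow
    mints exactly one permanent id per provisional term, so multiplicity is an
    out-of-band ontology event.

    With ``allow_dangling`` the chain may terminate at an id absent from the
    graph (a permanent id for a term that is simply not loaded); otherwise a
    dangling target raises :class:`DanglingReplacementError`.
    """
    if term_id not in graph.terms:
        raise MissingTermError(f"unknown term: {term_id}")
    visited = [term_id]
    current = term_id
    while True:
        term = graph.terms.get(current)
        if term is None or not term.replaced_by:
            return current
        if len(term.replaced_by) > 1:
            warnings.warn(
                f"{current} lists {len(term.replaced_by)} replaced_by targets; "
                f"following the first ({term.replaced_by[0]})",
                ReplacementAmbiguityWarning,
                stacklevel=2,
            )
        nxt = term.replaced_by[0]
        if nxt in visited:
            raise ReplacementCycleError(visited + [nxt])
        if nxt not in graph.terms and not allow_dangling:
            raise DanglingReplacementError(nxt)
        visited.append(nxt)
        current = nxt


# ---------------------------------------------------------------------------
# OBO parsing / serialization
# ---------------------------------------------------------------------------

_QUOTED = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(.*)$')


def _strip_comment(value: str) -> str:
    # OBO trailing comments start with " ! "
    idx = value.find(" ! ")
    if idx >= 0:
        value = value[:idx]
    if value.startswith("!"):
        return ""
    return value.strip()


def _parse_quoted(value: str, line_no: int, tag: str) -> tuple[str, str]:
    m = _QUOTED.match(value)
    if not m:
        raise OboParseError(f"{tag} value must start with a quoted string", line_no)
    text = m.group(1).replace('\\"', '"').replace("\\\\", "\\")
    return text, m.group(2).strip()


def parse_obo(text: str) -> OntologyGraph:
    """Parse an OBO document (documented tag subset) into an OntologyGraph.

    Raises :class:`DuplicateTermError` for a repeated term id,
    :class:`OntologyCycleError` when ``is_a`` is cyclic, and
    :class:`OboParseError` (with line number) for malformed stanzas.
    """
    graph = OntologyGraph()
    pending_edges: list[tuple[str, str, int]] = []

    current: dict | None = None
    current_line = 0
    in_term_stanza = False
    seen_ids: set[str] = set()

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        if "id" not in current:
            raise OboParseError("[Term] stanza has no id tag", current_line)
        tid = current["id"]
        if tid in seen_ids:
            raise DuplicateTermError(f"duplicate term id: {tid}", current_line)
        seen_ids.add(tid)
        graph.add_term(
            Term(
                id=tid,
                label=current.get("name"),
                definition=current.get("def"),
                synonyms=current.get("synonyms", []),
                is_obsolete=current.get("is_obsolete", False),
                replaced_by=current.get("replaced_by", []),
                namespace=current.get("namespace"),
            )
        )
        for parent, line_no in current.get("is_a", []):
            pending_edges.append((tid, parent, line_no))
        current = None

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush()
            if line == "[Term]":
                current = {}
                current_line = line_no
                in_term_stanza = True
            else:
                if not line.endswith("]"):
                    raise OboParseError(f"malformed stanza header: {line}", line_no)
                logger.info("ignoring %s stanza at line %d", line, line_no)
                in_term_stanza = False
            continue
        if ":" not in line:
            raise OboParseError(f"expected 'tag: value', got: {line}", line_no)
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = _strip_comment(value.strip())
        if current is None:
            # header line (format-version etc.) or tag inside ignored stanza
            if not in_term_stanza and tag not in ("format-version",) and "[" not in tag:
                logger.debug("header/ignored tag %s at line %d", tag, line_no)
            continue
        if tag not in KNOWN_TAGS:
            logger.info("ignoring unknown tag %r at line %d", tag, line_no)
            continue
        if tag == "id":
            if not value:
                raise OboParseError("empty id", line_no)
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "namespace":
            current["namespace"] = value
        elif tag == "def":
            text_val, _ = _parse_quoted(value, line_no, "def")
            current["def"] = text_val
        elif tag == "synonym":
            text_val, rest = _parse_quoted(value, line_no, "synonym")
            scope = rest.split()[0] if rest else "RELATED"
            if scope not in SYNONYM_SCOPES:
                scope = "RELATED"
            current.setdefault("synonyms", []).append((text_val, scope))
        elif tag == "is_a":
            if not value:
                raise OboParseError("empty is_a target", line_no)
            current.setdefault("is_a", []).append((value, line_no))
        elif tag == "is_obsolete":
            current["is_obsolete"] = value.lower() == "true"
        elif tag == "replaced_by":
            if not value:
                raise OboParseError("empty replaced_by target", line_no)
            current.setdefault("replaced_by", []).append(value)
    flush()

    for child, parent, _line_no in pending_edges:
        graph.add_is_a(child, parent)
    graph.check_acyclic()
    return graph


def serialize_obo(graph: OntologyGraph) -> str:
    """Deterministic OBO writer for debugging and round-trip tests.

    Stanzas are sorted by id; placeholder terms (dangling parents) are not
    written — re-parsing recreates them from the ``is_a`` lines, so
    ``parse(serialize(g)) == g``.
    """
    out = ["format-version: 1.2", ""]
    parents_of: dict[str, list[str]] = {}
    for child, parent in sorted(graph.is_a_edges):
        parents_of.setdefault(child, []).append(parent)
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        if term.is_placeholder:
            continue
        out.append("[Term]")
        out.append(f"id: {term.id}")
        if term.label is not None:
            out.append(f"name: {term.label}")
        if term.namespace is not None:
            out.append(f"namespace: {term.namespace}")
        if term.definition is not None:
            esc = term.definition.replace("\\", "\\\\").replace('"', '\\"')
            out.append(f'def: "{esc}" []')
        for text, scope in term.synonyms:
            esc = text.replace("\\", "\\\\").replace('"', '\\"')
            out.append(f'synonym: "{esc}" {scope} []')
        for parent in sorted(parents_of.get(tid, [])):
            out.append(f"is_a: {parent}")
        if term.is_obsolete:
            out.append("is_obsolete: true")
        for rep in term.replaced_by:
            out.append(f"replaced_by: {rep}")
        out.append("")
    return "\n".join(out)


def merge_provisional(graph: OntologyGraph, requests: Iterable) -> OntologyGraph:
    """Return a new graph with provisional-term requests merged in.

    Pending requests become provisional terms, attached below their suggested
    superclass when that superclass is present.  Resolved requests become
    obsolete provisional terms whose ``replaced_by`` names the permanent id,
    which is what annotation migration follows.  Idempotent for a fixed
    request list.  A provisional id colliding with an ordinary term raises
    :class:`TermCollisionError`.
    """
    merged = graph.copy()
    for req in requests:
        pid = req.provisional_id
        existing = merged.terms.get(pid)
        if existing is not None and not existing.is_provisional and not existing.is_placeholder:
            raise TermCollisionError(
                f"provisional id {pid} collides with a non-provisional term"
            )
        resolved = req.permanent_id is not None
        term = Term(
            id=pid,
            label=req.label,
            definition=req.definition or None,
            synonyms=[(s, "RELATED") for s in req.synonyms],
            is_provisional=True,
            is_obsolete=resolved,
            replaced_by=[req.permanent_id] if resolved else [],
        )
        merged.terms[pid] = term
        merged._dag.add_node(pid)
        if not resolved and req.suggested_superclass is not None:
            sup = req.suggested_superclass.id
            if sup in merged.terms and not merged.terms[sup].is_placeholder:
                merged._dag.add_edge(pid, sup)
    merged.check_acyclic()
    return merged


def combine_graphs(*graphs: OntologyGraph) -> OntologyGraph:
    """Union several ontology graphs (disjoint id spaces) into one.

    A real term always wins over a placeholder for the same id.
    """
    out = OntologyGraph()
    for g in graphs:
        for tid, term in g.terms.items():
            existing = out.terms.get(tid)
            if existing is None or (existing.is_placeholder and not term.is_placeholder):
                import copy as _copy

                out.terms[tid] = _copy.deepcopy(term)
                out._dag.add_node(tid)
            elif not existing.is_placeholder and not term.is_placeholder:
                raise DuplicateTermError(f"duplicate term id across graphs: {tid}")
        for child, parent in g.is_a_edges:
            out._dag.add_edge(child, parent)
    out.check_acyclic()
    return out
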