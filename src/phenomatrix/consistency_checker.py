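"""Ontology-aware quality-control rules for EQ annotations.

The rules encode the Entity-Quality annotation guidelines and the semantic
structure of the quality ontology (PATO):

``E_MISSING_ENTITY`` / ``E_MISSING_QUALITY``
    A complete phenotype annotation pairs an entity with a quality.
``E_RELATIONAL_NEEDS_RELATED``
    A *relational* quality relates two entities rather than inhering in one,
    so it requires a related-entity term.
``E_NONRELATIONAL_HAS_RELATED``
    Conversely, a quality defined as inhering in a single entity must not be
    given a related entity.
``E_PROCESS_NEEDS_PROCESS_QUALITY``
    Entities descending from 'biological process' (GO:0008150) may only be
    qualified by descendants of 'process quality' (PATO:0001236).
``W_OBSOLETE_REFERENCE``
    A referenced term is obsolete and should be migrated off.
``W_UNKNOWN_TERM``
    A referenced id is absent from the loaded ontologies (curators routinely
    work against ontology slices, so this is a warning, not a failure).
``N_INCOMPLETE_CHARACTER``
    Some but not all states of a character carry annotations — likely
    unfinished work.  A character with no annotations at all is simply
    untouched and produces no note; states with the reserved missing-data
    symbol are ignored by this census.

Rules are independent: one annotation can accumulate several issues.  The
process rule only fires when a quality term is actually present and known —
a missing quality is already reported as ``E_MISSING_QUALITY`` and firing
both would double-report one mistake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError
from .matrix_model import MISSING_SYMBOL, EQAnnotation, StudyDocument
from .ontology_store import OntologyGraph, TermRef

#: rule id -> severity; definition order fixes report ordering.
RULES: dict[str, str] = {
    "E_MISSING_ENTITY": "error",
    "E_MISSING_QUALITY": "error",
    "E_RELATIONAL_NEEDS_RELATED": "error",
    "E_NONRELATIONAL_HAS_RELATED": "error",
    "E_PROCESS_NEEDS_PROCESS_QUALITY": "error",
    "W_OBSOLETE_REFERENCE": "warning",
    "W_UNKNOWN_TERM": "warning",
    "N_INCOMPLETE_CHARACTER": "note",
}

_RULE_ORDER = {rule: i for i, rule in enumerate(RULES)}


@dataclass
class RuleConfig:
    """Which rules run and which ontology roots anchor the subsumption tests.

    ``relational_quality_root`` has no default: the quality ontology names no
    single canonical id for the relational branch, so the configuration must
    supply one when the relational rules are enabled.
    """

    process_entity_root: str = "GO:0008150"
    process_quality_root: str = "PATO:0001236"
    relational_quality_root: str | None = None
    enabled_rules: set[str] = field(default_factory=lambda: set(RULES))

    def enabled(self, rule_id: str) -> bool:
        return rule_id in self.enabled_rules


@dataclass(frozen=True)
class Issue:
    """One consistency finding at a document location.

    ``location`` is (character_index, state_symbol, annotation_index) for
    annotation-scope rules and (character_index,) for character-scope ones.
    """

    rule_id: str
    severity: str
    location: tuple
    message: str


def _check_roots(graph: OntologyGraph, config: RuleConfig) -> None:
    needs = []
    if config.enabled("E_PROCESS_NEEDS_PROCESS_QUALITY"):
        needs.append(("process_entity_root", config.process_entity_root))
        needs.append(("process_quality_root", config.process_quality_root))
    if config.enabled("E_RELATIONAL_NEEDS_RELATED") or config.enabled(
        "E_NONRELATIONAL_HAS_RELATED"
    ):
        needs.append(("relational_quality_root", config.relational_quality_root))
    for name, root in needs:
        if root is None:
            raise ConfigurationError(f"{name} is required but not configured")
        if root not in graph.terms or graph.terms[root].is_placeholder:
            raise ConfigurationError(
                f"{name} {root!r} is not present in the loaded ontologies"
            )


def check_annotation(
    ann: EQAnnotation,
    graph: OntologyGraph,
    config: RuleConfig,
    location: tuple = (),
) -> list[Issue]:
    """Evaluate every enabled annotation-scope rule on one EQ annotation."""
    _check_roots(graph, config)
    issues: list[Issue] = []

    def emit(rule_id: str, message: str) -> None:
        if config.enabled(rule_id):
            issues.append(Issue(rule_id, RULES[rule_id], location, message))

    def known(ref: TermRef | None) -> bool:
        return (
            ref is not None
            and ref.id in graph.terms
            and not graph.terms[ref.id].is_placeholder
        )

    for role, ref in (
        ("entity", ann.entity),
        ("quality", ann.quality),
        ("related entity", ann.related_entity),
    ):
        if ref is None:
            continue
        if not known(ref):
            emit("W_UNKNOWN_TERM", f"{role} term {ref.id} is not in any loaded ontology")
        elif graph.terms[ref.id].is_obsolete:
            emit("W_OBSOLETE_REFERENCE", f"{role} term {ref.id} is obsolete")

    if ann.entity is None:
        emit("E_MISSING_ENTITY", "annotation has no entity term")
    if ann.quality is None:
        emit("E_MISSING_QUALITY", "annotation has no quality term")

    quality_known = known(ann.quality)
    if quality_known:
        relational = graph.is_descendant(
            ann.quality.id, config.relational_quality_root
        ) if (
            config.enabled("E_RELATIONAL_NEEDS_RELATED")
            or config.enabled("E_NONRELATIONAL_HAS_RELATED")
        ) else False
        if relational and ann.related_entity is None:
            emit(
                "E_RELATIONAL_NEEDS_RELATED",
                f"relational quality {ann.quality.id} requires a related entity",
            )
        if not relational and ann.related_entity is not None:
            emit(
                "E_NONRELATIONAL_HAS_RELATED",
                f"quality {ann.quality.id} is not relational but a related "
                "entity is given",
            )

    if (
        config.enabled("E_PROCESS_NEEDS_PROCESS_QUALITY")
        and known(ann.entity)
        and quality_known
        and graph.is_descendant(ann.entity.id, config.process_entity_root)
        and not graph.is_descendant(ann.quality.id, config.process_quality_root)
    ):
        emit(
            "E_PROCESS_NEEDS_PROCESS_QUALITY",
            f"process entity {ann.entity.id} must be qualified by a descendant "
            f"of {config.process_quality_root}",
        )

    issues.sort(key=lambda i: _RULE_ORDER[i.rule_id])
    return issues


def check_document(
    doc: StudyDocument, graph: OntologyGraph, config: RuleConfig
) -> list[Issue]:
    """Run every rule over a whole document.

    Annotation-scope issues carry (character, state symbol, annotation index)
    locations; each incompletely annotated character additionally yields one
    character-scope ``N_INCOMPLETE_CHARACTER`` note.  Ordering is
    deterministic: by character, state, annotation, then rule.
    """
    _check_roots(graph, config)
    issues: list[Issue] = []
    for ci, char in enumerate(doc.characters):
        for si, state in enumerate(char.states):
            for ai, ann in enumerate(state.annotations):
                for issue in check_annotation(
                    ann, graph, config, location=(ci, state.symbol, ai)
                ):
                    issues.append(issue)

        if config.enabled("N_INCOMPLETE_CHARACTER"):
            real_states = [s for s in char.states if s.symbol != MISSING_SYMBOL]
            annotated = [s for s in real_states if s.annotations]
            if annotated and len(annotated) < len(real_states):
                missing = sorted(
                    s.symbol for s in real_states if not s.annotations
                )
                issues.append(
                    Issue(
                        "N_INCOMPLETE_CHARACTER",
                        RULES["N_INCOMPLETE_CHARACTER"],
                        (ci,),
                        f"character {char.label!r} has unannotated state(s) "
                        f"{', '.join(missing)}",
                    )
                )

    def sort_key(issue: Issue):
        if len(issue.location) == 1:
            return (issue.location[0], 1, 0, 0, _RULE_ORDER[issue.rule_id])
        ci, sym, ai = issue.location
        si = next(
            i for i, s in enumerate(doc.characters[ci].states) if s.symbol == sym
        )
        return (ci, 0, si, ai, _RULE_ORDER[issue.rule_id])

    issues.sort(key=sort_key)
    return issues


def issue_histogram(issues: list[Issue]) -> dict[str, int]:
    """Per-rule issue counts (rules with zero hits included)."""
    hist = {rule: 0 for rule in RULES}
    for issue in issues:
        hist[issue.rule_id] += 1
    return hist


def issues_to_tsv(issues: list[Issue]) -> str:
    """Machine-readable report: one row per issue."""
    lines = ["rule_id\tseverity\tcharacter\tstate\tannotation\tmessage"]
    for issue in issues:
        if len(issue.location) == 1:
            ci, sym, ai = issue.location[0], "", ""
        else:
            ci, sym, ai = issue.location
        lines.append(
            f"{issue.rule_id}\t{issue.severity}\t{ci}\t{sym}\t{ai}\t{issue.message}"
        )
    return "\n".join(lines) + "\n"


def issues_to_text(issues: list[Issue]) -> str:
    """Human-readable report, one line per issue."""
    if not issues:
        return "No issues found.\n"
    out = []
    for issue in issues:
        if len(issue.location) == 1:
            loc = f"character {issue.location[0]}"
        else:
            ci, sym, ai = issue.location
            loc = f"character {ci}, state {sym!r}, annotation {ai}"
        out.append(f"[{issue.severity.upper()}] {issue.rule_id} at {loc}: {issue.message}")
    return "\n".join(out) + "\n"
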