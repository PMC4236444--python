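"""Deterministic synthetic ontologies and annotated matrices with known truth.

Everything here is a pure function of a seed, so every other module can be
exercised offline and the consistency checker can be held to *exact* issue
counts: violations are planted at generation time and their counts recorded
from the plan, never by running the checker.  Generator and checker are thus
two independent routes to the same numbers — their agreement is the point.

The ontologies are synthetic stand-ins: term labels say so, and identifiers
use obviously synthetic ranges (``ANAT:…``, ``TAXON:…``, ``PATO:90…``,
``GO:90…``) except for the two rule-root ids that the checker defaults to,
'biological process' (GO:0008150) and 'process quality' (PATO:0001236),
which must be present under their real ids for the default configuration to
resolve.

Construction rules that make planted counts exact:

* a *clean* annotation pairs a non-obsolete anatomy entity with a plain
  (non-relational, non-process) quality and satisfies every rule;
* the annotated fraction selects whole characters, annotated on every
  state, so no incomplete-character note arises by accident;
* violation annotations are appended to states of already-annotated
  characters (leaving completeness untouched), each constructed to break
  exactly one rule;
* incomplete characters are planted by cleanly annotating exactly one state
  of a previously untouched character.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

from .consistency_checker import RULES, RuleConfig
from .errors import FixtureError
from .matrix_model import Character, EQAnnotation, State, StudyDocument, Taxon
from .ontology_store import OntologyGraph, Term, TermRef, combine_graphs

#: rule roots used by every fixture bundle
PROCESS_ROOT = "GO:0008150"
PROCESS_QUALITY_ROOT = "PATO:0001236"
RELATIONAL_QUALITY_ROOT = "PATO:9000001"
PLAIN_QUALITY_ROOT = "PATO:9000002"
QUALITY_ROOT = "PATO:9000000"
ANATOMY_ROOT = "ANAT:0000001"
TAXONOMY_ROOT = "TAXON:0000001"

#: rules whose violations the generator knows how to plant
INJECTABLE_RULES = (
    "E_MISSING_ENTITY",
    "E_MISSING_QUALITY",
    "E_RELATIONAL_NEEDS_RELATED",
    "E_NONRELATIONAL_HAS_RELATED",
    "E_PROCESS_NEEDS_PROCESS_QUALITY",
    "W_OBSOLETE_REFERENCE",
    "N_INCOMPLETE_CHARACTER",
)


@dataclass
class FixtureSpec:
    seed: int
    n_taxa: int = 8
    n_characters: int = 10
    states_per_character: int = 2
    annotated_fraction: float = 0.8
    injected_violations: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_taxa, self.n_characters, self.states_per_character) < 0:
            raise FixtureError("counts must be >= 0")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise FixtureError("annotated_fraction must be in [0, 1]")
        for rule, count in self.injected_violations.items():
            if rule not in INJECTABLE_RULES:
                raise FixtureError(f"cannot inject violations of {rule}")
            if count < 0:
                raise FixtureError("injected counts must be >= 0")


@dataclass
class FixtureBundle:
    anatomy_graph: OntologyGraph
    quality_graph: OntologyGraph
    process_graph: OntologyGraph
    taxonomy_graph: OntologyGraph
    document: StudyDocument
    expected_issues: dict[str, int]
    rule_config: RuleConfig

    @property
    def combined_graph(self) -> OntologyGraph:
        return combine_graphs(
            self.anatomy_graph,
            self.quality_graph,
            self.process_graph,
            self.taxonomy_graph,
        )


def _tree_graph(
    rng: random.Random,
    root_id: str,
    root_label: str,
    prefix: str,
    start: int,
    n_terms: int,
    min_depth: int,
) -> OntologyGraph:
    """A random rooted DAG: a guaranteed chain of ``min_depth`` plus random
    attachment of the remaining terms, with occasional extra is_a edges."""
    g = OntologyGraph()
    g.add_term(Term(id=root_id, label=root_label))
    ids = [root_id]
    # guaranteed depth
    parent = root_id
    for d in range(min_depth):
        tid = f"{prefix}:{start + d:07d}"
        g.add_term(Term(id=tid, label=f"synthetic {prefix.lower()} term {start + d}"))
        g.add_is_a(tid, parent)
        ids.append(tid)
        parent = tid
    for i in range(min_depth, n_terms - 1):
        tid = f"{prefix}:{start + i:07d}"
        g.add_term(Term(id=tid, label=f"synthetic {prefix.lower()} term {start + i}"))
        g.add_is_a(tid, rng.choice(ids))
        # a second parent now and then keeps the closure a true DAG exercise
        if rng.random() < 0.2 and len(ids) > 1:
            other = rng.choice(ids)
            if other != tid:
                g.add_is_a(tid, other)
        ids.append(tid)
    g.check_acyclic()
    return g


def make_ontologies(
    seed: int,
) -> tuple[OntologyGraph, OntologyGraph, OntologyGraph, OntologyGraph]:
    """Deterministic (anatomy, quality, process, taxonomy) graphs.

    The quality graph holds disjoint relational, process-quality and plain
    branches under one root; the anatomy graph carries two obsolete terms
    (with replacements) so obsolescence rules and migration chains can be
    exercised.
    """
    rng = random.Random(seed)

    anatomy = _tree_graph(rng, ANATOMY_ROOT, "anatomical structure (synthetic)",
                          "ANAT", 2, 22, 4)
    # two obsolete anatomy terms whose replacements are live terms
    live = sorted(anatomy.descendants(ANATOMY_ROOT, include_self=False))
    for i, old in enumerate(("ANAT:0000090", "ANAT:0000091")):
        anatomy.add_term(
            Term(
                id=old,
                label=f"retired synthetic structure {i}",
                is_obsolete=True,
                replaced_by=[live[i]],
            )
        )

    quality = OntologyGraph()
    quality.add_term(Term(id=QUALITY_ROOT, label="quality (synthetic root)"))
    for branch_root, label, start, n in (
        (RELATIONAL_QUALITY_ROOT, "relational quality (synthetic)", 9000010, 5),
        (PROCESS_QUALITY_ROOT, "process quality", 9000020, 5),
        (PLAIN_QUALITY_ROOT, "monadic quality (synthetic)", 9000030, 6),
    ):
        quality.add_term(Term(id=branch_root, label=label))
        quality.add_is_a(branch_root, QUALITY_ROOT)
        for i in range(n - 1):
            tid = f"PATO:{start + i}"
            quality.add_term(Term(id=tid, label=f"synthetic quality {start + i}"))
            quality.add_is_a(tid, branch_root)
    quality.check_acyclic()

    process = OntologyGraph()
    process.add_term(Term(id=PROCESS_ROOT, label="biological process"))
    parents = [PROCESS_ROOT]
    for i in range(6):
        tid = f"GO:{9000100 + i}"
        process.add_term(Term(id=tid, label=f"synthetic process {9000100 + i}"))
        process.add_is_a(tid, rng.choice(parents))
        parents.append(tid)
    process.check_acyclic()

    taxonomy = _tree_graph(rng, TAXONOMY_ROOT, "synthetic taxon root",
                           "TAXON", 2, 12, 3)
    return anatomy, quality, process, taxonomy


def make_rule_config() -> RuleConfig:
    return RuleConfig(relational_quality_root=RELATIONAL_QUALITY_ROOT)


def _branch_members(graph: OntologyGraph, root: str, strict: bool = False) -> list[str]:
    members = graph.descendants(root, include_self=not strict)
    if strict:
        members = members - {root}
    return sorted(members)


def make_bundle(spec: FixtureSpec) -> FixtureBundle:
    """Build a fully annotated document plus its planted issue counts."""
    rng = random.Random(spec.seed)
    anatomy, quality, process, taxonomy = make_ontologies(spec.seed)

    anat_terms = [
        t for t in _branch_members(anatomy, ANATOMY_ROOT) if not anatomy.terms[t].is_obsolete
    ]
    obsolete_terms = sorted(
        t.id for t in anatomy.terms.values() if t.is_obsolete
    )
    plain_qualities = _branch_members(quality, PLAIN_QUALITY_ROOT)
    relational_qualities = _branch_members(quality, RELATIONAL_QUALITY_ROOT)
    process_entities = _branch_members(process, PROCESS_ROOT, strict=True)
    taxon_terms = _branch_members(taxonomy, TAXONOMY_ROOT)

    injections = {rule: spec.injected_violations.get(rule, 0) for rule in INJECTABLE_RULES}

    n_annotated = round(spec.annotated_fraction * spec.n_characters)
    eq_level = sum(v for r, v in injections.items() if r != "N_INCOMPLETE_CHARACTER")
    if eq_level > 0 and n_annotated == 0:
        raise FixtureError(
            "EQ-level violations need at least one annotated character "
            "(annotated_fraction too low)"
        )
    if injections["N_INCOMPLETE_CHARACTER"] > spec.n_characters - n_annotated:
        raise FixtureError(
            "not enough unannotated characters to plant incomplete-character notes"
        )
    if injections["N_INCOMPLETE_CHARACTER"] > 0 and spec.states_per_character < 2:
        raise FixtureError("incomplete characters need >= 2 states")

    def clean_annotation() -> EQAnnotation:
        return EQAnnotation(
            entity=TermRef(rng.choice(anat_terms)),
            quality=TermRef(rng.choice(plain_qualities)),
        )

    taxa = [
        Taxon(
            publication_label=f"Taxon {i + 1}",
            taxonomy_ref=TermRef(rng.choice(taxon_terms)),
        )
        for i in range(spec.n_taxa)
    ]
    characters = [
        Character(
            label=f"Character {j + 1}",
            states=[
                State(symbol=str(k), label=f"state {k} of character {j + 1}")
                for k in range(spec.states_per_character)
            ],
        )
        for j in range(spec.n_characters)
    ]
    doc = StudyDocument(
        taxa=taxa,
        characters=characters,
        source_metadata={
            "citation": f"Synthetic study (fixture seed {spec.seed})",
            "curator": "phenomatrix-fixtures",
        },
    )

    for ti in range(spec.n_taxa):
        for ci in range(spec.n_characters):
            if rng.random() < 0.9:
                symbols = {rng.choice(characters[ci].states).symbol}
                if spec.states_per_character > 1 and rng.random() < 0.05:
                    symbols.add(rng.choice(characters[ci].states).symbol)
                doc.set_cell(ti, ci, symbols)

    char_order = list(range(spec.n_characters))
    rng.shuffle(char_order)
    annotated_chars = sorted(char_order[:n_annotated])
    untouched_chars = sorted(char_order[n_annotated:])

    for ci in annotated_chars:
        for state in characters[ci].states:
            doc.annotate_state(ci, state.symbol, clean_annotation())

    # --- plant violations, recording ground truth from the plan -------------
    def random_slot() -> tuple[int, str]:
        ci = rng.choice(annotated_chars)
        return ci, rng.choice(characters[ci].states).symbol

    def plant(rule: str) -> None:
        ci, sym = random_slot()
        if rule == "E_MISSING_ENTITY":
            ann = EQAnnotation(quality=TermRef(rng.choice(plain_qualities)))
        elif rule == "E_MISSING_QUALITY":
            ann = EQAnnotation(entity=TermRef(rng.choice(anat_terms)))
        elif rule == "E_RELATIONAL_NEEDS_RELATED":
            ann = EQAnnotation(
                entity=TermRef(rng.choice(anat_terms)),
                quality=TermRef(rng.choice(relational_qualities)),
            )
        elif rule == "E_NONRELATIONAL_HAS_RELATED":
            ann = EQAnnotation(
                entity=TermRef(rng.choice(anat_terms)),
                quality=TermRef(rng.choice(plain_qualities)),
                related_entity=TermRef(rng.choice(anat_terms)),
            )
        elif rule == "E_PROCESS_NEEDS_PROCESS_QUALITY":
            ann = EQAnnotation(
                entity=TermRef(rng.choice(process_entities)),
                quality=TermRef(rng.choice(plain_qualities)),
            )
        elif rule == "W_OBSOLETE_REFERENCE":
            ann = EQAnnotation(
                entity=TermRef(rng.choice(obsolete_terms)),
                quality=TermRef(rng.choice(plain_qualities)),
            )
        else:  # pragma: no cover - guarded by INJECTABLE_RULES
            raise FixtureError(rule)
        doc.annotate_state(ci, sym, ann)

    for rule in INJECTABLE_RULES:
        if rule == "N_INCOMPLETE_CHARACTER":
            continue
        for _ in range(injections[rule]):
            plant(rule)

    for k in range(injections["N_INCOMPLETE_CHARACTER"]):
        ci = untouched_chars[k]
        doc.annotate_state(ci, characters[ci].states[0].symbol, clean_annotation())

    expected = {rule: 0 for rule in RULES}
    expected.update(injections)
    return FixtureBundle(
        anatomy_graph=anatomy,
        quality_graph=quality,
        process_graph=process,
        taxonomy_graph=taxonomy,
        document=doc,
        expected_issues=expected,
        rule_config=make_rule_config(),
    )


def write_bundle(bundle: FixtureBundle, outdir: str) -> dict[str, str]:
    """Write a bundle to disk: four OBO files, the NeXML matrix, the rule
    configuration (JSON) and the expected-issues TSV.  Returns the paths."""
    import json

    from .nexml_io import write_nexml
    from .ontology_store import serialize_obo

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, graph in (
        ("anatomy", bundle.anatomy_graph),
        ("quality", bundle.quality_graph),
        ("process", bundle.process_graph),
        ("taxonomy", bundle.taxonomy_graph),
    ):
        path = os.path.join(outdir, f"{name}.obo")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(serialize_obo(graph))
        paths[name] = path

    matrix_path = os.path.join(outdir, "matrix.xml")
    write_nexml(bundle.document, matrix_path)
    paths["matrix"] = matrix_path

    config_path = os.path.join(outdir, "config.json")
    with open(config_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "rule_config": {
                    "process_entity_root": bundle.rule_config.process_entity_root,
                    "process_quality_root": bundle.rule_config.process_quality_root,
                    "relational_quality_root": bundle.rule_config.relational_quality_root,
                    "enabled_rules": sorted(bundle.rule_config.enabled_rules),
                },
                "ontologies": [paths[n] for n in ("anatomy", "quality", "process", "taxonomy")],
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    paths["config"] = config_path

    expected_path = os.path.join(outdir, "expected_issues.tsv")
    with open(expected_path, "w", encoding="utf-8") as fh:
        fh.write("rule_id\tcount\n")
        for rule in RULES:
            fh.write(f"{rule}\t{bundle.expected_issues[rule]}\n")
    paths["expected"] = expected_path
    return paths
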