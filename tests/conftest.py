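"""Shared test fixtures and independent oracles.

The oracles here are deliberately naive (fixed-point closure, random DAGs,
random documents) and independent of the library code paths they check.
"""

from __future__ import annotations

import random

import pytest

from phenomatrix.matrix_model import (
    Character,
    EQAnnotation,
    State,
    StudyDocument,
    Taxon,
)
from phenomatrix.ontology_store import OntologyGraph, Term, TermRef, parse_obo

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: X:1
name: A

[Term]
id: X:2
name: B
is_a: X:1

[Term]
id: X:3
name: C
is_a: X:2
"""


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """C is_a B is_a A."""
    return parse_obo(CHAIN_OBO)


def random_dag(
    rng: random.Random, n_nodes: int, edge_prob: float, obsolete_frac: float = 0.0
) -> OntologyGraph:
    """A random DAG: node Ni may be a child of any Nj with j < i."""
    g = OntologyGraph()
    for i in range(n_nodes):
        g.add_term(Term(id=f"N:{i}", label=f"node {i}",
                        is_obsolete=rng.random() < obsolete_frac))
    for i in range(1, n_nodes):
        for j in range(i):
            if rng.random() < edge_prob:
                g.add_is_a(f"N:{i}", f"N:{j}")
    g.check_acyclic()
    return g


def naive_descendants(
    graph: OntologyGraph, root: str, include_self: bool = True
) -> set[str]:
    """Reflexive-transitive closure by repeated edge relaxation.

    Edges whose child is obsolete do not participate, and obsolete terms
    never appear in a result.
    """
    obsolete = {tid for tid, t in graph.terms.items() if t.is_obsolete}
    desc = {tid: {tid} for tid in graph.terms}
    changed = True
    while changed:
        changed = False
        for child, parent in graph.is_a_edges:
            if child in obsolete:
                continue
            if not desc[child] <= desc[parent]:
                desc[parent] |= desc[child]
                changed = True
    out = desc[root] - obsolete
    if not include_self:
        out.discard(root)
    return out


_WORDS = ["femur", "curved", "dorsal fin", "élan", "absent", "round", "fused", ""]


def random_document(rng: random.Random) -> StudyDocument:
    """A random but serializable study document.

    Exercises optional fields (comments, cached labels, related entities),
    polymorphic and sparse cells, the reserved "?" state, and both CURIE and
    URI term ids.
    """
    def term_ref() -> TermRef:
        if rng.random() < 0.2:
            tid = f"http://example.org/provisional/{rng.randrange(10**6)}"
        else:
            tid = f"{rng.choice(['ANAT', 'PATO', 'GO'])}:{rng.randrange(10**7):07d}"
        label = rng.choice(_WORDS[:-1]) if rng.random() < 0.5 else None
        return TermRef(tid, cached_label=label)

    def annotation() -> EQAnnotation:
        shape = rng.random()
        entity = term_ref() if shape < 0.9 else None
        quality = term_ref() if (shape > 0.1) else None
        if entity is None and quality is None:
            entity = term_ref()
        return EQAnnotation(
            entity=entity,
            quality=quality,
            related_entity=term_ref() if rng.random() < 0.3 else None,
            comment=rng.choice(_WORDS) if rng.random() < 0.4 else None,
        )

    n_taxa = rng.randrange(0, 6)
    n_chars = rng.randrange(0, 5)
    taxa = [
        Taxon(
            publication_label=f"Taxon {i} {rng.choice(_WORDS[:-1])}",
            taxonomy_ref=term_ref() if rng.random() < 0.6 else None,
        )
        for i in range(n_taxa)
    ]
    characters = []
    for j in range(n_chars):
        n_states = rng.randrange(1, 4)
        states = [
            State(
                symbol=str(k),
                label=rng.choice(_WORDS),
                annotations=[annotation() for _ in range(rng.randrange(0, 3))],
            )
            for k in range(n_states)
        ]
        if rng.random() < 0.3:
            states.append(State(symbol="?", label="missing"))
        characters.append(Character(label=f"Character {j}", states=states))

    doc = StudyDocument(taxa=taxa, characters=characters)
    for ti in range(n_taxa):
        for ci in range(n_chars):
            if rng.random() < 0.6:
                syms = {rng.choice(characters[ci].states).symbol}
                if rng.random() < 0.2:
                    syms.add(rng.choice(characters[ci].states).symbol)
                doc.set_cell(ti, ci, syms)
    if rng.random() < 0.7:
        doc.source_metadata["citation"] = f"Fictitious et al. {rng.randrange(1990, 2020)}"
    if rng.random() < 0.3:
        doc.source_metadata["curator"] = "tester"
    return doc
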