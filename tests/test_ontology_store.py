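"""Ontology graph: OBO parsing, subsumption, replacement resolution."""

import random

import pytest

from phenomatrix.errors import (
    DanglingReplacementError,
    DuplicateTermError,
    MissingTermError,
    OboParseError,
    OntologyCycleError,
    ReplacementCycleError,
    TermCollisionError,
)
from phenomatrix.ontology_store import (
    ReplacementAmbiguityWarning,
    Term,
    TermRef,
    merge_provisional,
    parse_obo,
    resolve_replacement,
    serialize_obo,
)
from phenomatrix.orb_broker import ProvisionalRequest

from conftest import CHAIN_OBO, naive_descendants, random_dag


class TestParseObo:
    def test_three_stanza_chain(self, chain_graph):
        assert set(chain_graph.terms) == {"X:1", "X:2", "X:3"}
        assert chain_graph.is_a_edges == {("X:2", "X:1"), ("X:3", "X:2")}
        assert chain_graph.terms["X:2"].label == "B"

    def test_obsolete_and_replaced_by(self):
        g = parse_obo(
            "[Term]\nid: X:1\nis_obsolete: true\nreplaced_by: X:2\n\n"
            "[Term]\nid: X:2\n"
        )
        assert g.terms["X:1"].is_obsolete
        assert g.terms["X:1"].replaced_by == ["X:2"]

    def test_duplicate_id_raises(self):
        with pytest.raises(DuplicateTermError, match="X:1"):
            parse_obo("[Term]\nid: X:1\n\n[Term]\nid: X:1\n")

    def test_is_a_cycle_raises(self):
        with pytest.raises(OntologyCycleError) as exc:
            parse_obo("[Term]\nid: X:1\nis_a: X:2\n\n[Term]\nid: X:2\nis_a: X:1\n")
        assert set(exc.value.cycle) >= {"X:1", "X:2"}

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(OboParseError) as exc:
            parse_obo("[Term]\nid: X:1\nthis is not a tag line\n")
        assert exc.value.line == 3

    def test_stanza_without_id_raises(self):
        with pytest.raises(OboParseError):
            parse_obo("[Term]\nname: nameless\n")

    def test_dangling_parent_kept_as_placeholder(self):
        g = parse_obo("[Term]\nid: X:1\nis_a: X:99\n")
        assert g.terms["X:99"].is_placeholder
        assert g.placeholder_ids() == ["X:99"]

    def test_unknown_tags_and_stanzas_ignored(self):
        g = parse_obo(
            "format-version: 1.4\n\n[Typedef]\nid: part_of\n\n"
            "[Term]\nid: X:1\nxref: FOO:1\ncomment: hello\n"
        )
        assert set(g.terms) == {"X:1"}

    def test_def_and_synonyms_parsed(self):
        g = parse_obo(
            '[Term]\nid: X:1\ndef: "a \\"quoted\\" def" [PMID:1]\n'
            'synonym: "alt name" EXACT []\nsynonym: "loose" []\n'
        )
        t = g.terms["X:1"]
        assert t.definition == 'a "quoted" def'
        assert ("alt name", "EXACT") in t.synonyms
        assert ("loose", "RELATED") in t.synonyms

    def test_trailing_comment_stripped(self):
        g = parse_obo("[Term]\nid: X:1\n\n[Term]\nid: X:2\nis_a: X:1 ! the root\n")
        assert g.is_a_edges == {("X:2", "X:1")}


class TestDescendants:
    def test_chain_from_root(self, chain_graph):
        assert chain_graph.descendants("X:1", include_self=True) == {"X:1", "X:2", "X:3"}

    def test_leaf_has_no_descendants(self, chain_graph):
        assert chain_graph.descendants("X:3", include_self=False) == set()

    def test_unknown_root_raises(self, chain_graph):
        with pytest.raises(MissingTermError):
            chain_graph.descendants("X:99")

    def test_obsolete_terms_excluded_and_block_paths(self):
        g = parse_obo(
            "[Term]\nid: X:1\n\n[Term]\nid: X:2\nis_a: X:1\nis_obsolete: true\n\n"
            "[Term]\nid: X:3\nis_a: X:2\n"
        )
        # the retired branch neither appears nor transmits reachability
        assert g.descendants("X:1") == {"X:1"}

    def test_seed7_dag_matches_naive_closure(self):
        g = random_dag(random.Random(7), n_nodes=20, edge_prob=0.15)
        for node in g.terms:
            for include_self in (True, False):
                assert g.descendants(node, include_self=include_self) == \
                    naive_descendants(g, node, include_self=include_self), node

    def test_is_descendant_direction(self, chain_graph):
        assert chain_graph.is_descendant("X:3", "X:1")
        assert not chain_graph.is_descendant("X:1", "X:3")

    def test_is_descendant_agrees_with_descendants_on_random_pairs(self):
        rng = random.Random(7)
        g = random_dag(rng, n_nodes=20, edge_prob=0.15)
        nodes = sorted(g.terms)
        for _ in range(100):
            term, root = rng.choice(nodes), rng.choice(nodes)
            assert g.is_descendant(term, root) == (
                term in naive_descendants(g, root, include_self=True)
            )


class TestResolveReplacement:
    def _graph(self, text):
        return parse_obo(text)

    def test_chain_following(self):
        g = self._graph(
            "[Term]\nid: A:1\nis_obsolete: true\nreplaced_by: A:2\n\n"
            "[Term]\nid: A:2\nis_obsolete: true\nreplaced_by: A:3\n\n"
            "[Term]\nid: A:3\n"
        )
        assert resolve_replacement(g, "A:1") == "A:3"

    def test_identity_without_replacement(self, chain_graph):
        assert resolve_replacement(chain_graph, "X:2") == "X:2"

    def test_cycle_raises(self):
        g = self._graph(
            "[Term]\nid: A:1\nreplaced_by: A:2\n\n[Term]\nid: A:2\nreplaced_by: A:1\n"
        )
        with pytest.raises(ReplacementCycleError) as exc:
            resolve_replacement(g, "A:1")
        assert exc.value.visited[:2] == ["A:1", "A:2"]

    def test_dangling_target_raises_unless_allowed(self):
        g = self._graph("[Term]\nid: A:1\nreplaced_by: B:9\n")
        with pytest.raises(DanglingReplacementError, match="B:9"):
            resolve_replacement(g, "A:1")
        assert resolve_replacement(g, "A:1", allow_dangling=True) == "B:9"

    def test_multiple_targets_follow_first_with_warning(self):
        g = self._graph(
            "[Term]\nid: A:1\nreplaced_by: A:2\nreplaced_by: A:3\n\n"
            "[Term]\nid: A:2\n\n[Term]\nid: A:3\n"
        )
        with pytest.warns(ReplacementAmbiguityWarning):
            assert resolve_replacement(g, "A:1") == "A:2"

    def test_idempotent(self):
        g = self._graph(
            "[Term]\nid: A:1\nreplaced_by: A:2\n\n[Term]\nid: A:2\n"
        )
        once = resolve_replacement(g, "A:1")
        assert resolve_replacement(g, once) == once


class TestMergeProvisional:
    def _request(self, pid, superclass=None, permanent=None):
        return ProvisionalRequest(
            provisional_id=pid,
            label="new structure",
            definition="a synthetic provisional concept",
            suggested_superclass=superclass,
            submitter="team",
            created="2020-01-01T00:00:00+00:00",
            permanent_id=permanent,
        )

    def test_pending_request_adds_term_and_edge(self, chain_graph):
        merged = merge_provisional(
            chain_graph, [self._request("http://p/1", superclass=TermRef("X:1"))]
        )
        assert merged.terms["http://p/1"].is_provisional
        assert ("http://p/1", "X:1") in merged.is_a_edges
        assert len(merged.terms) == len(chain_graph.terms) + 1

    def test_resolved_request_becomes_obsolete_with_replaced_by(self, chain_graph):
        merged = merge_provisional(
            chain_graph, [self._request("http://p/1", permanent="X:2")]
        )
        t = merged.terms["http://p/1"]
        assert t.is_obsolete and t.replaced_by == ["X:2"]

    def test_empty_request_list_is_identity(self, chain_graph):
        assert merge_provisional(chain_graph, []) == chain_graph

    def test_idempotent_on_same_requests(self, chain_graph):
        reqs = [self._request("http://p/1", superclass=TermRef("X:2"))]
        once = merge_provisional(chain_graph, reqs)
        assert merge_provisional(once, reqs) == once

    def test_collision_with_ordinary_term_raises(self, chain_graph):
        with pytest.raises(TermCollisionError):
            merge_provisional(chain_graph, [self._request("X:1")])

    def test_provisional_participates_in_subsumption(self, chain_graph):
        merged = merge_provisional(
            chain_graph, [self._request("http://p/1", superclass=TermRef("X:2"))]
        )
        assert merged.is_descendant("http://p/1", "X:1")


class TestSerializeRoundTrip:
    def test_parse_serialize_parse_identity(self):
        for seed in range(5):
            g = random_dag(random.Random(seed), 15, 0.2, obsolete_frac=0.1)
            g2 = parse_obo(serialize_obo(g))
            assert g2 == g

    def test_serialize_deterministic(self, chain_graph):
        assert serialize_obo(chain_graph) == serialize_obo(chain_graph)

    def test_round_trip_preserves_metadata(self):
        g = parse_obo(CHAIN_OBO)
        g.terms["X:1"].definition = "the root"
        g.terms["X:1"].synonyms = [("origin", "EXACT")]
        g.terms["X:3"].is_obsolete = True
        g.terms["X:3"].replaced_by = ["X:2"]
        assert parse_obo(serialize_obo(g)) == g

    def test_agrees_with_obonet_reference_parser(self):
        obonet = pytest.importorskip("obonet")
        import io

        from phenomatrix.fixtures import make_ontologies

        anatomy, _q, _p, _t = make_ontologies(seed=4)
        text = serialize_obo(anatomy)
        ref = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
        ours_live = {t.id for t in anatomy.terms.values() if not t.is_placeholder}
        assert set(ref.nodes) == ours_live
        ref_edges = {
            (c, p) for c, p, k in ref.edges(keys=True) if k == "is_a"
        }
        assert ref_edges == anatomy.is_a_edges
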