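"""Annotation QC rules: per-rule behavior, exactness against planted truth."""

import pytest

from phenomatrix.consistency_checker import (
    RULES,
    Issue,
    RuleConfig,
    check_annotation,
    check_document,
    issue_histogram,
    issues_to_tsv,
)
from phenomatrix.errors import ConfigurationError
from phenomatrix.fixtures import (
    PLAIN_QUALITY_ROOT,
    PROCESS_QUALITY_ROOT,
    PROCESS_ROOT,
    RELATIONAL_QUALITY_ROOT,
    FixtureSpec,
    make_bundle,
    make_ontologies,
    make_rule_config,
)
from phenomatrix.matrix_model import Character, EQAnnotation, State, StudyDocument
from phenomatrix.ontology_store import TermRef, combine_graphs


@pytest.fixture(scope="module")
def graph():
    return combine_graphs(*make_ontologies(seed=0))


@pytest.fixture(scope="module")
def config():
    return make_rule_config()


def rules_of(issues):
    return [i.rule_id for i in issues]


class TestAnnotationRules:
    def test_missing_quality(self, graph, config):
        ann = EQAnnotation(entity=TermRef("ANAT:0000002"))
        assert rules_of(check_annotation(ann, graph, config)) == ["E_MISSING_QUALITY"]

    def test_missing_entity(self, graph, config):
        ann = EQAnnotation(quality=TermRef(PLAIN_QUALITY_ROOT))
        assert rules_of(check_annotation(ann, graph, config)) == ["E_MISSING_ENTITY"]

    def test_process_entity_with_non_process_quality(self, graph, config):
        ann = EQAnnotation(
            entity=TermRef("GO:9000100"), quality=TermRef(PLAIN_QUALITY_ROOT)
        )
        assert rules_of(check_annotation(ann, graph, config)) == [
            "E_PROCESS_NEEDS_PROCESS_QUALITY"
        ]

    def test_process_entity_with_process_quality_is_clean(self, graph, config):
        ann = EQAnnotation(
            entity=TermRef("GO:9000100"), quality=TermRef(PROCESS_QUALITY_ROOT)
        )
        assert check_annotation(ann, graph, config) == []

    def test_relational_quality_without_related_entity(self, graph, config):
        ann = EQAnnotation(
            entity=TermRef("ANAT:0000002"), quality=TermRef(RELATIONAL_QUALITY_ROOT)
        )
        assert rules_of(check_annotation(ann, graph, config)) == [
            "E_RELATIONAL_NEEDS_RELATED"
        ]
        ann.related_entity = TermRef("ANAT:0000003")
        assert check_annotation(ann, graph, config) == []

    def test_nonrelational_quality_with_related_entity(self, graph, config):
        ann = EQAnnotation(
            entity=TermRef("ANAT:0000002"),
            quality=TermRef(PLAIN_QUALITY_ROOT),
            related_entity=TermRef("ANAT:0000003"),
        )
        assert rules_of(check_annotation(ann, graph, config)) == [
            "E_NONRELATIONAL_HAS_RELATED"
        ]

    def test_obsolete_reference_warns(self, graph, config):
        ann = EQAnnotation(
            entity=TermRef("ANAT:0000090"), quality=TermRef(PLAIN_QUALITY_ROOT)
        )
        assert rules_of(check_annotation(ann, graph, config)) == [
            "W_OBSOLETE_REFERENCE"
        ]

    def test_unknown_term_warns_without_crash(self, graph, config):
        ann = EQAnnotation(
            entity=TermRef("NOPE:1"), quality=TermRef(PLAIN_QUALITY_ROOT)
        )
        assert rules_of(check_annotation(ann, graph, config)) == ["W_UNKNOWN_TERM"]

    def test_rules_are_independent_and_stack(self, graph, config):
        # relational quality, no related entity, and the entity is obsolete
        ann = EQAnnotation(
            entity=TermRef("ANAT:0000090"),
            quality=TermRef(RELATIONAL_QUALITY_ROOT),
        )
        assert set(rules_of(check_annotation(ann, graph, config))) == {
            "W_OBSOLETE_REFERENCE",
            "E_RELATIONAL_NEEDS_RELATED",
        }

    def test_severities_follow_prefix(self, graph, config):
        ann = EQAnnotation(entity=TermRef("ANAT:0000090"))
        issues = check_annotation(ann, graph, config)
        severities = {i.rule_id[0]: i.severity for i in issues}
        assert severities.get("E") == "error" and severities.get("W") == "warning"

    def test_disabled_rule_is_silent(self, graph):
        cfg = RuleConfig(
            relational_quality_root=RELATIONAL_QUALITY_ROOT,
            enabled_rules=set(RULES) - {"E_MISSING_QUALITY"},
        )
        ann = EQAnnotation(entity=TermRef("ANAT:0000002"))
        assert check_annotation(ann, graph, cfg) == []

    def test_missing_configured_root_is_configuration_error(self, graph):
        cfg = RuleConfig(relational_quality_root="PATO:404")
        with pytest.raises(ConfigurationError):
            check_annotation(EQAnnotation(entity=TermRef("ANAT:0000002")), graph, cfg)

    def test_unconfigured_relational_root_is_configuration_error(self, graph):
        with pytest.raises(ConfigurationError):
            check_annotation(
                EQAnnotation(entity=TermRef("ANAT:0000002")), graph, RuleConfig()
            )


class TestDocumentRules:
    def _doc(self):
        return StudyDocument(
            characters=[
                Character("c1", [State("0"), State("1")]),
                Character("c2", [State("0"), State("1"), State("?")]),
            ]
        )

    def test_mixed_character_yields_exactly_one_incomplete_note(self, graph, config):
        doc = self._doc()
        doc.annotate_state(
            0, "0", EQAnnotation(entity=TermRef("ANAT:0000002"),
                                 quality=TermRef(PLAIN_QUALITY_ROOT))
        )
        issues = check_document(doc, graph, config)
        assert rules_of(issues) == ["N_INCOMPLETE_CHARACTER"]
        assert issues[0].location == (0,)

    def test_unannotated_character_emits_nothing(self, graph, config):
        assert check_document(self._doc(), graph, config) == []

    def test_missing_symbol_state_excluded_from_census(self, graph, config):
        doc = self._doc()
        for sym in ("0", "1"):  # both real states of c2 annotated; "?" is not
            doc.annotate_state(
                1, sym, EQAnnotation(entity=TermRef("ANAT:0000002"),
                                     quality=TermRef(PLAIN_QUALITY_ROOT))
            )
        assert check_document(doc, graph, config) == []

    def test_document_restriction_equals_check_annotation(self, graph, config):
        bundle = make_bundle(FixtureSpec(seed=5, injected_violations={
            "E_MISSING_QUALITY": 2, "E_NONRELATIONAL_HAS_RELATED": 1}))
        doc = bundle.document
        doc_issues = check_document(doc, graph, config)
        for ci, sym, ai, ann in doc.iter_annotations():
            expected = check_annotation(ann, graph, config, location=(ci, sym, ai))
            got = [i for i in doc_issues if i.location == (ci, sym, ai)]
            assert got == expected

    def test_monotonicity_adding_annotation_keeps_existing_issues(self, graph, config):
        doc = self._doc()
        doc.annotate_state(0, "0", EQAnnotation(entity=TermRef("ANAT:0000002")))
        before = set(check_document(doc, graph, config))
        doc.annotate_state(1, "1", EQAnnotation(quality=TermRef(PLAIN_QUALITY_ROOT)))
        after = set(check_document(doc, graph, config))
        assert before <= after

    def test_ordering_is_deterministic(self, graph, config):
        bundle = make_bundle(FixtureSpec(seed=9, injected_violations={
            "E_MISSING_QUALITY": 3, "W_OBSOLETE_REFERENCE": 2}))
        a = check_document(bundle.document, graph, config)
        b = check_document(bundle.document, graph, config)
        assert a == b
        keys = [(i.location[0], i.location[1:] or ("~",)) for i in a]
        assert keys == sorted(keys, key=lambda k: (k[0], str(k[1])))


class TestExactnessAgainstPlantedTruth:
    @pytest.mark.parametrize("seed", range(20))
    def test_histogram_equals_injected_counts(self, seed):
        rng_injections = {
            "E_MISSING_ENTITY": seed % 3,
            "E_MISSING_QUALITY": (seed + 1) % 4,
            "E_RELATIONAL_NEEDS_RELATED": seed % 2,
            "E_NONRELATIONAL_HAS_RELATED": (seed + 2) % 3,
            "E_PROCESS_NEEDS_PROCESS_QUALITY": seed % 2,
            "W_OBSOLETE_REFERENCE": (seed + 1) % 2,
            "N_INCOMPLETE_CHARACTER": seed % 3,
        }
        bundle = make_bundle(FixtureSpec(
            seed=seed, n_taxa=6, n_characters=12, states_per_character=3,
            annotated_fraction=0.7, injected_violations=rng_injections,
        ))
        issues = check_document(
            bundle.document, bundle.combined_graph, bundle.rule_config
        )
        assert issue_histogram(issues) == bundle.expected_issues

    def test_clean_document_has_no_issues(self):
        bundle = make_bundle(FixtureSpec(seed=13, injected_violations={}))
        assert check_document(
            bundle.document, bundle.combined_graph, bundle.rule_config
        ) == []


def test_tsv_report_shape():
    issue = Issue("E_MISSING_QUALITY", "error", (2, "1", 0), "msg")
    note = Issue("N_INCOMPLETE_CHARACTER", "note", (3,), "msg2")
    tsv = issues_to_tsv([issue, note])
    lines = tsv.strip().split("\n")
    assert lines[0].split("\t") == [
        "rule_id", "severity", "character", "state", "annotation", "message"
    ]
    assert lines[1].split("\t")[:3] == ["E_MISSING_QUALITY", "error", "2"]
    assert lines[2].split("\t")[2:5] == ["3", "", ""]
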