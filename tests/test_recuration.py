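"""Re-curation quality gate: required annotations and the confidence
state machine."""

import random

import pytest

from kgcurate.model import KnowledgeGraph, Relation
from kgcurate.recuration import (
    Assessment,
    ConfidenceLevel,
    apply_action,
    apply_label_mapping,
    check_required_annotations,
    confidence_of,
    delete_with_related,
    load_label_mapping,
    second_curator_decision,
    third_curator_review,
)

from conftest import make_edge, make_protein


def edge_with_confidence(label=None, subj="A", obj="B", evidence="ev", citation="1"):
    annotations = {} if label is None else {"Confidence": label}
    return make_edge(make_protein(subj), make_protein(obj), Relation.INCREASES,
                     evidence=evidence, citation=citation, **annotations)


class TestOrdinalScale:
    def test_total_order(self):
        assert (
            ConfidenceLevel.NONE
            < ConfidenceLevel.LOW
            < ConfidenceLevel.MEDIUM
            < ConfidenceLevel.HIGH
            < ConfidenceLevel.VERY_HIGH
        )

    def test_labels_round_trip_verbatim(self):
        for level in ConfidenceLevel:
            assert ConfidenceLevel.from_label(level.label) is level
        assert ConfidenceLevel.VERY_HIGH.label == "Very High"


class TestRequiredAnnotations:
    def test_fully_annotated_graph_clean(self):
        kg = KnowledgeGraph()
        for i in range(3):
            kg.add_edge(edge_with_confidence("High", subj=f"S{i}"))
        assert check_required_annotations(kg, ["Confidence"]) == []

    def test_single_missing_edge_named(self):
        kg = KnowledgeGraph()
        kg.add_edge(edge_with_confidence("High", subj="S0"))
        kg.add_edge(edge_with_confidence("High", subj="S1"))
        kg.add_edge(edge_with_confidence(None, subj="NAKED", citation="77"))
        violations = check_required_annotations(kg, ["Confidence"])
        assert len(violations) == 1
        assert "NAKED" in violations[0].statement
        assert violations[0].citation == "77"
        assert violations[0].missing == ("Confidence",)

    def test_no_required_annotations_always_clean(self, random_kg):
        assert check_required_annotations(random_kg, []) == []

    def test_count_matches_brute_force(self, random_kg):
        rng = random.Random(9)
        kg = KnowledgeGraph()
        expected = 0
        for edge in random_kg.edges():
            if rng.random() < 0.5:
                edge.annotations["Confidence"] = "High"
            else:
                expected += 1
            kg.add_edge(edge)
        assert len(check_required_annotations(kg, ["Confidence"])) == expected


class TestSecondCurator:
    def test_assertable_sets_high(self):
        action = second_curator_decision(edge_with_confidence(), Assessment.ASSERTABLE)
        assert action.action == "set_confidence"
        assert action.confidence is ConfidenceLevel.HIGH

    def test_unclear_sets_low(self):
        action = second_curator_decision(edge_with_confidence(), Assessment.UNCLEAR)
        assert action.confidence is ConfidenceLevel.LOW

    def test_wrong_fixed_replaces_and_sets_medium(self):
        fixed = edge_with_confidence(subj="A", obj="C")
        action = second_curator_decision(edge_with_confidence(), Assessment.WRONG_FIXED, replacement=fixed)
        assert action.action == "replace"
        assert action.confidence is ConfidenceLevel.MEDIUM
        with pytest.raises(ValueError):
            second_curator_decision(edge_with_confidence(), Assessment.WRONG_FIXED)

    def test_nonsense_deletes_edge_and_same_evidence_statements(self):
        kg = KnowledgeGraph()
        doomed = edge_with_confidence(evidence="nonsense blob", subj="A")
        sibling = edge_with_confidence(evidence="nonsense blob", subj="Z")
        survivor = edge_with_confidence(evidence="fine sentence", subj="B")
        for e in (doomed, sibling, survivor):
            kg.add_edge(e)
        action = second_curator_decision(doomed, Assessment.NONSENSE)
        assert action.action == "delete"
        apply_action(kg, action)
        remaining = {e.evidence_text for e in kg.edges()}
        assert remaining == {"fine sentence"}

    def test_very_high_edge_is_noop_with_warning(self):
        action = second_curator_decision(edge_with_confidence("Very High"), Assessment.ASSERTABLE)
        assert action.action == "noop"
        assert "Very High" in action.note

    def test_applied_decisions_yield_predicted_confidence_multiset(self):
        rng = random.Random(5)
        kg = KnowledgeGraph()
        edges = [edge_with_confidence(subj=f"S{i}", evidence=f"e{i}") for i in range(20)]
        for e in edges:
            kg.add_edge(e)
        assessments = [rng.choice(list(Assessment)) for _ in edges]
        expected = []
        for edge, assessment in zip(edges, assessments):
            replacement = edge_with_confidence(subj=edge.subject.identifier, obj="R", evidence=edge.evidence_text) \
                if assessment is Assessment.WRONG_FIXED else None
            apply_action(kg, second_curator_decision(edge, assessment, replacement=replacement))
            if assessment is not Assessment.NONSENSE:
                expected.append(
                    {
                        Assessment.UNCLEAR: "Low",
                        Assessment.WRONG_FIXED: "Medium",
                        Assessment.ASSERTABLE: "High",
                    }[assessment]
                )
        observed = sorted(e.annotations.get("Confidence", "") for e in kg.edges())
        assert observed == sorted(expected)


class TestThirdCurator:
    @pytest.mark.parametrize("label", ["Medium", "High"])
    def test_agreement_promotes_to_very_high(self, label):
        action = third_curator_review(edge_with_confidence(label), agree=True)
        assert action.confidence is ConfidenceLevel.VERY_HIGH

    def test_disagreement_leaves_confidence_pending(self):
        edge = edge_with_confidence("High")
        action = third_curator_review(edge, agree=False)
        assert action.action == "fix_pending"
        kg = KnowledgeGraph()
        kg.add_edge(edge)
        apply_action(kg, action)
        assert confidence_of(next(kg.edges())) is ConfidenceLevel.HIGH

    @pytest.mark.parametrize("label", [None, "None", "Low", "Very High"])
    def test_ineligible_confidence_rejected(self, label):
        with pytest.raises(ValueError):
            third_curator_review(edge_with_confidence(label), agree=True)

    def test_very_high_only_reachable_through_review(self):
        """Random action sequences: an edge ends Very High only if the last
        effective transition was third-curator agreement from Medium/High."""
        rng = random.Random(11)
        for trial in range(300):
            kg = KnowledgeGraph()
            edge = edge_with_confidence(subj=f"T{trial}")
            kg.add_edge(edge)
            promoted_legally = False
            for _ in range(rng.randint(1, 6)):
                current = next(iter(kg.edges()), None)
                if current is None:
                    break
                if rng.random() < 0.5:
                    assessment = rng.choice(list(Assessment))
                    replacement = edge_with_confidence(subj="R", evidence=current.evidence_text) \
                        if assessment is Assessment.WRONG_FIXED else None
                    apply_action(kg, second_curator_decision(current, assessment, replacement=replacement))
                else:
                    before = confidence_of(current)
                    try:
                        action = third_curator_review(current, agree=rng.random() < 0.5)
                    except ValueError:
                        continue
                    apply_action(kg, action)
                    if action.confidence is ConfidenceLevel.VERY_HIGH:
                        assert before in (ConfidenceLevel.MEDIUM, ConfidenceLevel.HIGH)
                        promoted_legally = True
            final = next(iter(kg.edges()), None)
            if final is not None and confidence_of(final) is ConfidenceLevel.VERY_HIGH:
                assert promoted_legally


class TestLabelMapping:
    def test_mapping_applied_at_graph_level(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("HGNC\tOLDNAME\tNEWNAME\n")
        mapping = load_label_mapping(path)
        kg = KnowledgeGraph()
        kg.add_edge(make_edge(make_protein("OLDNAME"), make_protein("B")))
        updated = apply_label_mapping(kg, mapping)
        assert updated == 1
        assert {e.subject.identifier for e in kg.edges()} == {"NEWNAME"}

    def test_malformed_mapping_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("just-one-column\n")
        with pytest.raises(ValueError):
            load_label_mapping(path)
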