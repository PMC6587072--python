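"""Re-curation quality gate: required annotations and the Likert confidence
workflow.

Re-curating an existing knowledge graph that was built without
inter-annotator agreement proceeds in two curator passes:

* the **second curator** grades every statement against its evidence on a
  Likert scale — nonsense evidence deletes the statement (and all statements
  sharing that evidence), unclear biology gets Confidence "Low" for later
  discussion, a wrong-but-fixable statement is fixed and gets "Medium", and
  a statement that can be asserted from the evidence gets "High";
* the **third curator** (curation lead) reviews every "Medium"/"High"
  statement and promotes it to "Very High" on agreement, otherwise records
  a fix and leaves the confidence pending re-review.

"Very High" is therefore reachable *only* through third-curator agreement
on a Medium or High statement. Confidence values are stored verbatim as the
annotation strings ("Very High" with the space) for round-trip fidelity
with BEL documents; the ordinal order lives here.

The ``check_required_annotations`` gate re-implements the compile-and-check
contract used as a CI gate: one violation per edge missing any required
annotation (typically "Confidence").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Optional, Union

from .belscript import statement_to_bel
from .model import Edge, KnowledgeGraph

__all__ = [
    "ConfidenceLevel",
    "Assessment",
    "EdgeAction",
    "AnnotationViolation",
    "confidence_of",
    "check_required_annotations",
    "second_curator_decision",
    "third_curator_review",
    "apply_action",
    "delete_with_related",
    "apply_label_mapping",
    "load_label_mapping",
]

CONFIDENCE_ANNOTATION = "Confidence"


class ConfidenceLevel(IntEnum):
    """Ordinal Likert confidence: None < Low < Medium < High < Very High."""

    NONE = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3
    VERY_HIGH = 4

    @property
    def label(self) -> str:
        return _LEVEL_LABELS[self]

    @classmethod
    def from_label(cls, label: Optional[str]) -> Optional["ConfidenceLevel"]:
        if label is None:
            return None
        return _LABEL_LEVELS.get(label)


_LEVEL_LABELS = {
    ConfidenceLevel.NONE: "None",
    ConfidenceLevel.LOW: "Low",
    ConfidenceLevel.MEDIUM: "Medium",
    ConfidenceLevel.HIGH: "High",
    ConfidenceLevel.VERY_HIGH: "Very High",
}
_LABEL_LEVELS = {label: level for level, label in _LEVEL_LABELS.items()}


def confidence_of(edge: Edge) -> Optional[ConfidenceLevel]:
    return ConfidenceLevel.from_label(edge.annotations.get(CONFIDENCE_ANNOTATION))


class Assessment(str, Enum):
    NONSENSE = "nonsense"
    UNCLEAR = "unclear"
    WRONG_FIXED = "wrong_fixed"
    ASSERTABLE = "assertable"


@dataclass
class EdgeAction:
    """The action a curator decision implies for one edge."""

    action: str  # "delete" | "set_confidence" | "replace" | "fix_pending" | "noop"
    edge: Edge
    confidence: Optional[ConfidenceLevel] = None
    replacement: Optional[Edge] = None
    note: str = ""


@dataclass(frozen=True)
class AnnotationViolation:
    citation: str
    statement: str
    missing: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {"citation": self.citation, "statement": self.statement, "missing": list(self.missing)}
        )


def check_required_annotations(
    kg: KnowledgeGraph, required: Iterable[str]
) -> list[AnnotationViolation]:
    """One violation per edge missing any of the required annotations."""
    required = list(required)
    violations = []
    for edge in sorted(kg.edges(), key=lambda e: e.identity):
        missing = tuple(name for name in required if name not in edge.annotations)
        if missing:
            violations.append(
                AnnotationViolation(
                    citation=edge.citation,
                    statement=statement_to_bel(edge),
                    missing=missing,
                )
            )
    return violations


def second_curator_decision(
    edge: Edge, assessment: Assessment, replacement: Optional[Edge] = None
) -> EdgeAction:
    """Second-curator grading of one statement against its evidence.

    An edge already promoted to Very High is out of this pass's scope: the
    decision is a no-op with a warning note.
    """
    if confidence_of(edge) is ConfidenceLevel.VERY_HIGH:
        return EdgeAction("noop", edge, note="edge already at Very High confidence; not re-graded")
    if assessment is Assessment.NONSENSE:
        return EdgeAction("delete", edge, confidence=ConfidenceLevel.NONE)
    if assessment is Assessment.UNCLEAR:
        return EdgeAction("set_confidence", edge, confidence=ConfidenceLevel.LOW)
    if assessment is Assessment.WRONG_FIXED:
        if replacement is None:
            raise ValueError("wrong_fixed requires the corrected replacement edge")
        return EdgeAction("replace", edge, confidence=ConfidenceLevel.MEDIUM, replacement=replacement)
    return EdgeAction("set_confidence", edge, confidence=ConfidenceLevel.HIGH)


def third_curator_review(edge: Edge, agree: bool) -> EdgeAction:
    """Third-curator (lead) review of a Medium/High statement.

    Agreement promotes to Very High; disagreement records a fix and leaves
    the confidence unchanged pending re-review. Edges below Medium are not
    eligible and raise ``ValueError``.
    """
    level = confidence_of(edge)
    if level not in (ConfidenceLevel.MEDIUM, ConfidenceLevel.HIGH):
        raise ValueError(
            f"third-curator review requires Medium or High confidence, found "
            f"{level.label if level is not None else 'none'}"
        )
    if agree:
        return EdgeAction("set_confidence", edge, confidence=ConfidenceLevel.VERY_HIGH)
    return EdgeAction("fix_pending", edge, confidence=level, note="disagreement; fix recorded, pending re-review")


def delete_with_related(kg: KnowledgeGraph, edge: Edge, scope: str = "evidence") -> int:
    """Delete an edge and its related statements.

    ``scope="evidence"`` (default) removes every statement sharing the same
    evidence string; ``scope="citation"`` widens removal to the whole
    citation. Returns the number of edges removed.
    """
    if scope not in ("evidence", "citation"):
        raise ValueError("scope must be 'evidence' or 'citation'")
    if scope == "evidence":
        doomed = [e for e in kg.edges() if e.evidence_text == edge.evidence_text and e.citation == edge.citation]
    else:
        doomed = [e for e in kg.edges() if e.citation == edge.citation]
    for e in doomed:
        kg.remove_edge(e)
    return len(doomed)


def apply_action(kg: KnowledgeGraph, action: EdgeAction, delete_scope: str = "evidence") -> None:
    """Apply a curator action to the graph in place."""
    if action.action == "noop" or action.action == "fix_pending":
        return
    if action.action == "delete":
        delete_with_related(kg, action.edge, scope=delete_scope)
        return
    if action.action == "replace":
        kg.remove_edge(action.edge)
        replacement = action.replacement
        replacement.annotations[CONFIDENCE_ANNOTATION] = action.confidence.label
        kg.add_edge(replacement)
        return
    if action.action == "set_confidence":
        kg.remove_edge(action.edge)
        action.edge.annotations[CONFIDENCE_ANNOTATION] = action.confidence.label
        kg.add_edge(action.edge)
        return
    raise ValueError(f"unknown action {action.action!r}")


# ---------------------------------------------------------------------------
# Namespace label updates (pluggable old-label -> new-identifier tables)
# ---------------------------------------------------------------------------


def load_label_mapping(path: Union[str, Path]) -> dict[tuple[str, str], str]:
    """Read a 2-column-per-namespace TSV mapping table:
    ``namespace<TAB>old_label<TAB>new_identifier``."""
    mapping: dict[tuple[str, str], str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"mapping line {lineno}: expected 3 tab-separated fields")
        namespace, old_label, new_identifier = (p.strip() for p in parts)
        mapping[(namespace, old_label)] = new_identifier
    return mapping


def apply_label_mapping(kg: KnowledgeGraph, mapping: dict[tuple[str, str], str]) -> int:
    """Rewrite stale entity labels to current identifiers; returns the
    number of entities updated. Applied after parse, before QC."""
    from dataclasses import replace as _dc_replace

    updated = 0
    edges = list(kg.edges())

    def fix(entity):
        nonlocal updated
        key = (entity.namespace, entity.identifier)
        if key in mapping:
            updated += 1
            return _dc_replace(entity, identifier=mapping[key], label=mapping[key])
        return entity

    for edge in edges:
        new_subject = fix(edge.subject)
        new_object = fix(edge.object)
        if new_subject is not edge.subject or new_object is not edge.object:
            kg.remove_edge(edge)
            edge.subject = new_subject
            edge.object = new_object
            kg.add_edge(edge)
    return updated
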