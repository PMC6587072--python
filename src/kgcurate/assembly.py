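"""Conversion of machine-extracted statements into candidate BEL edges.

Assembly semantics:

* activation / inhibition → one causal edge onto the activity of the object
  (``act()`` wrapper), except that activities are *never* wrapped around
  biological processes or pathologies under the default policy — the
  ``activity()`` function is reserved for proteins and other physical
  entities, and emitting it on a process is invalid BEL;
* phosphorylation and other modifications → a causal edge from the subject
  onto the modified object node, plus a ``hasVariant`` edge from the
  reference protein to its modified form;
* complex formation over n members → one complex node, n membership edges,
  and bidirectional (pairwise, both directions) association statements
  between the members: n + n(n-1) edges in total;
* amount regulation → a regulates edge onto the unmodified target.

Causal edges default to the *indirect* relation family (plain increases /
decreases): whether a relation involves physical contact is hard to detect
automatically, so directness is only asserted when the statement carries an
explicit physical-contact flag. Negated statements are never assembled into
(positive) BEL statements; they are skipped with a structured record.

Every emitted edge conserves provenance: the source statement's uuid,
evidence sentence and citation travel on the edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .corpus import (
    DEFAULT_NAMESPACE_PRIORITY,
    ExtractedStatement,
    Mention,
    StatementType,
    ground_mention,
)
from .model import (
    Edge,
    Entity,
    EntityClass,
    Modification,
    ModType,
    Relation,
)

__all__ = ["AssemblyPolicy", "AssemblyResult", "SkipRecord", "assemble", "ground"]

#: Entity classes that may not carry an activity() wrapper.
_PROCESS_CLASSES = frozenset({EntityClass.BIOLOGICAL_PROCESS, EntityClass.PATHOLOGY})


@dataclass(frozen=True)
class AssemblyPolicy:
    namespace_priority: tuple[str, ...] = DEFAULT_NAMESPACE_PRIORITY
    directness_default: str = "indirect"  # "indirect" | "direct"
    allow_activity_on_processes: bool = False

    def __post_init__(self) -> None:
        if not self.namespace_priority:
            raise ValueError("namespace_priority must be non-empty")
        if self.directness_default not in ("indirect", "direct"):
            raise ValueError("directness_default must be 'indirect' or 'direct'")


@dataclass
class SkipRecord:
    uuid: str
    reason: str
    detail: str = ""

    def to_json(self) -> str:
        return json.dumps({"uuid": self.uuid, "reason": self.reason, "detail": self.detail})


@dataclass
class AssemblyResult:
    edges: list[Edge] = field(default_factory=list)
    skips: list[SkipRecord] = field(default_factory=list)
    fixes: list[SkipRecord] = field(default_factory=list)  # policy-driven rewrites, e.g. dropped activity wrappers


def ground(mention: Mention, policy: AssemblyPolicy) -> Entity:
    """Ground a mention by namespace priority; ungroundable mentions come
    back flagged (``entity.grounded`` is False)."""
    return ground_mention(mention, policy.namespace_priority)


def _provenance(stmt: ExtractedStatement) -> dict:
    annotations = {"uuid": stmt.uuid}
    if stmt.readers:
        annotations["Readers"] = ",".join(sorted(stmt.readers))
    return annotations


def _causal_relation(positive: bool, stmt: ExtractedStatement, policy: AssemblyPolicy) -> Relation:
    direct = stmt.direct if stmt.direct is not None else (policy.directness_default == "direct")
    if positive:
        return Relation.DIRECTLY_INCREASES if direct else Relation.INCREASES
    return Relation.DIRECTLY_DECREASES if direct else Relation.DECREASES


def _mod_for(stmt: ExtractedStatement) -> Modification:
    mod_type = (
        ModType.PHOSPHORYLATION
        if stmt.statement_type is StatementType.PHOSPHORYLATION
        else ModType.OTHER_PTM
    )
    return Modification(mod_type, residue=stmt.residue, position=stmt.position)


def assemble(stmt: ExtractedStatement, policy: AssemblyPolicy = AssemblyPolicy()) -> AssemblyResult:
    """Convert one extracted statement into candidate BEL edges."""
    result = AssemblyResult()

    if stmt.negated:
        result.skips.append(SkipRecord(stmt.uuid, "negated", "negated statements are not assembled"))
        return result

    def make_edge(subject: Entity, obj: Entity, relation: Relation, **annotations) -> Edge:
        return Edge(
            subject=subject,
            object=obj,
            relation=relation,
            evidence_text=stmt.evidence_text,
            citation=stmt.citation,
            annotations={**_provenance(stmt), **annotations},
        )

    if stmt.statement_type is StatementType.COMPLEX_FORMATION:
        members = [ground(m, policy) for m in stmt.members]
        bad = [m for g, m in zip(members, stmt.members) if not g.grounded]
        if bad or len(members) < 2:
            result.skips.append(
                SkipRecord(stmt.uuid, "ungroundable", f"complex members not groundable: {[m.label for m in bad]}")
            )
            return result
        complex_node = Entity(EntityClass.COMPLEX, members=tuple(members))
        for member in members:
            result.edges.append(make_edge(complex_node, member, Relation.COMPLEX_MEMBERSHIP))
        for i, a in enumerate(members):
            for j, b in enumerate(members):
                if i != j:
                    result.edges.append(make_edge(a, b, Relation.ASSOCIATION))
        return result

    if stmt.statement_type is StatementType.OTHER or stmt.object is None:
        result.skips.append(SkipRecord(stmt.uuid, "unsupported", f"statement type {stmt.statement_type.value}"))
        return result

    subject = ground(stmt.subject, policy)
    obj = ground(stmt.object, policy)
    if not (subject.grounded and obj.grounded):
        bad = [m.label for g, m in ((subject, stmt.subject), (obj, stmt.object)) if not g.grounded]
        result.skips.append(SkipRecord(stmt.uuid, "ungroundable", f"participants not groundable: {bad}"))
        return result

    if stmt.statement_type in (StatementType.ACTIVATION, StatementType.INHIBITION):
        positive = stmt.statement_type is StatementType.ACTIVATION
        relation = _causal_relation(positive, stmt, policy)
        annotations = {}
        if obj.entity_class in _PROCESS_CLASSES and not policy.allow_activity_on_processes:
            result.fixes.append(
                SkipRecord(stmt.uuid, "activity_dropped", "activity() is invalid on process nodes; emitted bare")
            )
        else:
            annotations["_object_activity"] = "true"
        result.edges.append(make_edge(subject, obj, relation, **annotations))
        return result

    if stmt.statement_type in (StatementType.PHOSPHORYLATION, StatementType.OTHER_MODIFICATION):
        if obj.entity_class not in (EntityClass.PROTEIN, EntityClass.GENE, EntityClass.RNA):
            result.skips.append(
                SkipRecord(stmt.uuid, "invalid_target", "modification target must be a gene product")
            )
            return result
        modified = Entity(
            obj.entity_class,
            namespace=obj.namespace,
            identifier=obj.identifier,
            label=obj.label,
            variants=obj.variants + (_mod_for(stmt),),
        )
        result.edges.append(make_edge(subject, modified, _causal_relation(True, stmt, policy)))
        result.edges.append(make_edge(obj.strip_variants(), modified, Relation.HAS_VARIANT))
        return result

    if stmt.statement_type is StatementType.REGULATE_AMOUNT:
        result.edges.append(make_edge(subject, obj.strip_variants(), Relation.REGULATES))
        return result

    result.skips.append(SkipRecord(stmt.uuid, "unsupported", stmt.statement_type.value))
    return result
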