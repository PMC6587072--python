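"""Core data model for a BEL-subset knowledge graph.

Entities are grounded biological concepts (a namespace/identifier pair from a
terminology such as HGNC, CHEBI or GO), optionally carrying post-translational
modifications. Edges are typed, evidence-bearing relations between entities;
the graph is a directed multigraph in which parallel edges are distinguished
by their provenance (citation and evidence sentence).

The canonical-triple machinery collapses entities to gene level (RNA,
microRNA, protein and their variants map to the cognate gene) so that two
statements about the same underlying causal relation compare equal regardless
of which gene product they mention. This gene-level equivalence is what the
enrichment workflow uses to decide whether a machine-extracted relation is
already known.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "EntityClass",
    "ModType",
    "Relation",
    "RelationClass",
    "Modification",
    "Entity",
    "Edge",
    "Triple",
    "KnowledgeGraph",
    "canonical_entity_key",
    "canonical_triple",
    "CAUSAL_RELATIONS",
]


class EntityClass(str, Enum):
    GENE = "gene"
    RNA = "rna"
    MICRORNA = "microrna"
    PROTEIN = "protein"
    ABUNDANCE = "abundance"
    COMPLEX = "complex"
    FAMILY = "family"
    BIOLOGICAL_PROCESS = "biological_process"
    PATHOLOGY = "pathology"
    REACTION = "reaction"


#: Entity classes that collapse onto the same gene-level node.
GENE_PRODUCT_CLASSES = frozenset(
    {EntityClass.GENE, EntityClass.RNA, EntityClass.MICRORNA, EntityClass.PROTEIN}
)

#: Classes allowed to carry variants (modifications).
VARIANT_CLASSES = frozenset({EntityClass.GENE, EntityClass.RNA, EntityClass.PROTEIN})


class ModType(str, Enum):
    PHOSPHORYLATION = "phosphorylation"
    UBIQUITINATION = "ubiquitination"
    OTHER_PTM = "other_ptm"
    SEQUENCE_VARIANT = "sequence_variant"


class Relation(str, Enum):
    INCREASES = "increases"
    DIRECTLY_INCREASES = "directly_increases"
    DECREASES = "decreases"
    DIRECTLY_DECREASES = "directly_decreases"
    REGULATES = "regulates"
    COMPLEX_MEMBERSHIP = "complex_membership"
    HAS_VARIANT = "has_variant"
    ASSOCIATION = "association"
    CORRELATION = "correlation"
    ONTOLOGICAL = "ontological"


#: Relations that carry causal information. The causal flag on an edge is a
#: pure function of its relation; membership and variant edges are never causal.
CAUSAL_RELATIONS = frozenset(
    {
        Relation.INCREASES,
        Relation.DIRECTLY_INCREASES,
        Relation.DECREASES,
        Relation.DIRECTLY_DECREASES,
        Relation.REGULATES,
    }
)


class RelationClass(str, Enum):
    """Coarse relation classes used for gene-level statement equivalence."""

    UP = "up"
    DOWN = "down"
    REGULATES = "regulates"
    BINDS = "binds"
    MEMBERSHIP = "membership"
    OTHER = "other"


_RELATION_TO_CLASS = {
    Relation.INCREASES: RelationClass.UP,
    Relation.DIRECTLY_INCREASES: RelationClass.UP,
    Relation.DECREASES: RelationClass.DOWN,
    Relation.DIRECTLY_DECREASES: RelationClass.DOWN,
    Relation.REGULATES: RelationClass.REGULATES,
    Relation.ASSOCIATION: RelationClass.BINDS,
    Relation.COMPLEX_MEMBERSHIP: RelationClass.MEMBERSHIP,
    Relation.HAS_VARIANT: RelationClass.OTHER,
    Relation.CORRELATION: RelationClass.OTHER,
    Relation.ONTOLOGICAL: RelationClass.OTHER,
}

#: Relation classes that are symmetric at gene level; their triples are stored
#: with endpoints in sorted order so A-binds-B equals B-binds-A.
_SYMMETRIC_CLASSES = frozenset({RelationClass.BINDS})


@dataclass(frozen=True)
class Modification:
    """A protein/gene variant: a PTM (e.g. phosphorylation at Ser396) or a
    sequence variant."""

    mod_type: ModType
    residue: Optional[str] = None
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.position is not None and self.residue is None:
            raise ValueError("modification position requires a residue")
        if self.position is not None and self.position < 1:
            raise ValueError("modification position must be positive")


@dataclass(frozen=True)
class Entity:
    """A grounded biological entity.

    ``namespace``/``identifier`` ground the entity in a terminology; an entity
    with neither (and no complex members) is ungrounded and must be flagged by
    the producer. ``variants`` holds modifications and is only legal on gene,
    RNA and protein entities. ``members`` is only legal on composite
    complexes.
    """

    entity_class: EntityClass
    namespace: str = ""
    identifier: str = ""
    label: str = ""
    variants: tuple[Modification, ...] = ()
    members: tuple["Entity", ...] = ()

    def __post_init__(self) -> None:
        if self.variants and self.entity_class not in VARIANT_CLASSES:
            raise ValueError(
                f"variants not permitted on {self.entity_class.value} entities"
            )
        if self.members and self.entity_class is not EntityClass.COMPLEX:
            raise ValueError("members only permitted on complex entities")

    @property
    def grounded(self) -> bool:
        return bool(self.namespace and self.identifier) or bool(self.members)

    @property
    def key(self) -> tuple:
        """Full node identity, including class and variants."""
        if self.members:
            return (
                self.entity_class.value,
                "members",
                tuple(m.key for m in self.members),
            )
        return (
            self.entity_class.value,
            self.namespace,
            self.identifier,
            tuple((v.mod_type.value, v.residue or "", v.position or 0) for v in self.variants),
        )

    def strip_variants(self) -> "Entity":
        if not self.variants:
            return self
        return Entity(
            entity_class=self.entity_class,
            namespace=self.namespace,
            identifier=self.identifier,
            label=self.label,
            members=self.members,
        )


@dataclass
class Edge:
    """One evidence-bearing relation between two entities.

    ``annotations`` holds SET-style metadata (e.g. ``Confidence``); the edge's
    identity for multigraph purposes is (subject, relation, object, citation,
    evidence hash), so the same relation re-asserted from different evidence
    yields parallel edges.
    """

    subject: Entity
    object: Entity
    relation: Relation
    evidence_text: str = ""
    citation: str = ""
    annotations: dict = field(default_factory=dict)

    @property
    def causal(self) -> bool:
        return self.relation in CAUSAL_RELATIONS

    @property
    def identity(self) -> tuple:
        evidence_hash = hashlib.sha256(self.evidence_text.encode()).hexdigest()[:16]
        return (
            self.subject.key,
            self.relation.value,
            self.object.key,
            self.citation,
            evidence_hash,
        )


@dataclass(frozen=True)
class Triple:
    """Gene-collapsed statement equivalence class.

    ``comparable`` is False when either endpoint could not be grounded; such
    triples never compare equal to anything (including themselves) for
    deduplication purposes and are left to the curator.
    """

    subject_key: tuple
    relation_class: RelationClass
    object_key: tuple
    comparable: bool = True


def canonical_entity_key(entity: Entity) -> Optional[tuple]:
    """Gene-level canonical key: (namespace, identifier) with variants
    stripped and gene products collapsed onto the cognate gene grounding.

    Returns None for ungrounded entities. Idempotent by construction: the key
    depends only on the grounding, which collapsing does not alter.
    """
    if entity.members:
        return ("complex", tuple(sorted(filter(None, (canonical_entity_key(m) for m in entity.members)))))
    if not entity.grounded:
        return None
    return (entity.namespace, entity.identifier)


def canonical_triple(edge: Edge) -> Triple:
    """Map an edge to its gene-collapsed triple for novelty comparison."""
    s_key = canonical_entity_key(edge.subject)
    o_key = canonical_entity_key(edge.object)
    rel_class = _RELATION_TO_CLASS[edge.relation]
    if s_key is None or o_key is None:
        return Triple(s_key or ("", ""), rel_class, o_key or ("", ""), comparable=False)
    if rel_class in _SYMMETRIC_CLASSES and o_key < s_key:
        s_key, o_key = o_key, s_key
    return Triple(s_key, rel_class, o_key)


class KnowledgeGraph:
    """A multigraph of grounded entities with typed, annotated edges.

    Backed by :class:`networkx.MultiDiGraph`; nodes are keyed by the full
    entity key and edges by their provenance identity, so adding the same
    statement twice is a no-op while the same relation under different
    evidence accumulates parallel edges.
    """

    def __init__(self, name: str = "", version: str = "", namespaces: Optional[dict] = None):
        self._g = nx.MultiDiGraph()
        self.document_metadata: dict = {
            "name": name,
            "version": version,
            "namespaces": dict(namespaces or {}),
        }

    # -- construction ------------------------------------------------------

    def add_entity(self, entity: Entity) -> None:
        self._g.add_node(entity.key, entity=entity)

    def add_edge(self, edge: Edge) -> None:
        self.add_entity(edge.subject)
        self.add_entity(edge.object)
        self._g.add_edge(edge.subject.key, edge.object.key, key=edge.identity, edge=edge)

    def remove_edge(self, edge: Edge) -> None:
        self._g.remove_edge(edge.subject.key, edge.object.key, key=edge.identity)

    # -- access ------------------------------------------------------------

    @property
    def nx(self) -> nx.MultiDiGraph:
        return self._g

    def entities(self) -> Iterator[Entity]:
        for _, data in self._g.nodes(data=True):
            yield data["entity"]

    def edges(self) -> Iterator[Edge]:
        for _, _, data in self._g.edges(data=True):
            yield data["edge"]

    def node_keys(self) -> set:
        return set(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_entity(self, entity: Entity) -> bool:
        return entity.key in self._g

    def triples(self) -> set[Triple]:
        """All comparable gene-collapsed triples present in the graph."""
        return {t for t in map(canonical_triple, self.edges()) if t.comparable}

    def namespaces_used(self) -> set[str]:
        out = set()
        for entity in self.entities():
            stack = [entity]
            while stack:
                e = stack.pop()
                if e.namespace:
                    out.add(e.namespace)
                stack.extend(e.members)
        return out

    def copy(self) -> "KnowledgeGraph":
        other = KnowledgeGraph(
            name=self.document_metadata["name"],
            version=self.document_metadata["version"],
            namespaces=self.document_metadata["namespaces"],
        )
        for entity in self.entities():
            other.add_entity(entity)
        for edge in self.edges():
            other.add_edge(edge)
        return other

    @classmethod
    def from_edges(cls, edges: Iterable[Edge], name: str = "", version: str = "") -> "KnowledgeGraph":
        kg = cls(name=name, version=version)
        for edge in edges:
            kg.add_edge(edge)
        return kg
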