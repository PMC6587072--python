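"""Curation prioritization by information density.

The enrichment workflow pre-processes a knowledge graph down to its causal,
gene-level core and then ranks genes by how little the graph already knows
about them. Information density of a gene is its in-degree plus out-degree
in that pre-processed graph — isolated genes have no causal information at
all, leaves very little — and the genes with the *lowest* density are the
highest-priority curation targets.

Pre-processing does three things, each switchable:

1. drops entity classes that are out of scope for causal reasoning between
   genes (by default: chemical abundances, reactions, pathologies and
   biological processes);
2. drops non-causal edges (associations, correlations, ontological and
   membership links);
3. collapses every gene product (RNA, microRNA, protein, and modified
   variants thereof) onto a single gene-level node, rewiring incident causal
   edges accordingly. Protein families with a family-level grounding (e.g.
   FPLX) are kept as their own gene-level nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .model import (
    CAUSAL_RELATIONS,
    Edge,
    Entity,
    EntityClass,
    GENE_PRODUCT_CLASSES,
    KnowledgeGraph,
    canonical_triple,
)

__all__ = [
    "PreprocessConfig",
    "RankedGene",
    "preprocess",
    "information_density",
    "rank_genes",
    "select_round",
    "gene_key",
    "ranking_to_tsv",
]

#: Default number of genes per curation round.
DEFAULT_ROUND_SIZE = 30

_DEFAULT_EXCLUDED = frozenset(
    {
        EntityClass.ABUNDANCE,
        EntityClass.REACTION,
        EntityClass.PATHOLOGY,
        EntityClass.BIOLOGICAL_PROCESS,
    }
)

#: Classes that survive pre-processing as gene-level nodes.
_GENE_LEVEL = GENE_PRODUCT_CLASSES | {EntityClass.FAMILY}


@dataclass(frozen=True)
class PreprocessConfig:
    collapse_central_dogma: bool = True
    remove_noncausal: bool = True
    excluded_entity_classes: frozenset = _DEFAULT_EXCLUDED
    #: Count every evidence (parallel edge) toward density, not just unique
    #: relations. Density is meant to proxy the amount of causal information
    #: available, which accrues per evidence.
    count_evidences: bool = True

    def __post_init__(self) -> None:
        if EntityClass.GENE in self.excluded_entity_classes:
            raise ValueError("gene entities can never be excluded from pre-processing")


@dataclass(frozen=True)
class RankedGene:
    gene_key: str
    information_density: int
    rank: int


def gene_key(entity: Entity) -> str:
    """Canonical gene-level key string, e.g. ``"HGNC:GSK3B"``."""
    return f"{entity.namespace}:{entity.identifier}"


def _collapse(entity: Entity) -> Entity:
    """Collapse a gene product onto its gene-level node (variants stripped)."""
    if entity.entity_class in GENE_PRODUCT_CLASSES:
        return Entity(
            EntityClass.GENE,
            namespace=entity.namespace,
            identifier=entity.identifier,
            label=entity.label,
        )
    return entity.strip_variants()


def preprocess(kg: KnowledgeGraph, config: PreprocessConfig = PreprocessConfig()) -> KnowledgeGraph:
    """Reduce a knowledge graph to its causal gene-level core.

    Idempotent: pre-processing an already pre-processed graph is a no-op.
    Nodes whose entity class is excluded (or that are not gene-level at all,
    e.g. composite complexes) are removed along with their incident edges.
    Rewired duplicate edges with identical (gene-level triple, citation,
    evidence) are merged. Self-loops arising from collapsing (e.g.
    autophosphorylation) are kept.
    """
    out = KnowledgeGraph(
        name=kg.document_metadata.get("name", ""),
        version=kg.document_metadata.get("version", ""),
        namespaces=kg.document_metadata.get("namespaces", {}),
    )
    seen: set[tuple] = set()
    for edge in sorted(kg.edges(), key=lambda e: e.identity):
        if config.remove_noncausal and not edge.causal:
            continue
        s_cls = edge.subject.entity_class
        o_cls = edge.object.entity_class
        if s_cls in config.excluded_entity_classes or o_cls in config.excluded_entity_classes:
            continue
        if s_cls not in _GENE_LEVEL or o_cls not in _GENE_LEVEL:
            continue
        if not (edge.subject.grounded and edge.object.grounded):
            continue
        subject = _collapse(edge.subject) if config.collapse_central_dogma else edge.subject
        obj = _collapse(edge.object) if config.collapse_central_dogma else edge.object
        new_edge = Edge(
            subject=subject,
            object=obj,
            relation=edge.relation,
            evidence_text=edge.evidence_text,
            citation=edge.citation,
            annotations=dict(edge.annotations),
        )
        dedup_key = (canonical_triple(new_edge), new_edge.citation, new_edge.evidence_text)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        out.add_edge(new_edge)

    # Gene-level entities that lost all their edges stay as isolated nodes:
    # those are exactly the zero-density, highest-priority genes.
    for entity in kg.entities():
        if entity.entity_class in _GENE_LEVEL and entity.grounded:
            collapsed = _collapse(entity) if config.collapse_central_dogma else entity
            if not out.has_entity(collapsed):
                out.add_entity(collapsed)
    return out


def _node_index(kg: KnowledgeGraph) -> dict[str, tuple]:
    return {gene_key(entity): entity.key for entity in kg.entities()}


def information_density(kg: KnowledgeGraph, gene: str, count_evidences: bool = True) -> int:
    """In-degree plus out-degree of a gene in the pre-processed graph.

    Counts parallel edges (evidences) by default; with
    ``count_evidences=False`` counts unique gene-level triples instead.
    Isolated genes score 0. Raises ``KeyError`` for unknown genes.
    """
    index = _node_index(kg)
    if gene not in index:
        raise KeyError(f"gene {gene!r} not present in graph")
    node = index[gene]
    if count_evidences:
        return kg.nx.in_degree(node) + kg.nx.out_degree(node)
    in_t = {canonical_triple(d["edge"]) for _, _, d in kg.nx.in_edges(node, data=True)}
    out_t = {canonical_triple(d["edge"]) for _, _, d in kg.nx.out_edges(node, data=True)}
    return len(in_t) + len(out_t)


def rank_genes(
    kg: KnowledgeGraph,
    exclude: Optional[Iterable[str]] = None,
    density_fn: Optional[Callable[[KnowledgeGraph, str], int]] = None,
) -> list[RankedGene]:
    """Rank genes ascending by information density (lowest = curate first).

    ``exclude`` omits genes already handled in earlier rounds, so iterative
    application keeps surfacing new low-density genes. Ties break
    lexicographically by gene key, making the ranking deterministic and
    permutation-invariant. A custom ``density_fn`` may replace degree-based
    density.
    """
    excluded = set(exclude or ())
    fn = density_fn or information_density
    scored = [
        (fn(kg, key), key)
        for key in _node_index(kg)
        if key not in excluded
    ]
    scored.sort(key=lambda pair: (pair[0], pair[1]))
    return [
        RankedGene(gene_key=key, information_density=density, rank=i)
        for i, (density, key) in enumerate(scored, start=1)
    ]


def select_round(ranked: list[RankedGene], k: int = DEFAULT_ROUND_SIZE) -> list[str]:
    """First ``min(k, len(ranked))`` gene keys — one curation round's worth."""
    if k < 1:
        raise ValueError("round size k must be >= 1")
    return [r.gene_key for r in ranked[:k]]


def ranking_to_tsv(ranked: list[RankedGene]) -> str:
    lines = ["gene_key\tinformation_density\trank"]
    lines.extend(f"{r.gene_key}\t{r.information_density}\t{r.rank}" for r in ranked)
    return "\n".join(lines) + "\n"
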