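"""Machine-extracted statement corpus: reading, querying and filtering.

The corpus emulates a dump of statements produced by large-scale relation
extraction (readers such as REACH or Sparser, assembled and scored by a
system like INDRA). Each row carries the extracted relation, candidate
groundings for its participants, a belief score in [0, 1], the evidence
sentence and its citation.

The triage pipeline queries this corpus for the prioritized genes, drops
relations the knowledge graph already contains (novelty filter, compared at
gene-collapsed triple granularity) and drops low-belief statements
(default threshold 0.80: scores strictly below are removed to raise
precision at the cost of recall).

On-disk format: tab-separated with JSON columns for participant mentions —
portable, diff-able, and adaptable from real extraction dumps by a thin
converter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import (
    Edge,
    Entity,
    EntityClass,
    KnowledgeGraph,
    Relation,
    Triple,
    canonical_triple,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StatementType",
    "Mention",
    "ExtractedStatement",
    "CorpusQueryConfig",
    "read_corpus",
    "write_corpus",
    "query_corpus",
    "filter_novel",
    "filter_belief",
    "statement_triples",
    "DEFAULT_NAMESPACE_PRIORITY",
]

#: Namespace preference order used when a mention carries several candidate
#: groundings; gene-level namespaces first.
DEFAULT_NAMESPACE_PRIORITY = ("HGNC", "FPLX", "UP", "CHEBI", "GO", "MESH", "DOID", "HP")


class StatementType(str, Enum):
    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    PHOSPHORYLATION = "phosphorylation"
    OTHER_MODIFICATION = "other_modification"
    COMPLEX_FORMATION = "complex_formation"
    REGULATE_AMOUNT = "regulate_amount"
    OTHER = "other"


_TYPE_TO_RELATION = {
    StatementType.ACTIVATION: Relation.INCREASES,
    StatementType.INHIBITION: Relation.DECREASES,
    StatementType.PHOSPHORYLATION: Relation.INCREASES,
    StatementType.OTHER_MODIFICATION: Relation.INCREASES,
    StatementType.REGULATE_AMOUNT: Relation.REGULATES,
    StatementType.OTHER: Relation.ASSOCIATION,
}


@dataclass(frozen=True)
class Mention:
    """A recognized entity mention with zero or more candidate groundings,
    ordered as produced by the reader."""

    label: str
    entity_class: EntityClass = EntityClass.PROTEIN
    candidates: tuple[tuple[str, str], ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "class": self.entity_class.value,
                "candidates": [list(c) for c in self.candidates],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Mention":
        data = json.loads(text)
        return cls(
            label=data["label"],
            entity_class=EntityClass(data.get("class", "protein")),
            candidates=tuple((ns, ident) for ns, ident in data.get("candidates", [])),
        )


def ground_mention(mention: Mention, namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY) -> Entity:
    """Pick the candidate grounding whose namespace has highest priority.

    Candidates in namespaces outside the priority list rank after all listed
    ones (in candidate order); a mention with no candidates at all yields an
    ungrounded entity carrying only its text label.
    """
    if not mention.candidates:
        return Entity(mention.entity_class, label=mention.label)
    order = {ns: i for i, ns in enumerate(namespace_priority)}
    best = min(
        range(len(mention.candidates)),
        key=lambda i: (order.get(mention.candidates[i][0], len(order)), i),
    )
    ns, ident = mention.candidates[best]
    return Entity(mention.entity_class, namespace=ns, identifier=ident, label=mention.label or ident)


@dataclass(frozen=True)
class ExtractedStatement:
    uuid: str
    statement_type: StatementType
    subject: Mention
    object: Optional[Mention] = None
    members: tuple[Mention, ...] = ()  # complex_formation participants
    belief: Optional[float] = None
    evidence_text: str = ""
    citation: str = ""
    readers: frozenset = frozenset()
    negated: bool = False
    direct: Optional[bool] = None  # physical-contact flag when the reader asserts it
    residue: Optional[str] = None
    position: Optional[int] = None
    matched_genes: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.belief is not None and not (0.0 <= self.belief <= 1.0):
            raise ValueError(f"belief {self.belief} outside [0, 1]")

    def participants(self) -> tuple[Mention, ...]:
        if self.statement_type is StatementType.COMPLEX_FORMATION:
            return self.members
        return tuple(m for m in (self.subject, self.object) if m is not None)


def statement_triples(
    stmt: ExtractedStatement,
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> list[Triple]:
    """Gene-collapsed triples the statement would assert if curated.

    Complex formation over members {M1..Mn} asserts the pairwise binds
    triples; every other type asserts one triple from its implied relation.
    Ungroundable participants yield non-comparable triples.
    """
    if stmt.statement_type is StatementType.COMPLEX_FORMATION:
        grounded = [ground_mention(m, namespace_priority) for m in stmt.members]
        triples = []
        for i in range(len(grounded)):
            for j in range(i + 1, len(grounded)):
                triples.append(
                    canonical_triple(
                        Edge(subject=grounded[i], object=grounded[j], relation=Relation.ASSOCIATION)
                    )
                )
        return triples
    if stmt.object is None:
        return []
    edge = Edge(
        subject=ground_mention(stmt.subject, namespace_priority),
        object=ground_mention(stmt.object, namespace_priority),
        relation=_TYPE_TO_RELATION[stmt.statement_type],
    )
    return [canonical_triple(edge)]


@dataclass(frozen=True)
class CorpusQueryConfig:
    belief_threshold: float = 0.80
    exclude_existing: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.belief_threshold <= 1.0):
            raise ValueError("belief_threshold must lie in [0, 1]")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "uuid",
    "statement_type",
    "subject",
    "object",
    "members",
    "belief",
    "evidence",
    "citation",
    "readers",
    "negated",
    "residue",
    "position",
]


def write_corpus(statements: Iterable[ExtractedStatement], path: Union[str, Path],
                 truth_labels: Optional[dict] = None) -> None:
    """Write statements as TSV; optionally append a ``truth_label`` column
    (used by the synthetic generator, never read by the pipeline filters)."""
    path = Path(path)
    columns = list(_COLUMNS) + (["truth_label"] if truth_labels is not None else [])
    lines = ["\t".join(columns)]
    for stmt in statements:
        row = [
            stmt.uuid,
            stmt.statement_type.value,
            stmt.subject.to_json(),
            stmt.object.to_json() if stmt.object else "",
            json.dumps([json.loads(m.to_json()) for m in stmt.members], sort_keys=True) if stmt.members else "",
            "" if stmt.belief is None else f"{stmt.belief:.6f}",
            stmt.evidence_text.replace("\t", " ").replace("\n", " "),
            stmt.citation,
            ",".join(sorted(stmt.readers)),
            "1" if stmt.negated else "0",
            stmt.residue or "",
            "" if stmt.position is None else str(stmt.position),
        ]
        if truth_labels is not None:
            row.append(truth_labels.get(stmt.uuid, ""))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_members(text: str) -> tuple[Mention, ...]:
    if not text:
        return ()
    return tuple(
        Mention(
            label=d["label"],
            entity_class=EntityClass(d.get("class", "protein")),
            candidates=tuple((ns, ident) for ns, ident in d.get("candidates", [])),
        )
        for d in json.loads(text)
    )


def read_corpus(path: Union[str, Path]) -> tuple[list[ExtractedStatement], dict]:
    """Read a corpus TSV. Malformed rows are skipped with a logged warning;
    returns (statements, truth_labels) where truth_labels is empty unless the
    file carries a ``truth_label`` column."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return [], {}
    header = lines[0].split("\t")
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise ValueError(f"corpus file missing columns: {missing}")
    idx = {c: header.index(c) for c in header}
    has_truth = "truth_label" in idx
    statements: list[ExtractedStatement] = []
    truth: dict[str, str] = {}
    for row_index, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            logger.warning("corpus row %d: wrong column count, skipped", row_index)
            continue
        try:
            belief_text = cells[idx["belief"]]
            stmt = ExtractedStatement(
                uuid=cells[idx["uuid"]],
                statement_type=StatementType(cells[idx["statement_type"]]),
                subject=Mention.from_json(cells[idx["subject"]]),
                object=Mention.from_json(cells[idx["object"]]) if cells[idx["object"]] else None,
                members=_parse_members(cells[idx["members"]]),
                belief=float(belief_text) if belief_text else None,
                evidence_text=cells[idx["evidence"]],
                citation=cells[idx["citation"]],
                readers=frozenset(filter(None, cells[idx["readers"]].split(","))),
                negated=cells[idx["negated"]] == "1",
                residue=cells[idx["residue"]] or None,
                position=int(cells[idx["position"]]) if cells[idx["position"]] else None,
            )
        except (ValueError, KeyError, json.JSONDecodeError) as exc:
            logger.warning("corpus row %d: %s, skipped", row_index, exc)
            continue
        statements.append(stmt)
        if has_truth and cells[idx["truth_label"]]:
            truth[stmt.uuid] = cells[idx["truth_label"]]
    return statements, truth


# ---------------------------------------------------------------------------
# Query and filters
# ---------------------------------------------------------------------------


def _mention_gene_keys(mention: Mention, namespace_priority: Sequence[str]) -> set[str]:
    entity = ground_mention(mention, namespace_priority)
    if not entity.grounded:
        return set()
    return {f"{entity.namespace}:{entity.identifier}"}


def query_corpus(
    statements: Iterable[ExtractedStatement],
    genes: Iterable[str],
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> list[ExtractedStatement]:
    """Statements in which any participant's grounding matches a queried
    gene key; each hit is tagged with the matching gene(s)."""
    gene_set = set(genes)
    if not gene_set:
        return []
    out = []
    for stmt in statements:
        hits: set[str] = set()
        for mention in stmt.participants():
            hits |= _mention_gene_keys(mention, namespace_priority) & gene_set
        if hits:
            out.append(replace(stmt, matched_genes=tuple(sorted(hits))))
    return out


def filter_novel(
    statements: Iterable[ExtractedStatement],
    kg: KnowledgeGraph,
    namespace_priority: Sequence[str] = DEFAULT_NAMESPACE_PRIORITY,
) -> list[ExtractedStatement]:
    """Drop statements whose gene-collapsed triples the graph already holds.

    Comparison runs against the *un-preprocessed* curated graph so nothing
    the curators already handled comes back. A statement is dropped only when
    it asserts at least one comparable triple and every comparable triple it
    asserts is already present. Ungroundable statements are retained and
    flagged for the curator.
    """
    existing = kg.triples()
    out = []
    for stmt in statements:
        triples = statement_triples(stmt, namespace_priority)
        comparable = [t for t in triples if t.comparable]
        if not comparable:
            out.append(replace(stmt, flags=stmt.flags + ("ungroundable",)))
            continue
        if all(t in existing for t in comparable):
            continue
        out.append(stmt)
    return out


def filter_belief(statements: Iterable[ExtractedStatement], threshold: float = 0.80) -> list[ExtractedStatement]:
    """Keep statements with belief >= threshold.

    Statements *strictly below* the threshold are removed (a threshold of
    0.80 keeps a statement scored exactly 0.80). A missing belief is treated
    as 0 — conservatively removed at any positive threshold — and logged.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    out = []
    for stmt in statements:
        belief = stmt.belief
        if belief is None:
            logger.warning("statement %s has no belief score; treated as 0", stmt.uuid)
            belief = 0.0
        if belief >= threshold:
            out.append(stmt)
    return out
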