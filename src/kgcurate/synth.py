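"""Synthetic knowledge graphs, statement corpora and simulated curators.

Every stage of the enrichment workflow is testable without external data:
this module generates (i) random BEL-subset knowledge graphs with a
configurable mixture of entity classes and causal/non-causal relations,
(ii) machine-extraction corpora with *planted* truth structure — each row is
labeled correct, fixable with a known error type, or uncorrectable — and
(iii) a perfect simulated curator that fills curation sheets exactly
according to the marking protocol and the planted labels.

Default planted proportions are 0.31 correct / 0.48 fixable / 0.21
uncorrectable, the regime a large curation exercise over text-mined
statements realistically encounters, so downstream reports exercise
realistic magnitudes. Belief scores are drawn from Beta(5, 2) for correct
rows and Beta(2, 5) for corrupted rows, giving the 0.80 belief threshold a
visible precision effect. All generators are pure functions of
(config, seed): fixed seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .corpus import ExtractedStatement, Mention, StatementType, statement_triples
from .model import (
    CAUSAL_RELATIONS,
    Edge,
    Entity,
    EntityClass,
    KnowledgeGraph,
    Modification,
    ModType,
    Relation,
)
from .sheets import CurationRow, ErrorType

__all__ = ["FixtureConfig", "generate_kg", "generate_corpus", "simulate_curator"]

_DEFAULT_ERROR_RATES = {
    ErrorType.NER_WRONG_ENTITY.value: 0.18,
    ErrorType.SUBJECT_OBJECT_SWAP.value: 0.10,
    ErrorType.NO_RELATION_IN_EVIDENCE.value: 0.08,
    ErrorType.NEGATION_MISSED.value: 0.06,
    ErrorType.DIRECT_INDIRECT.value: 0.04,
    ErrorType.GRAMMAR_STRUCTURE.value: 0.02,
}

UNCORRECTABLE_LABEL = "uncorrectable"
CORRECT_LABEL = "correct"


@dataclass(frozen=True)
class FixtureConfig:
    n_genes: int = 40
    n_edges: int = 150
    frac_noncausal: float = 0.2
    frac_nongene_nodes: float = 0.2
    corpus_size: int = 1000
    #: (a, b) Beta parameters for belief of correct and corrupted rows.
    belief_correct: tuple[float, float] = (5.0, 2.0)
    belief_corrupted: tuple[float, float] = (2.0, 5.0)
    planted_error_rates: dict = field(default_factory=lambda: dict(_DEFAULT_ERROR_RATES))
    planted_correct_rate: float = 0.31
    planted_uncorrectable_rate: float = 0.21
    #: Fraction of corpus rows duplicating relations already in the graph,
    #: assigned independently of the truth label so the novelty filter works
    #: without biasing planted proportions.
    frac_duplicates: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        rates = [self.planted_correct_rate, self.planted_uncorrectable_rate, *self.planted_error_rates.values()]
        if any(not (0.0 <= r <= 1.0) for r in rates + [self.frac_noncausal, self.frac_nongene_nodes, self.frac_duplicates]):
            raise ValueError("all rates must lie in [0, 1]")
        total = sum(rates)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"planted rates must sum to 1, got {total}")


# ---------------------------------------------------------------------------
# Knowledge graph generation
# ---------------------------------------------------------------------------

_NONCAUSAL = (Relation.ASSOCIATION, Relation.CORRELATION, Relation.ONTOLOGICAL)
_CAUSAL = tuple(sorted(CAUSAL_RELATIONS, key=lambda r: r.value))


def _gene_symbol(i: int) -> str:
    return f"SYN{i:04d}"


def _gene_product(rng: np.random.Generator, symbol: str) -> Entity:
    """A random gene-product mention of one gene: protein/RNA/gene, with an
    occasional phosphorylated protein variant."""
    roll = rng.random()
    if roll < 0.6:
        variants = ()
        if rng.random() < 0.15:
            residue = str(rng.choice(["Ser", "Thr", "Tyr"]))
            variants = (Modification(ModType.PHOSPHORYLATION, residue=residue, position=int(rng.integers(1, 600))),)
        return Entity(EntityClass.PROTEIN, "HGNC", symbol, symbol, variants=variants)
    if roll < 0.8:
        return Entity(EntityClass.RNA, "HGNC", symbol, symbol)
    return Entity(EntityClass.GENE, "HGNC", symbol, symbol)


def _nongene_entity(rng: np.random.Generator, i: int) -> Entity:
    roll = rng.random()
    if roll < 0.4:
        return Entity(EntityClass.BIOLOGICAL_PROCESS, "GO", f"{7000000 + i}", f"process {i}")
    if roll < 0.7:
        return Entity(EntityClass.ABUNDANCE, "CHEBI", f"{40000 + i}", f"compound {i}")
    return Entity(EntityClass.PATHOLOGY, "MESH", f"D{10000 + i}", f"disease {i}")


def generate_kg(config: FixtureConfig, seed: Optional[int] = None) -> KnowledgeGraph:
    """Random multigraph with the configured entity-class and causality mix.

    Gene nodes are synthetic HGNC-style symbols; a ``frac_nongene_nodes``
    share of additional process/chemical/pathology nodes participates in
    edges so pre-processing has something to remove. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    kg = KnowledgeGraph(name="synthetic-kg", version="1.0.0")
    symbols = [_gene_symbol(i) for i in range(config.n_genes)]
    n_nongene = int(round(config.frac_nongene_nodes * config.n_genes))
    nongene = [_nongene_entity(rng, i) for i in range(n_nongene)]

    for symbol in symbols:
        kg.add_entity(Entity(EntityClass.PROTEIN, "HGNC", symbol, symbol))
    for entity in nongene:
        kg.add_entity(entity)

    for k in range(config.n_edges):
        subject = _gene_product(rng, symbols[int(rng.integers(config.n_genes))])
        if nongene and rng.random() < config.frac_nongene_nodes:
            obj: Entity = nongene[int(rng.integers(len(nongene)))]
        else:
            obj = _gene_product(rng, symbols[int(rng.integers(config.n_genes))])
        noncausal = rng.random() < config.frac_noncausal
        relation = (
            _NONCAUSAL[int(rng.integers(len(_NONCAUSAL)))]
            if noncausal
            else _CAUSAL[int(rng.integers(len(_CAUSAL)))]
        )
        kg.add_edge(
            Edge(
                subject=subject,
                object=obj,
                relation=relation,
                evidence_text=f"Synthetic evidence sentence {k} supporting the relation.",
                citation=str(int(rng.integers(10_000_000, 40_000_000))),
            )
        )
    return kg


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

_STATEMENT_TYPES = (
    StatementType.ACTIVATION,
    StatementType.INHIBITION,
    StatementType.PHOSPHORYLATION,
    StatementType.REGULATE_AMOUNT,
    StatementType.COMPLEX_FORMATION,
)

_READERS = ("reach", "sparser")


def _mention_for_gene(symbol: str) -> Mention:
    return Mention(label=symbol, entity_class=EntityClass.PROTEIN, candidates=(("HGNC", symbol),))


def _gene_pool(kg: KnowledgeGraph) -> list[str]:
    pool = sorted(
        {
            e.identifier
            for e in kg.entities()
            if e.namespace == "HGNC" and e.entity_class in (EntityClass.PROTEIN, EntityClass.RNA, EntityClass.GENE)
        }
    )
    return pool


def _random_statement(
    rng: np.random.Generator, uuid: str, pool: list[str], stype: StatementType
) -> ExtractedStatement:
    if stype is StatementType.COMPLEX_FORMATION:
        n_members = int(rng.integers(2, 4))
        idx = rng.choice(len(pool), size=min(n_members, len(pool)), replace=False)
        members = tuple(_mention_for_gene(pool[i]) for i in idx)
        return ExtractedStatement(
            uuid=uuid,
            statement_type=stype,
            subject=members[0],
            members=members,
            evidence_text="",
            citation="",
        )
    i, j = rng.integers(len(pool)), rng.integers(len(pool))
    residue = position = None
    if stype is StatementType.PHOSPHORYLATION and rng.random() < 0.5:
        residue = str(rng.choice(["Ser", "Thr", "Tyr"]))
        position = int(rng.integers(1, 600))
    return ExtractedStatement(
        uuid=uuid,
        statement_type=stype,
        subject=_mention_for_gene(pool[int(i)]),
        object=_mention_for_gene(pool[int(j)]),
        residue=residue,
        position=position,
    )


def generate_corpus(
    kg: KnowledgeGraph, config: FixtureConfig, seed: Optional[int] = None
) -> tuple[list[ExtractedStatement], dict[str, str]]:
    """Emulated machine-extraction dump about the graph's genes.

    Each row draws a truth label from the planted categorical distribution
    (correct / one of the fixable error types / uncorrectable); belief
    scores are drawn from the label-dependent Beta distributions so that
    corrupted statements are stochastically less believable. A
    label-independent ``frac_duplicates`` share of rows re-asserts a
    relation already present in the graph (at gene-collapsed granularity).

    Returns (statements, truth_labels keyed by uuid).
    """
    if kg.n_nodes == 0:
        raise ValueError("cannot generate a corpus for an empty graph")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    pool = _gene_pool(kg)
    if not pool:
        raise ValueError("graph contains no gene-level HGNC entities")
    existing = kg.triples()
    _up_down = (
        Relation.INCREASES,
        Relation.DIRECTLY_INCREASES,
        Relation.DECREASES,
        Relation.DIRECTLY_DECREASES,
    )
    duplicate_sources = [
        e
        for e in sorted(kg.edges(), key=lambda e: e.identity)
        if e.relation in _up_down and e.subject.namespace == "HGNC" and e.object.namespace == "HGNC"
    ]

    labels = [CORRECT_LABEL, UNCORRECTABLE_LABEL, *sorted(config.planted_error_rates)]
    probs = np.array(
        [config.planted_correct_rate, config.planted_uncorrectable_rate]
        + [config.planted_error_rates[k] for k in sorted(config.planted_error_rates)]
    )
    probs = probs / probs.sum()

    statements: list[ExtractedStatement] = []
    truth: dict[str, str] = {}
    for i in range(config.corpus_size):
        uuid = f"stmt-{i:06d}"
        label = labels[int(rng.choice(len(labels), p=probs))]
        duplicate = bool(duplicate_sources) and rng.random() < config.frac_duplicates
        if duplicate:
            src = duplicate_sources[int(rng.integers(len(duplicate_sources)))]
            stype = (
                StatementType.ACTIVATION
                if src.relation in (Relation.INCREASES, Relation.DIRECTLY_INCREASES)
                else StatementType.INHIBITION
            )
            stmt = ExtractedStatement(
                uuid=uuid,
                statement_type=stype,
                subject=_mention_for_gene(src.subject.identifier),
                object=_mention_for_gene(src.object.identifier),
            )
        else:
            stype = _STATEMENT_TYPES[int(rng.integers(len(_STATEMENT_TYPES)))]
            stmt = _random_statement(rng, uuid, pool, stype)
            # Resample a few times to keep non-duplicate rows genuinely novel.
            for _ in range(10):
                triples = [t for t in statement_triples(stmt) if t.comparable]
                if not triples or not all(t in existing for t in triples):
                    break
                stmt = _random_statement(rng, uuid, pool, stype)

        a, b = config.belief_correct if label == CORRECT_LABEL else config.belief_corrupted
        belief = float(np.clip(rng.beta(a, b), 0.0, 1.0))
        n_readers = 1 + int(rng.random() < 0.5)
        readers = frozenset(rng.choice(_READERS, size=n_readers, replace=False).tolist())
        stmt = replace(
            stmt,
            belief=belief,
            evidence_text=f"Synthetic evidence for {stmt.uuid}: reported interaction in a model system.",
            citation=str(int(rng.integers(10_000_000, 40_000_000))),
            readers=readers,
            negated=False,
        )
        statements.append(stmt)
        truth[uuid] = label
    return statements, truth


# ---------------------------------------------------------------------------
# Simulated curator
# ---------------------------------------------------------------------------


def simulate_curator(
    rows: list[CurationRow], truth_labels: dict[str, str], seed: Optional[int] = None, curator: str = "synthetic-curator"
) -> list[CurationRow]:
    """Fill a sheet exactly per the marking protocol using planted labels.

    The simulated curator is perfect: correct rows get Correct, fixable
    corruptions get Changed plus their planted error type and a corrected
    statement, uncorrectable rows get Checked with neither mark. Every row
    is Checked. Raises on rows whose uuid has no truth label.
    """
    filled = []
    for row in rows:
        if row.uuid not in truth_labels:
            raise ValueError(f"row uuid {row.uuid!r} has no truth label; inputs misaligned")
        label = truth_labels[row.uuid]
        if label == CORRECT_LABEL:
            filled.append(replace(row, checked=True, correct=True, curator=curator))
        elif label == UNCORRECTABLE_LABEL:
            filled.append(replace(row, checked=True, curator=curator))
        else:
            filled.append(
                replace(
                    row,
                    checked=True,
                    changed=True,
                    error_type=label,
                    corrected_bel=row.bel_statement,
                    curator=curator,
                )
            )
    return filled
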