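import pytest

from kgcurate.model import Edge, Entity, EntityClass, KnowledgeGraph, Relation
from kgcurate.synth import FixtureConfig, generate_corpus, generate_kg


def make_protein(symbol: str, variants=()) -> Entity:
    return Entity(EntityClass.PROTEIN, "HGNC", symbol, symbol, variants=tuple(variants))


def make_edge(subject, obj, relation=Relation.INCREASES, evidence="ev", citation="111", **annotations):
    return Edge(
        subject=subject,
        object=obj,
        relation=relation,
        evidence_text=evidence,
        citation=citation,
        annotations=dict(annotations),
    )


@pytest.fixture
def small_config():
    return FixtureConfig(n_genes=20, n_edges=60, corpus_size=200, seed=11)


@pytest.fixture
def random_kg(small_config):
    return generate_kg(small_config)


@pytest.fixture
def random_corpus(random_kg, small_config):
    return generate_corpus(random_kg, small_config)


@pytest.fixture
def toy_kg():
    """MAPT / GSK3B toy graph with a process node and an association."""
    kg = KnowledgeGraph(name="toy", version="1.0.0")
    gsk = make_protein("GSK3B")
    mapt = make_protein("MAPT")
    apoptosis = Entity(EntityClass.BIOLOGICAL_PROCESS, "GO", "0006915", "apoptotic process")
    kg.add_edge(make_edge(gsk, mapt, Relation.INCREASES, evidence="e1", citation="101"))
    kg.add_edge(make_edge(mapt, apoptosis, Relation.INCREASES, evidence="e2", citation="102"))
    kg.add_edge(make_edge(gsk, apoptosis, Relation.ASSOCIATION, evidence="e3", citation="103"))
    return kg
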