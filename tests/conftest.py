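import numpy as np
import pytest

from pathsem.kg_core import Entity, KnowledgeGraph, Relation, Triple


@pytest.fixture
def chain_kg() -> KnowledgeGraph:
    """A -r1-> B -r2-> C plus a direct A -rq-> C edge."""
    triples = [Triple("A", "r1", "B"), Triple("B", "r2", "C"),
               Triple("A", "rq", "C")]
    entities = {
        "A": Entity("A", "alpha", ("disease",)),
        "B": Entity("B", "beta", ("symptom",)),
        "C": Entity("C", "gamma", ("department",)),
    }
    relations = {
        "r1": Relation("r1", "the related symptom of {h} is {t}"),
        "r2": Relation("r2", "the related department of {h} is {t}"),
        "rq": Relation("rq", "the treating department of {h} is {t}"),
    }
    return KnowledgeGraph(triples, entities=entities, relations=relations)


@pytest.fixture
def figure_kg() -> KnowledgeGraph:
    """The worked subgraph: a disease connected to a department through a
    shared symptom (one 2-hop path) and through two 3-hop detours."""
    D, S, M = "drainage", "distress", "medicine"
    triples = [
        Triple(D, "disease_related_symptoms", S),
        Triple(S, "symptom_related_departments", M),
        Triple(D, "disease_related_symptoms", "clubbing"),
        Triple("clubbing", "symptom_related_symptoms", "lymphangio"),
        Triple("lymphangio", "symptom_related_departments", M),
        Triple(S, "symptom_related_diseases", "hemopneumothorax"),
        Triple("hemopneumothorax", "disease_related_departments", M),
    ]
    return KnowledgeGraph(triples)


def random_kg(rng: np.random.Generator, n_entities: int = 12,
              n_relations: int = 4, n_triples: int = 30) -> KnowledgeGraph:
    """Small random multigraph for property tests."""
    ents = [f"e{i}" for i in range(n_entities)]
    rels = [f"r{i}" for i in range(n_relations)]
    triples = []
    for _ in range(n_triples):
        h, t = rng.choice(n_entities, size=2, replace=False)
        triples.append(Triple(ents[h], rels[rng.integers(n_relations)], ents[t]))
    return KnowledgeGraph(triples)
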