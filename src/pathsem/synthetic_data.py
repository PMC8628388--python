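"""Synthetic medical-KG generator with the statistics the method assumes.

The generator emulates the structure of a symptom-centered medical knowledge
graph: a fixed schema of up to 17 relation types over six entity categories
(disease, symptom, examination, department, drug, body part), long-tailed
entity usage (Zipf-weighted endpoint sampling, so a large fraction of
entities participate in exactly one triple), multi-path evidence between
pairs, and planted chain rules — e.g. *disease —related symptom→ X
—related department→ Y  ⇒  disease —related department→ Y* — whose head
triples are the learnable signal.  Relation phrases are built so that
relations sharing a tail category form synonym groups verbalizing with the
same clause pattern ("the related symptom of {h} is {t}"), the
textual-semantics signal the text-enhanced models exploit.

Everything is deterministic given the config seed, and the output is the
standard TSV trio plus a gold-standard JSON consumed unchanged by the rest
of the pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .kg_core import (INVERSE_SUFFIX, Entity, KnowledgeGraph, Relation,
                      Triple, _largest_remainder)

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "Rule",
    "GoldStandard",
    "RELATION_SCHEMA",
    "generate_kg",
    "generate_names",
    "cskg_like_preset",
    "shuffle_relation_phrases",
    "write_gold",
    "read_gold",
]

#: (relation id, head category, tail category) — a 17-relation inventory of
#: a symptom knowledge graph.  Three category pairs carry *two* relation
#: ids each (e.g. ``symptom_related_departments`` and its rarer sibling
#: ``symptom_consulting_departments``): duplicated near-synonymous relation
#: types are a documented feature of real symptom graphs, and they are the
#: place where textual similarity between relations carries information
#: that the graph structure alone does not.
RELATION_SCHEMA: list[tuple[str, str, str]] = [
    ("disease_related_symptoms", "disease", "symptom"),
    ("symptom_related_diseases", "symptom", "disease"),
    ("symptom_related_symptoms", "symptom", "symptom"),
    ("disease_related_diseases", "disease", "disease"),
    ("disease_related_departments", "disease", "department"),
    ("symptom_related_departments", "symptom", "department"),
    ("symptom_consulting_departments", "symptom", "department"),
    ("disease_related_examinations", "disease", "examination"),
    ("symptom_related_examinations", "symptom", "examination"),
    ("examination_related_departments", "examination", "department"),
    ("examination_related_body_parts", "examination", "body_part"),
    ("disease_related_body_parts", "disease", "body_part"),
    ("symptom_related_body_parts", "symptom", "body_part"),
    ("symptom_affected_body_parts", "symptom", "body_part"),
    ("disease_related_drugs", "disease", "drug"),
    ("symptom_related_drugs", "symptom", "drug"),
    ("symptom_treating_drugs", "symptom", "drug"),
]

CATEGORY_PROPORTIONS: dict[str, float] = {
    "disease": 0.30,
    "symptom": 0.30,
    "examination": 0.15,
    "drug": 0.15,
    "department": 0.05,
    "body_part": 0.05,
}

_TAIL_NOUN = {"symptom": "symptom", "disease": "disease",
              "department": "department", "examination": "examination",
              "body_part": "body part", "drug": "drug"}

#: Name words are disjoint from the phrase nouns so that a statement's
#: relation-phrase tokens carry information the entity names do not repeat.
DEFAULT_LEXICON: dict[str, list[str]] = {
    "disease": ["morbus", "syndrome", "disorder", "lesion"],
    "symptom": ["ache", "sign", "complaint", "finding"],
    "examination": ["probe", "test", "scan", "assay"],
    "department": ["clinic", "ward", "unit", "service"],
    "drug": ["pill", "remedy", "tablet", "tincture"],
    "body_part": ["organ", "tissue", "region", "limb"],
}


@dataclass(frozen=True)
class Rule:
    """A chain rule: the body relation sequence entails the head relation."""

    body: tuple[str, ...]
    head: str
    precision: float


@dataclass
class GoldStandard:
    """Planted rules plus the head triples they entailed into the graph."""

    rules: list[Rule]
    held_out_positives: set[Triple] = field(default_factory=set)


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the desk-scale study conditions."""

    n_entities: int = 2000
    n_relations: int = 17
    zipf_exponent: float = 1.1
    edges_per_relation: int = 150
    #: examination-headed relations are this fraction as frequent as the
    #: rest — a long tail over *relations*, mirroring real symptom graphs
    #: where some relation types are an order of magnitude rarer.
    rare_head_factor: float = 0.15
    #: synonym-variant relations (the second relation of a duplicated
    #: category pair) are this fraction as frequent as their common sibling.
    variant_factor: float = 0.2
    n_rules: int = 6
    n_rule_chains: int = 30
    rule_precision: float = 1.0
    rule_max_length: int = 2
    synonym_groups: list[list[str]] | None = None
    max_path_len: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_relations <= len(RELATION_SCHEMA)):
            raise ValueError(f"n_relations must be in [1, {len(RELATION_SCHEMA)}]")
        if not (0.0 <= self.rule_precision <= 1.0):
            raise ValueError("rule_precision must lie in [0, 1]")
        if self.rule_max_length > self.max_path_len:
            raise ValueError("rule_max_length must not exceed max_path_len")


def _schema(config: SynthConfig) -> list[tuple[str, str, str]]:
    return RELATION_SCHEMA[: config.n_relations]


def variant_relations(config: SynthConfig) -> set[str]:
    """Relation ids that are synonym variants: for each duplicated category
    pair, every relation after the first in schema order."""
    seen: set[tuple[str, str]] = set()
    variants: set[str] = set()
    for rid, h, t in _schema(config):
        if (h, t) in seen:
            variants.add(rid)
        seen.add((h, t))
    return variants


#: head-category adjective: phrases within a synonym group (shared tail
#: noun) are near-identical, not equal, across head categories
_HEAD_ADJECTIVE = {"disease": "related", "symptom": "associated",
                   "examination": "linked"}


def relation_phrase(relation_id: str, head_cat: str, tail_cat: str) -> str:
    """Relations sharing a tail category verbalize with near-identical
    clause patterns ("the related department of …" / "the associated
    department of …"), and a synonym-variant relation shares its sibling's
    phrase *exactly* — the similar-semantics structure of real symptom
    graphs, where distinct relation ids carry the same surface meaning."""
    adj = _HEAD_ADJECTIVE.get(head_cat, "related")
    noun = _TAIL_NOUN.get(tail_cat, tail_cat)
    return f"the {adj} {noun} of {{h}} is {{t}}"


def synonym_groups_from_schema(config: SynthConfig) -> list[list[str]]:
    """Relations sharing a tail category share the noun of their phrase."""
    by_tail: dict[str, list[str]] = {}
    for rid, _, tail_cat in _schema(config):
        by_tail.setdefault(tail_cat, []).append(rid)
    return [sorted(group) for _, group in sorted(by_tail.items())
            if len(group) > 1]


def generate_names(
    config: SynthConfig, lexicon: dict[str, list[str]] | None = None
) -> tuple[dict[str, Entity], dict[str, Relation]]:
    """Deterministic entity/relation metadata.

    Entity names are a category type-word plus an index ("disease 0007");
    each entity carries its category as a type plus a subtype word from the
    lexicon.  Relation phrases follow the synonym-group construction.
    """
    lexicon = lexicon or DEFAULT_LEXICON
    schema = _schema(config)
    categories = sorted({c for _, h, t in schema for c in (h, t)})
    for cat in categories:
        if not lexicon.get(cat):
            raise ValueError(f"lexicon has no type words for category {cat!r}")
    sizes = _category_sizes(config, categories)
    entities: dict[str, Entity] = {}
    for cat in categories:
        words = lexicon[cat]
        for i in range(sizes[cat]):
            eid = f"{cat}_{i:04d}"
            subtype = words[i % len(words)]
            types = (cat,) if subtype == cat else (cat, subtype)
            entities[eid] = Entity(id=eid, name=f"{words[0]} {i:04d}",
                                   types=types)
    relations = {
        rid: Relation(id=rid, phrase=relation_phrase(rid, h, t))
        for rid, h, t in schema
    }
    if len({e.name for e in entities.values()}) != len(entities):
        raise ValueError("lexicon too small: entity names collide")
    return entities, relations


def _category_sizes(config: SynthConfig, categories: list[str]) -> dict[str, int]:
    weights = [CATEGORY_PROPORTIONS.get(c, 0.05) for c in categories]
    sizes = _largest_remainder(config.n_entities, weights)
    return dict(zip(categories, sizes))


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=float)) ** (-exponent)
    return w / w.sum()


def _rule_candidates(config: SynthConfig) -> list[Rule]:
    """Composable schema triads (A→B, B→C ⇒ A→C), deterministic order.

    Candidates whose second body relation belongs to a duplicated category
    pair come first, common sibling before its rare variant, so the default
    rule set pairs every rule with a synonym-variant route to the same
    head: evidence for the head can arrive through either relation, and
    the two routes verbalize with the same clause pattern.
    """
    schema = _schema(config)
    by_id = {rid: (h, t) for rid, h, t in schema}
    pair_counts: dict[tuple[str, str], int] = {}
    for _, h, t in schema:
        pair_counts[(h, t)] = pair_counts.get((h, t), 0) + 1
    variants = variant_relations(config)
    candidates = []
    for r1, (h1, t1) in by_id.items():
        for r2, (h2, t2) in by_id.items():
            if t1 != h2:
                continue
            for rh, (hh, th) in by_id.items():
                if (hh, th) == (h1, t2) and rh not in (r1, r2):
                    candidates.append(Rule(body=(r1, r2), head=rh,
                                           precision=config.rule_precision))
    head_rank = {"disease": 0, "symptom": 1, "examination": 2}
    candidates.sort(key=lambda r: (
        0 if pair_counts[by_id[r.body[1]]] > 1 else 1,  # variant-backed first
        head_rank.get(by_id[r.head][0], 9),  # disease-headed rules first
        by_id[r.body[1]],
        r.head,
        1 if r.body[1] in variants else 0,  # common route before variant
        r.body,
    ))
    return candidates


def generate_kg(config: SynthConfig) -> tuple[KnowledgeGraph, GoldStandard]:
    """Generate the graph and its gold standard.

    Construction: (1) Zipf-weighted background edges per relation; (2) a set
    of planted rule chains guaranteeing each rule has body instances; (3) a
    closure pass adding, with probability ``rule_precision``, the head
    triple of every entity pair connected by a rule body.  At precision 1.0
    every body-connected pair therefore has its head triple.
    """
    if config.rule_max_length < 2 and config.n_rules > 0:
        raise ValueError("chain rules need rule_max_length >= 2")
    rng = np.random.default_rng(config.seed)
    entities, relations = generate_names(config)
    schema = _schema(config)
    categories = sorted({c for _, h, t in schema for c in (h, t)})
    sizes = _category_sizes(config, categories)
    members = {cat: sorted(e for e in entities if e.startswith(cat + "_"))
               for cat in categories}
    weights = {cat: _zipf_weights(sizes[cat], config.zipf_exponent)
               for cat in categories}

    def draw(cat: str) -> str:
        idx = rng.choice(sizes[cat], p=weights[cat])
        return members[cat][idx]

    variants = variant_relations(config)

    def edge_budget(rid: str, head_cat: str) -> int:
        scale = 1.0
        if head_cat == "examination":
            scale *= config.rare_head_factor
        if rid in variants:
            scale *= config.variant_factor
        return max(1, int(round(config.edges_per_relation * scale)))

    triples: set[Triple] = set()
    for rid, head_cat, tail_cat in schema:
        target = edge_budget(rid, head_cat)
        added = 0
        attempts = 0
        while added < target and attempts < 20 * target:
            attempts += 1
            h, t = draw(head_cat), draw(tail_cat)
            if h == t:
                continue
            triple = Triple(h, rid, t)
            if triple not in triples:
                triples.add(triple)
                added += 1

    rules = _rule_candidates(config)[: config.n_rules]
    cat_of = {rid: (h, t) for rid, h, t in schema}
    for rule in rules:
        r1, r2 = rule.body
        chain_scale = 1.0
        if cat_of[r1][0] == "examination":
            chain_scale *= config.rare_head_factor
        if r2 in variants or r1 in variants:
            chain_scale *= config.variant_factor
        n_chains = max(1, int(round(config.n_rule_chains * chain_scale)))
        for _ in range(n_chains):
            e1 = draw(cat_of[r1][0])
            e2 = draw(cat_of[r1][1])
            e3 = draw(cat_of[r2][1])
            if len({e1, e2, e3}) < 3:
                continue
            triples.add(Triple(e1, r1, e2))
            triples.add(Triple(e2, r2, e3))

    # closure: entail rule heads over every body-connected pair
    gold = GoldStandard(rules=list(rules))
    by_relation: dict[str, list[Triple]] = {}
    for t in sorted(triples):
        by_relation.setdefault(t.relation, []).append(t)
    for rule in rules:
        r1, r2 = rule.body
        tails_by_head: dict[str, list[str]] = {}
        for t in by_relation.get(r2, []):
            tails_by_head.setdefault(t.head, []).append(t.tail)
        for t1 in by_relation.get(r1, []):
            for e3 in tails_by_head.get(t1.tail, []):
                if e3 == t1.head:
                    continue
                if rng.random() < rule.precision:
                    head_triple = Triple(t1.head, rule.head, e3)
                    triples.add(head_triple)
                    gold.held_out_positives.add(head_triple)

    kg = KnowledgeGraph(triples, entities=entities, relations=relations)
    logger.info("generated synthetic KG: %d entities, %d relations, %d triples, "
                "%d rule-entailed positives", kg.n_entities, len(schema),
                kg.n_triples, len(gold.held_out_positives))
    return kg, gold


def cskg_like_preset(seed: int = 0) -> SynthConfig:
    """Desk-scale preset mirroring the target graph's shape: 17 relation
    types, max path length 7, a long-tailed entity distribution with roughly
    a third of the active entities appearing exactly once (approximate by
    construction, not asserted)."""
    return SynthConfig(n_entities=2000, n_relations=17, zipf_exponent=1.1,
                       edges_per_relation=150, n_rules=6, n_rule_chains=30,
                       rule_precision=1.0, rule_max_length=2,
                       max_path_len=7, seed=seed)


def singleton_entity_fraction(kg: KnowledgeGraph) -> float:
    """Fraction of active entities participating in exactly one triple."""
    degree: dict[str, int] = {}
    for t in kg.triples:
        degree[t.head] = degree.get(t.head, 0) + 1
        degree[t.tail] = degree.get(t.tail, 0) + 1
    if not degree:
        return 0.0
    return sum(1 for d in degree.values() if d == 1) / len(degree)


def shuffle_relation_phrases(kg: KnowledgeGraph, seed: int = 0) -> KnowledgeGraph:
    """Ablation graph: relation phrases deranged across relations, so
    textual similarity between relations no longer reflects semantics.

    Only forward relations are permuted (a derangement by phrase value);
    inverse relations, when enabled, regenerate their slot-swapped phrase
    from the shuffled forward phrase, exactly as in the unshuffled graph.
    """
    rng = np.random.default_rng(seed)
    rids = [r for r in sorted(kg.relations) if not r.endswith(INVERSE_SUFFIX)]
    phrases = [kg.relations[r].phrase for r in rids]
    perm = np.arange(len(rids))
    if len(set(phrases)) > 1:
        while True:  # derangement by value: nobody keeps an equal phrase
            rng.shuffle(perm)
            if all(phrases[perm[i]] != phrases[i] for i in range(len(rids))):
                break
    relations = {r: Relation(id=r, phrase=phrases[perm[i]])
                 for i, r in enumerate(rids)}
    return KnowledgeGraph(kg.triples, entities=kg.entities,
                          relations=relations, add_inverse=kg.add_inverse)


def write_gold(gold: GoldStandard, path) -> None:
    obj = {
        "rules": [asdict(r) | {"body": list(r.body)} for r in gold.rules],
        "held_out_positives": sorted(
            [t.head, t.relation, t.tail] for t in gold.held_out_positives
        ),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)


def read_gold(path) -> GoldStandard:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    rules = [Rule(body=tuple(r["body"]), head=r["head"],
                  precision=r["precision"]) for r in obj["rules"]]
    positives = {Triple(h, r, t) for h, r, t in obj["held_out_positives"]}
    return GoldStandard(rules=rules, held_out_positives=positives)
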