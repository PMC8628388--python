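"""Knowledge-graph data model, TSV I/O, indexing and dataset splitting.

A knowledge graph is a set of ``(head, relation, tail)`` triples over string
identifiers, plus optional metadata: a display name and a list of type labels
per entity, and a verbalization phrase per relation.  Triples have set
semantics — duplicates collapse.  Adjacency is indexed per entity as a sorted
list of outgoing ``(relation, neighbor)`` edges; inverse edges (suffix
``_inv``) can be added so that walks may traverse relations backwards.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

INVERSE_SUFFIX = "_inv"

__all__ = [
    "Entity",
    "Relation",
    "Triple",
    "KnowledgeGraph",
    "SplitSpec",
    "load_graph",
    "write_graph",
    "split_dataset",
    "relation_participants",
    "default_phrase",
    "INVERSE_SUFFIX",
]


def default_phrase(relation_id: str) -> str:
    """Fallback verbalization template for a relation without metadata."""
    return "{h} <%s> {t}" % relation_id


@dataclass
class Entity:
    """A graph node: opaque id, display name, ordered type labels."""

    id: str
    name: str = ""
    types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("entity id must be non-empty")
        if not self.name:
            self.name = self.id
        self.types = tuple(self.types)


@dataclass
class Relation:
    """An edge label with a verbalization phrase containing {h} and {t} slots."""

    id: str
    phrase: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("relation id must be non-empty")
        if not self.phrase:
            self.phrase = default_phrase(self.id)
        if "{h}" not in self.phrase or "{t}" not in self.phrase:
            raise ValueError(
                f"relation {self.id!r} phrase must contain {{h}} and {{t}}: {self.phrase!r}"
            )


@dataclass(frozen=True, order=True)
class Triple:
    head: str
    relation: str
    tail: str

    def __post_init__(self) -> None:
        if not self.head or not self.tail or not self.relation:
            raise ValueError(f"triple fields must be non-empty: {self!r}")

    def inverse(self) -> "Triple":
        return Triple(self.tail, self.relation + INVERSE_SUFFIX, self.head)


class KnowledgeGraph:
    """Indexed triple store with entity/relation vocabularies and adjacency.

    Parameters
    ----------
    triples:
        Iterable of :class:`Triple`; duplicates collapse (logged).
    entities, relations:
        Optional metadata maps.  Ids referenced by triples but missing from
        the maps are auto-filled with degenerate metadata (name = id, no
        types; phrase = ``"{h} <id> {t}"``).
    add_inverse:
        When true, adjacency additionally contains a traversable inverse edge
        ``(tail, relation_inv, head)`` for every triple.  Off by default.
    """

    def __init__(
        self,
        triples: Iterable[Triple],
        entities: dict[str, Entity] | None = None,
        relations: dict[str, Relation] | None = None,
        add_inverse: bool = False,
    ) -> None:
        raw = list(triples)
        self.triples: set[Triple] = set(raw)
        n_dup = len(raw) - len(self.triples)
        if n_dup:
            logger.info("collapsed %d duplicate triples", n_dup)
        self.add_inverse = add_inverse
        self.entities: dict[str, Entity] = dict(entities or {})
        self.relations: dict[str, Relation] = dict(relations or {})
        for t in self.triples:
            for eid in (t.head, t.tail):
                if eid not in self.entities:
                    self.entities[eid] = Entity(id=eid)
            if t.relation not in self.relations:
                self.relations[t.relation] = Relation(id=t.relation)
            if add_inverse:
                inv = t.relation + INVERSE_SUFFIX
                if inv not in self.relations:
                    fwd = self.relations[t.relation].phrase
                    # Swapping the slots verbalizes the inverse edge as the
                    # forward fact it encodes.
                    inv_phrase = (
                        fwd.replace("{h}", "\x00").replace("{t}", "{h}").replace("\x00", "{t}")
                    )
                    self.relations[inv] = Relation(id=inv, phrase=inv_phrase)
        self._adjacency: dict[str, list[tuple[str, str]]] = {e: [] for e in self.entities}
        for t in sorted(self.triples):
            self._adjacency[t.head].append((t.relation, t.tail))
            if add_inverse:
                self._adjacency[t.tail].append((t.relation + INVERSE_SUFFIX, t.head))
        for edges in self._adjacency.values():
            edges.sort()

    # -- queries ---------------------------------------------------------

    def neighbors(self, entity_id: str) -> Sequence[tuple[str, str]]:
        """Outgoing ``(relation, neighbor)`` edges of an entity, sorted."""
        if entity_id not in self._adjacency:
            raise KeyError(f"unknown entity: {entity_id!r}")
        return self._adjacency[entity_id]

    def has_entity(self, entity_id: str) -> bool:
        return entity_id in self.entities

    def has_triple(self, triple: Triple) -> bool:
        return triple in self.triples

    def entity(self, entity_id: str) -> Entity:
        try:
            return self.entities[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity: {entity_id!r}") from None

    def relation(self, relation_id: str) -> Relation:
        try:
            return self.relations[relation_id]
        except KeyError:
            raise KeyError(f"unknown relation: {relation_id!r}") from None

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def relation_ids(self) -> list[str]:
        """Relation ids that label at least one (non-inverse) triple, sorted."""
        return sorted({t.relation for t in self.triples})

    def subgraph(self, triples: Iterable[Triple]) -> "KnowledgeGraph":
        """A graph over a triple subset, sharing this graph's metadata."""
        return KnowledgeGraph(
            triples, entities=self.entities, relations=self.relations,
            add_inverse=self.add_inverse,
        )


def relation_participants(kg: KnowledgeGraph, relation: str, slot: str) -> set[str]:
    """Entities appearing in the head or tail slot of a relation's triples."""
    if relation not in kg.relations:
        raise KeyError(f"unknown relation: {relation!r}")
    if slot not in ("head", "tail"):
        raise ValueError(f"slot must be 'head' or 'tail', got {slot!r}")
    if slot == "head":
        return {t.head for t in kg.triples if t.relation == relation}
    return {t.tail for t in kg.triples if t.relation == relation}


# -- file I/O ------------------------------------------------------------


def _read_tsv(path: FilePath | str, n_cols: int) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} tab-separated "
                    f"columns, got {len(cols)}"
                )
            rows.append(cols)
    return rows


def load_graph(
    triples_path: FilePath | str,
    entities_path: FilePath | str | None = None,
    relations_path: FilePath | str | None = None,
    add_inverse: bool = False,
) -> KnowledgeGraph:
    """Load a graph from a 3-column triple TSV plus optional metadata TSVs.

    Entity metadata rows are ``id<TAB>name<TAB>type1|type2|...``; relation
    metadata rows are ``id<TAB>phrase``.  Missing metadata degrades to
    name-equals-id entities and ``"{h} <id> {t}"`` phrases.
    """
    triples = [Triple(h, r, t) for h, r, t in _read_tsv(triples_path, 3)]
    entities: dict[str, Entity] = {}
    if entities_path is not None:
        for eid, name, types in _read_tsv(entities_path, 3):
            tlist = tuple(t for t in types.split("|") if t)
            entities[eid] = Entity(id=eid, name=name, types=tlist)
    relations: dict[str, Relation] = {}
    if relations_path is not None:
        for rid, phrase in _read_tsv(relations_path, 2):
            relations[rid] = Relation(id=rid, phrase=phrase)
    return KnowledgeGraph(triples, entities=entities, relations=relations,
                          add_inverse=add_inverse)


def write_graph(
    kg: KnowledgeGraph,
    triples_path: FilePath | str,
    entities_path: FilePath | str | None = None,
    relations_path: FilePath | str | None = None,
) -> None:
    """Write the triple set (and optionally metadata) as TSV, sorted."""
    write_triples(sorted(kg.triples), triples_path)
    if entities_path is not None:
        with open(entities_path, "w", encoding="utf-8") as fh:
            for eid in sorted(kg.entities):
                e = kg.entities[eid]
                fh.write(f"{e.id}\t{e.name}\t{'|'.join(e.types)}\n")
    if relations_path is not None:
        with open(relations_path, "w", encoding="utf-8") as fh:
            for rid in sorted(kg.relations):
                if rid.endswith(INVERSE_SUFFIX):
                    continue
                fh.write(f"{rid}\t{kg.relations[rid].phrase}\n")


def write_triples(triples: Iterable[Triple], path: FilePath | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


# -- splitting -----------------------------------------------------------


@dataclass
class SplitSpec:
    """Train/dev/test ratio weights and the shuffle seed."""

    ratios: tuple[float, float, float] = (7.0, 1.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be three non-negative weights")
        if sum(self.ratios) <= 0:
            raise ValueError("ratios must sum to a positive value")


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    total = float(sum(ratios))
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    remainder = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_dataset(
    kg: KnowledgeGraph, spec: SplitSpec
) -> tuple[list[Triple], list[Triple], list[Triple]]:
    """Partition the triples into train/dev/test by ratio.

    Splitting is stratified by relation (so each relation contributes to
    every split in proportion) while the *global* split sizes follow
    largest-remainder rounding of the ratios — e.g. 1000 triples at
    7:1.5:1.5 give exactly 700/150/150.  Deterministic given the seed.
    """
    if not kg.triples:
        raise ValueError("cannot split an empty graph")
    global_sizes = _largest_remainder(kg.n_triples, spec.ratios)
    by_relation: dict[str, list[Triple]] = {}
    for t in sorted(kg.triples):
        by_relation.setdefault(t.relation, []).append(t)

    alloc: dict[str, list[int]] = {}
    for rid, ts in by_relation.items():
        random.Random(f"{spec.seed}:{rid}").shuffle(ts)
        alloc[rid] = _largest_remainder(len(ts), spec.ratios)

    # Per-relation largest-remainder totals can drift from the global
    # largest-remainder sizes by a few units; rebalance deterministically by
    # moving one triple at a time from the relation with the largest donor
    # allocation.
    def totals() -> list[int]:
        return [sum(a[i] for a in alloc.values()) for i in range(3)]

    cur = totals()
    while cur != global_sizes:
        over = max(range(3), key=lambda i: cur[i] - global_sizes[i])
        under = min(range(3), key=lambda i: cur[i] - global_sizes[i])
        donor = max(
            (rid for rid in alloc if alloc[rid][over] > 0),
            key=lambda rid: (alloc[rid][over], rid),
        )
        alloc[donor][over] -= 1
        alloc[donor][under] += 1
        cur = totals()

    splits: tuple[list[Triple], list[Triple], list[Triple]] = ([], [], [])
    for rid in sorted(by_relation):
        ts = by_relation[rid]
        a, b, _ = alloc[rid]
        splits[0].extend(ts[:a])
        splits[1].extend(ts[a : a + b])
        splits[2].extend(ts[a + b :])
    return splits


def write_splits(
    splits: tuple[list[Triple], list[Triple], list[Triple]],
    spec: SplitSpec,
    out_dir: FilePath | str,
) -> None:
    """Write train/dev/test TSVs plus a JSON manifest into a directory."""
    out = FilePath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = ("train", "dev", "test")
    for name, triples in zip(names, splits):
        write_triples(triples, out / f"{name}.tsv")
    manifest = {
        "ratios": list(spec.ratios),
        "seed": spec.seed,
        "counts": {name: len(ts) for name, ts in zip(names, splits)},
    }
    (out / "split_manifest.json").write_text(json.dumps(manifest, indent=2))
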