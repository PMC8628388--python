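"""Relation-path extraction between entity pairs.

Two extractors share one contract: :func:`enumerate_paths` exhaustively lists
all simple paths up to a length bound (bounded DFS via networkx — the slow,
exact oracle) and :func:`random_walk_paths` discovers paths by repeated
uniform random walks, the data-preparation method used to build instances at
scale.  Every sampled path is, by construction, a member of the exhaustive
set for the same bound.

:func:`build_instances` turns labeled triples into query instances, attaching
the discovered path set of each entity pair.  The pair's own direct edge for
the query relation is excluded from every path so that the label never leaks
into the evidence.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .kg_core import INVERSE_SUFFIX, KnowledgeGraph, Triple

logger = logging.getLogger(__name__)

__all__ = [
    "Path",
    "PathSet",
    "QueryInstance",
    "enumerate_paths",
    "random_walk_paths",
    "build_instances",
    "write_instances",
    "read_instances",
]


@dataclass(frozen=True)
class Path:
    """An alternating relation/entity sequence from ``source`` to ``target``.

    ``steps`` holds ``(relation, entity)`` hops; the last hop's entity is the
    target.  Length is the number of relations.
    """

    source: str
    target: str
    steps: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a path must contain at least one hop")
        if self.steps[-1][1] != self.target:
            raise ValueError("last hop must end at the target entity")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def relations(self) -> tuple[str, ...]:
        return tuple(r for r, _ in self.steps)

    @property
    def entities(self) -> tuple[str, ...]:
        """All entities on the path, source first, target last."""
        return (self.source,) + tuple(e for _, e in self.steps)

    def path_type(self) -> tuple[str, ...]:
        """The relation sequence — the PRA 'path type' feature identity."""
        return self.relations

    def as_flat(self) -> list[str]:
        flat: list[str] = []
        for r, e in self.steps:
            flat.extend((r, e))
        return flat

    @staticmethod
    def from_flat(source: str, flat: Sequence[str]) -> "Path":
        if len(flat) % 2 != 0 or not flat:
            raise ValueError("flat path must be a non-empty even-length list")
        steps = tuple((flat[i], flat[i + 1]) for i in range(0, len(flat), 2))
        return Path(source=source, target=steps[-1][1], steps=steps)


@dataclass
class PathSet:
    """Deduplicated paths between one entity pair, shortest first."""

    source: str
    target: str
    paths: list[Path] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.paths)

    def truncated(self, max_paths: int) -> "PathSet":
        """Keep at most ``max_paths`` paths, shortest (then lexicographic) first."""
        kept = sorted(self.paths, key=lambda p: (len(p), p.as_flat()))[:max_paths]
        return PathSet(self.source, self.target, kept)


@dataclass
class QueryInstance:
    """One (source, query relation, target) judgment with its path evidence."""

    source: str
    relation: str
    target: str
    label: int
    paths: list[Path] = field(default_factory=list)

    @property
    def instance_id(self) -> str:
        return f"{self.source}|{self.relation}|{self.target}"


def _check_entities(kg: KnowledgeGraph, *entity_ids: str) -> None:
    for eid in entity_ids:
        if not kg.has_entity(eid):
            raise KeyError(f"unknown entity: {eid!r}")


def _multigraph(kg: KnowledgeGraph) -> nx.MultiDiGraph:
    # Cached on the graph instance: adjacency is immutable after build.
    g = getattr(kg, "_nx_cache", None)
    if g is None:
        g = nx.MultiDiGraph()
        g.add_nodes_from(kg.entities)
        for eid in kg.entities:
            for rel, nbr in kg.neighbors(eid):
                g.add_edge(eid, nbr, key=rel)
        kg._nx_cache = g  # type: ignore[attr-defined]
    return g


def _forbidden(exclude_triple: Triple | None) -> set[tuple[str, str, str]]:
    if exclude_triple is None:
        return set()
    t = exclude_triple
    return {
        (t.head, t.relation, t.tail),
        (t.tail, t.relation + INVERSE_SUFFIX, t.head),
    }


def enumerate_paths(
    kg: KnowledgeGraph,
    e_s: str,
    e_t: str,
    max_len: int,
    exclude_triple: Triple | None = None,
) -> PathSet:
    """All simple paths (no repeated entity) from ``e_s`` to ``e_t`` of
    length <= ``max_len``, by exhaustive bounded search.

    ``exclude_triple`` removes one specific edge (and its inverse) from the
    searched graph — used to hide a query's own direct edge.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    _check_entities(kg, e_s, e_t)
    paths: list[Path] = []
    if e_s == e_t:
        return PathSet(e_s, e_t, paths)
    g = _multigraph(kg)
    banned = _forbidden(exclude_triple)
    for edge_path in nx.all_simple_edge_paths(g, e_s, e_t, cutoff=max_len):
        steps = tuple((key, v) for (_, v, key) in edge_path)
        if banned and any((u, key, v) in banned for (u, v, key) in edge_path):
            continue
        paths.append(Path(e_s, e_t, steps))
    uniq = sorted(set(paths), key=lambda p: (len(p), p.as_flat()))
    return PathSet(e_s, e_t, uniq)


class _WalkIndex:
    """Integer-indexed CSR adjacency for vectorized random walks."""

    def __init__(self, kg: KnowledgeGraph) -> None:
        self.entity_ids = sorted(kg.entities)
        self.entity_index = {e: i for i, e in enumerate(self.entity_ids)}
        rel_set = sorted(kg.relations)
        self.relation_ids = rel_set
        self.relation_index = {r: i for i, r in enumerate(rel_set)}
        offsets = [0]
        rel_flat: list[int] = []
        nbr_flat: list[int] = []
        for eid in self.entity_ids:
            for rel, nbr in kg.neighbors(eid):
                rel_flat.append(self.relation_index[rel])
                nbr_flat.append(self.entity_index[nbr])
            offsets.append(len(rel_flat))
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.rel_flat = np.asarray(rel_flat, dtype=np.int64)
        self.nbr_flat = np.asarray(nbr_flat, dtype=np.int64)
        self.degrees = np.diff(self.offsets)


def _walk_index(kg: KnowledgeGraph) -> _WalkIndex:
    idx = getattr(kg, "_walk_index_cache", None)
    if idx is None:
        idx = _WalkIndex(kg)
        kg._walk_index_cache = idx  # type: ignore[attr-defined]
    return idx


def random_walk_paths(
    kg: KnowledgeGraph,
    e_s: str,
    e_t: str,
    max_len: int,
    n_walks: int = 200,
    seed: int = 0,
    exclude_triple: Triple | None = None,
) -> PathSet:
    """Discover simple paths by ``n_walks`` uniform random walks from ``e_s``.

    Each walk repeatedly chooses uniformly among the current entity's
    outgoing edges; it ends at a dead end (restart), on reaching ``e_t``
    (recording the walked prefix), or after ``max_len`` steps.  Walked
    prefixes that revisit an entity are discarded, so every returned path is
    simple and a member of the exhaustive enumeration for the same bound.
    Duplicates collapse; deterministic given the seed.  Walks are batched
    over integer-indexed adjacency so tens of thousands per pair stay cheap.
    """
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    _check_entities(kg, e_s, e_t)
    if e_s == e_t:
        return PathSet(e_s, e_t, [])
    idx = _walk_index(kg)
    rng = np.random.default_rng(seed)
    s, t = idx.entity_index[e_s], idx.entity_index[e_t]
    banned = _forbidden(exclude_triple)
    banned_int = {
        (idx.entity_index[u], idx.relation_index[r], idx.entity_index[v])
        for u, r, v in banned
        if u in idx.entity_index and r in idx.relation_index
        and v in idx.entity_index
    }

    cur = np.full(n_walks, s, dtype=np.int64)
    alive = np.ones(n_walks, dtype=bool)
    # (relation, entity) hop trace per walk
    trace = np.full((n_walks, max_len, 2), -1, dtype=np.int64)
    hit_at = np.full(n_walks, -1, dtype=np.int64)
    for step in range(max_len):
        deg = idx.degrees[cur]
        alive &= deg > 0
        if not alive.any():
            break
        live = np.flatnonzero(alive)
        pick = idx.offsets[cur[live]] + rng.integers(0, deg[live])
        rel, nbr = idx.rel_flat[pick], idx.nbr_flat[pick]
        if banned_int:
            # reject the excluded edge by redrawing a few times, then kill
            for _ in range(4):
                bad = np.array([
                    (u, r, v) in banned_int
                    for u, r, v in zip(cur[live], rel, nbr)
                ])
                if not bad.any():
                    break
                bidx = np.flatnonzero(bad)
                redraw = idx.offsets[cur[live[bidx]]] + rng.integers(
                    0, idx.degrees[cur[live[bidx]]])
                rel[bidx], nbr[bidx] = idx.rel_flat[redraw], idx.nbr_flat[redraw]
            else:
                still = np.array([
                    (u, r, v) in banned_int
                    for u, r, v in zip(cur[live], rel, nbr)
                ])
                alive[live[still]] = False
                live = live[~still]
                rel, nbr = rel[~still], nbr[~still]
        trace[live, step, 0] = rel
        trace[live, step, 1] = nbr
        arrived = nbr == t
        hit_at[live[arrived]] = step
        alive[live[arrived]] = False
        cur[live] = nbr

    found: set[Path] = set()
    for w in np.flatnonzero(hit_at >= 0):
        k = hit_at[w] + 1
        hops = trace[w, :k]
        nodes = [s] + hops[:, 1].tolist()
        if len(set(nodes)) != len(nodes):
            continue  # revisit: not a simple path
        steps = tuple(
            (idx.relation_ids[r], idx.entity_ids[e]) for r, e in hops
        )
        found.add(Path(e_s, e_t, steps))
    uniq = sorted(found, key=lambda p: (len(p), p.as_flat()))
    return PathSet(e_s, e_t, uniq)


def _pair_seed(seed: int, triple: Triple) -> int:
    key = f"{seed}|{triple.head}|{triple.relation}|{triple.tail}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def build_instances(
    kg: KnowledgeGraph,
    triples: Iterable[Triple],
    max_len: int = 7,
    n_walks: int = 200,
    max_paths: int = 622,
    seed: int = 0,
    label: int = 1,
    exclude_direct: bool = True,
) -> list[QueryInstance]:
    """One :class:`QueryInstance` per triple, with its sampled path set.

    The query's own direct edge is excluded from every path (label-leakage
    guard).  Pairs with zero discovered paths are dropped with a logged
    count.  Path sets are truncated to ``max_paths``, shortest paths first.
    """
    instances: list[QueryInstance] = []
    dropped = 0
    for t in sorted(set(triples)):
        exclude = t if exclude_direct else None
        ps = random_walk_paths(
            kg, t.head, t.tail, max_len=max_len, n_walks=n_walks,
            seed=_pair_seed(seed, t), exclude_triple=exclude,
        ).truncated(max_paths)
        if not ps.paths:
            dropped += 1
            continue
        instances.append(
            QueryInstance(t.head, t.relation, t.tail, label=label, paths=ps.paths)
        )
    if dropped:
        logger.info("dropped %d pairs with zero discovered paths", dropped)
    return instances


# -- serialization (JSON Lines) -----------------------------------------


def write_instances(instances: Iterable[QueryInstance], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            obj = {
                "source": inst.source,
                "target": inst.target,
                "relation": inst.relation,
                "label": inst.label,
                "paths": [p.as_flat() for p in inst.paths],
            }
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def read_instances(path) -> list[QueryInstance]:
    out: list[QueryInstance] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            paths = [Path.from_flat(obj["source"], flat) for flat in obj["paths"]]
            out.append(
                QueryInstance(
                    obj["source"], obj["relation"], obj["target"],
                    label=int(obj["label"]), paths=paths,
                )
            )
    return out
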