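"""Path-scoring models for knowledge-graph relation prediction.

The model ladder, from baseline to the text-enhanced contributions:

* **PRA** — each distinct relation sequence ("path type") between a pair is
  a binary feature; a logistic classifier scores the pair.
* **Path-RNN / Single-Model** — an RNN folds each path's relation (and
  optionally entity-type) embeddings into a path vector π; per-path match
  scores against the query relation δ are pooled with LogSumExp.
* **Att-Model** — the same path vectors pooled with softmax attention:
  z_i = tanh(π_i T)·δ, α = softmax(z), ep = tanh(Σ α_i π_i), p = σ(ep·δ).
* **Text-enhanced entity representation** — each entity's verbalized
  statement is encoded to a [CLS] vector C and concatenated with its mean
  type embedding, projected back to the type width, before entering the RNN.
* **Text-enhanced path representation** — the whole path is verbalized and
  encoded; π is a linear projection of the statement vector, skipping the
  RNN entirely.

The RNN consumes, at step t, the previous hidden state, a relation embedding
and an entity representation: h_t = ReLU(W1 h_{t-1} + W2 r_{t-1} + W3 e_{t-1}),
with a learned dummy relation at the first step (there is no incoming
relation at the source entity) so that an L-hop path unrolls over L+1 steps
consuming every relation and entity on the path.

Public functions operate on plain NumPy arrays and mirror, operation by
operation, the :class:`PathScorer` training graph built on the autodiff
engine; tests hold the two routes together.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path as FilePath

import numpy as np
from scipy.special import expit
from scipy.special import logsumexp as _scipy_logsumexp

from . import autodiff as ad
from .kg_core import Entity, KnowledgeGraph
from .path_sampler import Path, QueryInstance
from .text_encoder import EncodedText
from .verbalizer import DEFAULT_TEMPLATES, TemplateSet, entity_statement, path_statement

logger = logging.getLogger(__name__)

DUMMY_RELATION = "__dummy__"

__all__ = [
    "DUMMY_RELATION",
    "ModelConfig",
    "ModelParams",
    "PairContext",
    "rnn_step",
    "entity_representation",
    "encode_path_rnn",
    "encode_path_text",
    "path_match_score",
    "attention_weights",
    "combine_paths",
    "logsumexp_pool",
    "score_pair",
    "PathScorer",
    "PRAFeatureIndex",
    "pra_features",
    "pra_score",
    "PRAModel",
    "make_model",
]


@dataclass
class ModelConfig:
    """Widths and architectural switches.

    d — relation/hidden width; k — entity-type embedding width; H — text
    encoder width; pooling — ``attention`` or ``logsumexp``; entity_mode —
    ``none`` (shared constant entity vector), ``types`` (mean type
    embedding) or ``types_plus_text``; path_mode — ``rnn`` or ``text``.
    """

    d: int = 50
    k: int = 50
    H: int = 32
    pooling: str = "attention"
    entity_mode: str = "types"
    path_mode: str = "rnn"
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if min(self.d, self.k, self.H) < 1:
            raise ValueError("d, k, H must be >= 1")
        if self.pooling not in ("attention", "logsumexp"):
            raise ValueError(f"unknown pooling: {self.pooling!r}")
        if self.entity_mode not in ("none", "types", "types_plus_text"):
            raise ValueError(f"unknown entity_mode: {self.entity_mode!r}")
        if self.path_mode not in ("rnn", "text"):
            raise ValueError(f"unknown path_mode: {self.path_mode!r}")


#: Named model presets mirroring the comparative-experiment ladder.
MODEL_PRESETS: dict[str, dict] = {
    "path-rnn": dict(pooling="logsumexp", entity_mode="none", path_mode="rnn"),
    "single": dict(pooling="logsumexp", entity_mode="none", path_mode="rnn"),
    "single-types": dict(pooling="logsumexp", entity_mode="types", path_mode="rnn"),
    "att": dict(pooling="attention", entity_mode="none", path_mode="rnn"),
    "att-types": dict(pooling="attention", entity_mode="types", path_mode="rnn"),
    "text-entity": dict(pooling="attention", entity_mode="types_plus_text",
                        path_mode="rnn"),
    "text-path": dict(pooling="attention", entity_mode="none", path_mode="text"),
}


class ModelParams:
    """All learned arrays plus the vocabulary index maps.

    Arrays (name → shape): ``relation_emb`` (R, d) including the dummy
    relation; ``type_emb`` (Ty, k); ``entity_shared`` (k,); ``query_emb``
    (Q, d); ``W1`` (d, d); ``W2`` (d, d); ``W3`` (d, k); ``T`` (d, d);
    ``P_ent`` (k+H, k); ``P_path`` (H, d).  Initialization is
    uniform(-init_scale, init_scale), seeded.
    """

    WEIGHT_MATRICES = ("W1", "W2", "W3", "T", "P_ent", "P_path", "pra_w")

    def __init__(self, config: ModelConfig, relation_index: dict[str, int],
                 type_index: dict[str, int], query_index: dict[str, int],
                 arrays: dict[str, np.ndarray]) -> None:
        self.config = config
        self.relation_index = relation_index
        self.type_index = type_index
        self.query_index = query_index
        self.arrays = arrays
        for name, arr in arrays.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"parameter {name} contains non-finite entries")

    def __getattr__(self, name: str) -> np.ndarray:
        arrays = self.__dict__.get("arrays", {})
        if name in arrays:
            return arrays[name]
        raise AttributeError(name)

    @classmethod
    def initialize(
        cls,
        config: ModelConfig,
        relation_ids: list[str],
        type_labels: list[str],
        query_relations: list[str],
        seed: int = 0,
    ) -> "ModelParams":
        rng = np.random.default_rng(seed)
        rel_vocab = [DUMMY_RELATION] + sorted(set(relation_ids) - {DUMMY_RELATION})
        relation_index = {r: i for i, r in enumerate(rel_vocab)}
        type_index = {t: i for i, t in enumerate(sorted(set(type_labels)))}
        query_index = {q: i for i, q in enumerate(sorted(set(query_relations)))}
        s = config.init_scale
        d, k, H = config.d, config.k, config.H

        def u(*shape):
            return rng.uniform(-s, s, size=shape)

        arrays = {
            "relation_emb": u(len(relation_index), d),
            "type_emb": u(max(len(type_index), 1), k),
            "entity_shared": u(k),
            "query_emb": u(max(len(query_index), 1), d),
            "W1": u(d, d),
            "W2": u(d, d),
            "W3": u(d, k),
            "T": u(d, d),
            "P_ent": u(k + H, k),
            "P_path": u(H, d),
        }
        return cls(config, relation_index, type_index, query_index, arrays)

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.config, dict(self.relation_index), dict(self.type_index),
            dict(self.query_index), {n: a.copy() for n, a in self.arrays.items()},
        )

    # -- checkpointing ---------------------------------------------------

    def save(self, directory) -> None:
        out = FilePath(directory)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "relation_index": self.relation_index,
            "type_index": self.type_index,
            "query_index": self.query_index,
            "arrays": sorted(self.arrays),
        }
        (out / "config.json").write_text(json.dumps(meta, indent=2))
        for name, arr in self.arrays.items():
            np.save(out / f"{name}.npy", arr)

    @classmethod
    def load(cls, directory) -> "ModelParams":
        src = FilePath(directory)
        meta = json.loads((src / "config.json").read_text())
        config = ModelConfig(**meta["config"])
        arrays = {name: np.load(src / f"{name}.npy") for name in meta["arrays"]}
        return cls(config, meta["relation_index"], meta["type_index"],
                   meta["query_index"], arrays)


@dataclass
class PairContext:
    """Pooled entity-pair context vector plus the per-path attention."""

    vector: np.ndarray
    attention: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.max(np.abs(self.vector)) > 1.0 + 1e-12:
            raise ValueError("pair context entries must lie in [-1, 1]")
        if self.attention is not None:
            a = np.asarray(self.attention, dtype=float)
            if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-9:
                raise ValueError("attention weights must be a distribution")
            self.attention = a


# -- functional forward pass (NumPy) ------------------------------------


def rnn_step(h_prev: np.ndarray, r_prev: np.ndarray, e_prev: np.ndarray,
             params: ModelParams) -> np.ndarray:
    """One recurrence: ReLU(W1 h_{t-1} + W2 r_{t-1} + W3 e_{t-1})."""
    W1, W2, W3 = params.W1, params.W2, params.W3
    if h_prev.shape != (W1.shape[1],) or r_prev.shape != (W2.shape[1],) \
            or e_prev.shape != (W3.shape[1],):
        raise ValueError("rnn_step: input shapes do not conform to W1/W2/W3")
    return np.maximum(W1 @ h_prev + W2 @ r_prev + W3 @ e_prev, 0.0)


def _mean_type_embedding(entity: Entity, params: ModelParams) -> np.ndarray:
    rows = [params.type_emb[params.type_index[t]] for t in entity.types
            if t in params.type_index]
    if not rows:
        return np.zeros(params.config.k)
    return np.mean(rows, axis=0)


def entity_representation(entity: Entity, params: ModelParams,
                          config: ModelConfig, encoder=None,
                          templates: TemplateSet = DEFAULT_TEMPLATES) -> np.ndarray:
    """k-vector for an entity under the configured entity mode.

    ``types``: mean of type embeddings (zeros when typeless).
    ``types_plus_text``: the mean type embedding concatenated with the
    entity statement's encoded [CLS] vector, projected back to k.
    """
    if config.entity_mode == "none":
        return params.entity_shared
    mean_types = _mean_type_embedding(entity, params)
    if config.entity_mode == "types":
        return mean_types
    if encoder is None:
        raise ValueError("entity_mode=types_plus_text requires an encoder")
    C = encoder.encode(entity_statement(entity, templates)).vector
    return np.concatenate([mean_types, C]) @ params.P_ent


def _rnn_inputs(path: Path) -> list[tuple[str, str]]:
    """(relation, entity) pairs consumed by the RNN: dummy+source first."""
    return [(DUMMY_RELATION, path.source)] + list(path.steps)


def encode_path_rnn(path: Path, kg: KnowledgeGraph, params: ModelParams,
                    config: ModelConfig, encoder=None,
                    templates: TemplateSet = DEFAULT_TEMPLATES) -> np.ndarray:
    """Fold the RNN along the path; the final hidden state is π."""
    h = np.zeros(config.d)
    for rel, eid in _rnn_inputs(path):
        if rel not in params.relation_index:
            raise KeyError(f"unknown relation on path: {rel!r}")
        r = params.relation_emb[params.relation_index[rel]]
        e = entity_representation(kg.entity(eid), params, config, encoder, templates)
        h = rnn_step(h, r, e, params)
    return h


def encode_path_text(path: Path, kg: KnowledgeGraph, params: ModelParams,
                     config: ModelConfig, encoder,
                     templates: TemplateSet = DEFAULT_TEMPLATES) -> np.ndarray:
    """π = projection of the encoded path statement (H → d)."""
    C = encoder.encode(path_statement(path, kg, templates)).vector
    return C @ params.P_path


def path_match_score(pi: np.ndarray, delta: np.ndarray,
                     params: ModelParams) -> float:
    """z = tanh(π T) · δ — how well a path matches the query relation."""
    T = params.T
    if pi.shape != (T.shape[0],) or delta.shape != (T.shape[1],):
        raise ValueError("path_match_score: shapes do not conform to T")
    return float(np.tanh(pi @ T) @ delta)


def attention_weights(z) -> np.ndarray:
    """Softmax over per-path match scores, max-stabilized."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("attention over an empty score list")
    if not np.all(np.isfinite(z)):
        raise ValueError("attention scores must be finite")
    e = np.exp(z - z.max())
    return e / e.sum()


def combine_paths(path_reps, alpha, activation=np.tanh) -> PairContext:
    """ep = tanh(Σ α_i π_i); the attention is stored in the result."""
    alpha = np.asarray(alpha, dtype=float)
    if len(path_reps) != len(alpha):
        raise ValueError("path_reps and alpha length mismatch")
    weighted = sum(a * p for a, p in zip(alpha, path_reps))
    return PairContext(vector=activation(weighted), attention=alpha)


def logsumexp_pool(z) -> float:
    """Smooth-maximum pooling of per-path scores."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("logsumexp over an empty score list")
    return float(_scipy_logsumexp(z))


def _path_vector(path: Path, kg: KnowledgeGraph, params: ModelParams,
                 config: ModelConfig, encoder, templates) -> np.ndarray:
    if config.path_mode == "text":
        return encode_path_text(path, kg, params, config, encoder, templates)
    return encode_path_rnn(path, kg, params, config, encoder, templates)


def score_pair(instance: QueryInstance, params: ModelParams, config: ModelConfig,
               encoder=None, kg: KnowledgeGraph | None = None,
               templates: TemplateSet = DEFAULT_TEMPLATES) -> float:
    """Probability that the query relation holds for the entity pair.

    Attention pooling: σ(ep·δ) with ep from the attention combiner.
    LogSumExp pooling: σ(LSE_i(π_i·δ)).
    """
    if not instance.paths:
        raise ValueError("score_pair requires at least one path")
    if kg is None:
        raise ValueError("score_pair requires the knowledge graph for lookups")
    delta = params.query_emb[params.query_index[instance.relation]]
    pis = [_path_vector(p, kg, params, config, encoder, templates)
           for p in instance.paths]
    if config.pooling == "attention":
        z = [path_match_score(pi, delta, params) for pi in pis]
        ep = combine_paths(pis, attention_weights(z))
        return float(expit(ep.vector @ delta))
    scores = [float(pi @ delta) for pi in pis]
    return float(expit(logsumexp_pool(scores)))


# -- trainable scorer (autodiff graph) -----------------------------------


class PathScorer:
    """Trainable model: the autodiff twin of the functional forward pass.

    Leaf tensors wrap the :class:`ModelParams` arrays in place, so optimizer
    updates through the leaves mutate the checkpointable arrays directly.
    """

    def __init__(self, config: ModelConfig, kg: KnowledgeGraph, encoder=None,
                 templates: TemplateSet = DEFAULT_TEMPLATES, seed: int = 0,
                 query_relations: list[str] | None = None,
                 params: ModelParams | None = None) -> None:
        self.config = config
        self.kg = kg
        self.encoder = encoder
        self.templates = templates
        if params is None:
            relation_ids = sorted(kg.relations)
            type_labels = sorted({t for e in kg.entities.values() for t in e.types})
            queries = query_relations or kg.relation_ids()
            params = ModelParams.initialize(config, relation_ids, type_labels,
                                            queries, seed=seed)
        self.params = params
        self.leaves = {name: ad.Tensor(arr) for name, arr in params.arrays.items()}
        self._text_cache: dict[str, np.ndarray] = {}

    # names whose squared L2 norm enters the regularizer
    @property
    def weight_decay_names(self) -> list[str]:
        names = ["W1", "W2", "W3", "T"]
        if self.config.entity_mode == "types_plus_text":
            names.append("P_ent")
        if self.config.path_mode == "text":
            names.append("P_path")
        return names

    def zero_grad(self) -> None:
        for leaf in self.leaves.values():
            leaf.zero_grad()

    def _encode_text(self, text: str) -> np.ndarray:
        vec = self._text_cache.get(text)
        if vec is None:
            vec = self.encoder.encode(text).vector
            self._text_cache[text] = vec
        return vec

    def _entity_tensor(self, eid: str, cache: dict) -> ad.Tensor:
        node = cache.get(eid)
        if node is not None:
            return node
        cfg, params = self.config, self.params
        if cfg.entity_mode == "none":
            node = self.leaves["entity_shared"]
        else:
            entity = self.kg.entity(eid)
            rows = [ad.take_row(self.leaves["type_emb"], params.type_index[t])
                    for t in entity.types if t in params.type_index]
            if rows:
                mean_types = rows[0]
                for r in rows[1:]:
                    mean_types = mean_types + r
                mean_types = mean_types * (1.0 / len(rows))
            else:
                mean_types = ad.constant(np.zeros(cfg.k))
            if cfg.entity_mode == "types":
                node = mean_types
            else:
                C = ad.constant(
                    self._encode_text(entity_statement(entity, self.templates))
                )
                node = ad.concat(mean_types, C) @ self.leaves["P_ent"]
        cache[eid] = node
        return node

    def _path_matrix(self, paths: list[Path]) -> ad.Tensor:
        """All path vectors of one instance as an (n_paths, d) node.

        RNN paths are batched in cohorts of equal length so each recurrence
        step is a single matrix product; the per-path math is identical to
        the functional :func:`encode_path_rnn`.
        """
        cfg, params = self.config, self.params
        if cfg.path_mode == "text":
            C = ad.constant(np.stack([
                self._encode_text(path_statement(p, self.kg, self.templates))
                for p in paths
            ]))
            return C @ self.leaves["P_path"]
        ent_cache: dict = {}
        W1T = ad.transpose(self.leaves["W1"])
        W2T = ad.transpose(self.leaves["W2"])
        W3T = ad.transpose(self.leaves["W3"])
        cohorts: dict[int, list[int]] = {}
        for i, p in enumerate(paths):
            cohorts.setdefault(len(p), []).append(i)
        rows: list[ad.Tensor | None] = [None] * len(paths)
        for length, idxs in sorted(cohorts.items()):
            seqs = [_rnn_inputs(paths[i]) for i in idxs]
            H: ad.Tensor = ad.constant(np.zeros((len(idxs), cfg.d)))
            for t in range(length + 1):
                rel_ids = []
                for seq in seqs:
                    rel = seq[t][0]
                    if rel not in params.relation_index:
                        raise KeyError(f"unknown relation on path: {rel!r}")
                    rel_ids.append(params.relation_index[rel])
                R = ad.gather(self.leaves["relation_emb"], rel_ids)
                E = ad.stack([self._entity_tensor(seq[t][1], ent_cache)
                              for seq in seqs])
                H = ad.relu((H @ W1T) + (R @ W2T) + (E @ W3T))
            for row, i in enumerate(idxs):
                rows[i] = ad.index(H, row)
        return ad.stack(rows)  # type: ignore[arg-type]

    def logit(self, instance: QueryInstance) -> ad.Tensor:
        """The pre-sigmoid pair score as a graph node."""
        if not instance.paths:
            raise ValueError("cannot score an instance with zero paths")
        delta = ad.take_row(self.leaves["query_emb"],
                            self.params.query_index[instance.relation])
        Pi = self._path_matrix(instance.paths)
        if self.config.pooling == "attention":
            z = ad.tanh(Pi @ self.leaves["T"]) @ delta
            alpha = ad.softmax(z)
            ep = ad.tanh(alpha @ Pi)
            return ad.dot(ep, delta)
        return ad.logsumexp(Pi @ delta)

    def score(self, instance: QueryInstance) -> float:
        """Probability in (0, 1); no gradient bookkeeping retained."""
        return float(expit(self.logit(instance).item()))

    def attention(self, instance: QueryInstance) -> np.ndarray:
        """Per-path attention weights (attention pooling only)."""
        if self.config.pooling != "attention":
            raise ValueError("attention weights require attention pooling")
        delta = self.params.query_emb[self.params.query_index[instance.relation]]
        Pi = self._path_matrix(instance.paths).value
        z = [path_match_score(pi, delta, self.params) for pi in Pi]
        return attention_weights(z)


# -- PRA baseline --------------------------------------------------------


class PRAFeatureIndex:
    """Maps each observed relation sequence (path type) to a feature column."""

    def __init__(self, columns: dict[tuple[str, ...], int]) -> None:
        self.columns = columns
        self.n_unseen = 0

    @classmethod
    def from_instances(cls, instances) -> "PRAFeatureIndex":
        types = sorted({p.path_type() for inst in instances for p in inst.paths})
        return cls({t: i for i, t in enumerate(types)})

    @property
    def n_features(self) -> int:
        return len(self.columns)


def pra_features(instance: QueryInstance, feature_index: PRAFeatureIndex) -> np.ndarray:
    """Binary path-type indicator vector; unseen types contribute 0 (logged)."""
    x = np.zeros(feature_index.n_features)
    for p in instance.paths:
        col = feature_index.columns.get(p.path_type())
        if col is None:
            feature_index.n_unseen += 1
            logger.debug("unseen path type at scoring time: %r", p.path_type())
            continue
        x[col] = 1.0
    return x


def pra_score(instance: QueryInstance, feature_index: PRAFeatureIndex,
              weights: tuple[np.ndarray, float]) -> float:
    """σ(w·x + b) over the binary path-type features."""
    w, b = weights
    return float(expit(w @ pra_features(instance, feature_index) + float(b)))


class PRAModel:
    """PRA baseline exposed through the same trainable-scorer interface."""

    config = ModelConfig(pooling="logsumexp", entity_mode="none", path_mode="rnn")

    def __init__(self, feature_index: PRAFeatureIndex, seed: int = 0) -> None:
        self.feature_index = feature_index
        rng = np.random.default_rng(seed)
        self.arrays = {
            "pra_w": rng.uniform(-0.1, 0.1, size=feature_index.n_features),
            "pra_b": np.zeros(()),
        }
        self.leaves = {name: ad.Tensor(arr) for name, arr in self.arrays.items()}

    @property
    def weight_decay_names(self) -> list[str]:
        return ["pra_w"]

    def zero_grad(self) -> None:
        for leaf in self.leaves.values():
            leaf.zero_grad()

    def logit(self, instance: QueryInstance) -> ad.Tensor:
        x = ad.constant(pra_features(instance, self.feature_index))
        return ad.dot(self.leaves["pra_w"], x) + self.leaves["pra_b"]

    def score(self, instance: QueryInstance) -> float:
        return float(expit(self.logit(instance).item()))


def make_model(name: str, kg: KnowledgeGraph, encoder=None,
               templates: TemplateSet = DEFAULT_TEMPLATES, seed: int = 0,
               train_instances=None, d: int = 50, k: int = 50,
               H: int | None = None):
    """Build a model by preset name (``pra`` or a :data:`MODEL_PRESETS` key)."""
    if name == "pra":
        if train_instances is None:
            raise ValueError("PRA needs training instances to build its features")
        return PRAModel(PRAFeatureIndex.from_instances(train_instances), seed=seed)
    if name not in MODEL_PRESETS:
        raise ValueError(f"unknown model {name!r}; choose from "
                         f"{['pra'] + sorted(MODEL_PRESETS)}")
    H = H if H is not None else (encoder.H if encoder is not None else 32)
    config = ModelConfig(d=d, k=k, H=H, **MODEL_PRESETS[name])
    return PathScorer(config, kg, encoder=encoder, templates=templates, seed=seed)
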