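"""Negative sampling, loss, Adam optimization, early stopping, grid search.

Negatives are built once, up front, by corrupting true triples: one of
head / tail / relation is replaced, and — to make negatives hard — an entity
slot is refilled, with configurable probability (default 0.7), from the pool
of entities that participate in the same slot of the query relation rather
than from the whole entity set.  Corruptions that collide with a known true
triple are rejected and resampled.

Training minimizes the negative log-likelihood of the labeled instances plus
an L2 penalty on the weight matrices, with Adam at a constant learning rate.
A single model is trained for all query relations.  Early stopping watches
dev accuracy; the returned checkpoint is the best-dev-MAP epoch.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from . import autodiff as ad
from .kg_core import KnowledgeGraph, Triple, relation_participants
from .path_sampler import QueryInstance

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "LabeledSets",
    "CorruptionStats",
    "corrupt_triple",
    "make_negatives",
    "nll_loss",
    "Adam",
    "train_model",
    "grid_search",
]


@dataclass
class TrainConfig:
    """Optimizer and sampling settings (defaults follow the study protocol:
    batch 64, learning rate 1e-3, λ=1e-5, Adam β=(0.9, 0.999), ε=1e-8,
    100-epoch cap, stop when dev accuracy gains < 0.01 over 10 epochs,
    70% same-relation corruption bias, ≈0.75 negatives per positive)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    l2_lambda: float = 1e-5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    same_relation_prob: float = 0.7
    neg_ratio: float = 0.75
    patience_epochs: int = 10
    min_improve: float = 0.01
    resample_negatives: bool = False
    #: evaluate dev metrics every k-th epoch (and always on the last);
    #: skipped epochs record None.  Early stopping only advances on
    #: evaluated epochs.
    dev_eval_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.same_relation_prob <= 1.0):
            raise ValueError("same_relation_prob must lie in [0, 1]")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning rate, batch size and epochs must be positive")


@dataclass
class LabeledSets:
    """Positive and negative query instances for one split."""

    positives: list[QueryInstance] = field(default_factory=list)
    negatives: list[QueryInstance] = field(default_factory=list)

    @property
    def all(self) -> list[QueryInstance]:
        return list(self.positives) + list(self.negatives)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


@dataclass
class CorruptionStats:
    """Counters over corruption draws (for bias diagnostics)."""

    n_entity_draws: int = 0
    n_same_pool: int = 0
    n_uniform: int = 0
    n_fallback: int = 0

    @property
    def same_pool_fraction(self) -> float:
        return self.n_same_pool / max(self.n_entity_draws, 1)


def corrupt_triple(
    triple: Triple,
    kg: KnowledgeGraph,
    corrupt_slot: str,
    rng: np.random.Generator,
    same_relation_prob: float = 0.7,
    stats: CorruptionStats | None = None,
    max_tries: int = 200,
) -> Triple:
    """Corrupt exactly one slot of a true triple into a filtered negative.

    When an entity slot is corrupted, with probability ``same_relation_prob``
    the replacement is drawn from the entities filling that slot of the same
    relation (minus the original); otherwise — or when that pool is empty
    (logged fallback) — uniformly from all entities.  Results colliding with
    a known true triple are rejected and resampled.
    """
    if corrupt_slot not in ("head", "tail", "relation"):
        raise ValueError(f"corrupt_slot must be head|tail|relation: {corrupt_slot!r}")
    all_entities = sorted(kg.entities)
    if corrupt_slot == "relation":
        pool = [r for r in kg.relation_ids() if r != triple.relation]
        if not pool:
            raise ValueError("cannot corrupt the relation of a 1-relation graph")
        for _ in range(max_tries):
            new = Triple(triple.head, pool[rng.integers(len(pool))], triple.tail)
            if new != triple and not kg.has_triple(new):
                return new
        raise RuntimeError("could not find a filtered relation corruption")

    original = triple.head if corrupt_slot == "head" else triple.tail
    same_pool = sorted(
        relation_participants(kg, triple.relation, corrupt_slot) - {original}
    )
    for _ in range(max_tries):
        use_same = same_pool and rng.random() < same_relation_prob
        if same_pool:
            pool = same_pool if use_same else all_entities
        else:
            pool = all_entities  # degenerate same-relation pool: fall back
        # the audit counts draw *decisions*: rejected candidates (collisions
        # with true triples) are redrawn, and same-pool candidates collide
        # more often, so counting only accepted draws would understate the
        # configured bias
        if stats is not None:
            stats.n_entity_draws += 1
            if not same_pool:
                stats.n_fallback += 1
                stats.n_uniform += 1
            elif use_same:
                stats.n_same_pool += 1
            else:
                stats.n_uniform += 1
        replacement = pool[rng.integers(len(pool))]
        if replacement == original:
            continue
        if corrupt_slot == "head":
            new = Triple(replacement, triple.relation, triple.tail)
        else:
            new = Triple(triple.head, triple.relation, replacement)
        if kg.has_triple(new):
            continue
        if not same_pool:
            logger.debug("same-relation pool empty; uniform fallback for %r", triple)
        return new
    raise RuntimeError(f"could not corrupt {triple!r} into a filtered negative")


def make_negatives(
    kg: KnowledgeGraph,
    positives: Sequence[Triple],
    rng: np.random.Generator,
    neg_ratio: float = 0.75,
    same_relation_prob: float = 0.7,
    stats: CorruptionStats | None = None,
) -> list[Triple]:
    """Corrupt randomly chosen positives into ``round(ratio·n)`` distinct
    negatives; the corrupted slot is uniform over head/tail/relation."""
    if not positives:
        return []
    slots = ("head", "tail", "relation")
    target = int(round(neg_ratio * len(positives)))
    negatives: set[Triple] = set()
    attempts = 0
    while len(negatives) < target and attempts < 50 * max(target, 1):
        attempts += 1
        t = positives[rng.integers(len(positives))]
        slot = slots[rng.integers(3)]
        try:
            negatives.add(corrupt_triple(t, kg, slot, rng,
                                         same_relation_prob, stats))
        except (RuntimeError, ValueError):
            continue
    return sorted(negatives)


def nll_loss(scores, labels, params=None, l2_lambda: float = 0.0) -> float:
    """−Σ_pos log p − Σ_neg log(1−p) + λ‖Θ‖₂² (squared L2 over weight
    matrices).  Scores exactly 0 or 1 are clamped to [ε, 1−ε], ε=1e-12."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_clamped = int(np.sum((scores <= 0.0) | (scores >= 1.0)))
    if n_clamped:
        logger.warning("clamped %d degenerate probabilities in nll_loss", n_clamped)
    p = np.clip(scores, 1e-12, 1.0 - 1e-12)
    loss = -float(np.sum(np.log(p[labels == 1]))) \
        - float(np.sum(np.log(1.0 - p[labels == 0])))
    if params is not None and l2_lambda > 0.0:
        for name in getattr(params, "WEIGHT_MATRICES", ()):
            if name in params.arrays:
                loss += l2_lambda * float(np.sum(params.arrays[name] ** 2))
    return loss


class Adam:
    """Adam over named leaf tensors, updating their arrays in place."""

    def __init__(self, leaves: dict[str, ad.Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.leaves = leaves
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(l.value) for n, l in leaves.items()}
        self.v = {n: np.zeros_like(l.value) for n, l in leaves.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, leaf in self.leaves.items():
            g = leaf.grad
            if g is None:
                continue
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / (1 - b1**self.t)
            v_hat = self.v[name] / (1 - b2**self.t)
            leaf.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _batch_loss(model, batch: Sequence[QueryInstance],
                l2_lambda: float) -> ad.Tensor:
    # -log σ(s) = softplus(-s); -log(1-σ(s)) = softplus(s): logit-space NLL.
    total: ad.Tensor | None = None
    for inst in batch:
        s = model.logit(inst)
        term = ad.softplus(-s) if inst.label == 1 else ad.softplus(s)
        total = term if total is None else total + term
    if l2_lambda > 0.0:
        for name in model.weight_decay_names:
            if name in model.leaves:
                w = model.leaves[name]
                total = total + l2_lambda * ad.tsum(w * w)
    return total


def train_model(
    train: LabeledSets,
    dev: LabeledSets,
    model,
    config: TrainConfig,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Fit a model; returns (best-dev-MAP parameter arrays, per-epoch history).

    The model is any trainable scorer (``PathScorer``, ``PRAModel``): it
    exposes ``leaves``, ``logit``, ``score``, ``weight_decay_names`` and
    ``zero_grad``.  Early stopping fires when dev accuracy has not improved
    by ``min_improve`` for ``patience_epochs`` consecutive epochs.  Fully
    reproducible given the config seed.
    """
    from .evaluation import (average_precision, build_ranked_lists,
                             mean_average_precision)  # local: no cycle at load

    def dev_metrics(instances) -> tuple[float, float]:
        if not instances:
            return 0.0, 0.0
        scores = [model.score(inst) for inst in instances]
        acc = np.mean([(s >= 0.5) == bool(i.label)
                       for s, i in zip(scores, instances)])
        ranked = build_ranked_lists(instances, scores)
        aps = {rel: average_precision(rl) for rel, rl in ranked.items()
               if rl.n_positive > 0}
        return float(acc), (mean_average_precision(aps) if aps else 0.0)

    if not len(train):
        raise ValueError("empty training set")
    instances = train.all
    dev_instances = dev.all
    optimizer = Adam(model.leaves, config.learning_rate, config.adam_beta1,
                     config.adam_beta2, config.adam_epsilon)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_acc: float | None = None
    best_map = -np.inf
    best_arrays = {n: l.value.copy() for n, l in model.leaves.items()}
    wait = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(instances))
        epoch_loss = 0.0
        for start in range(0, len(instances), config.batch_size):
            batch = [instances[i] for i in order[start : start + config.batch_size]]
            model.zero_grad()
            loss = _batch_loss(model, batch, config.l2_lambda)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (batch starting {start}): "
                    f"{value}"
                )
            loss.backward()
            optimizer.step()
            epoch_loss += value
        evaluate_now = (epoch % config.dev_eval_every == 0
                        or epoch == config.epochs)
        if evaluate_now:
            dev_acc, dev_map = dev_metrics(dev_instances)
        else:
            dev_acc = dev_map = None
        history.append({"epoch": epoch, "loss": epoch_loss,
                        "dev_accuracy": dev_acc, "dev_map": dev_map})
        if not evaluate_now:
            continue
        if dev_map > best_map:
            best_map = dev_map
            best_arrays = {n: l.value.copy() for n, l in model.leaves.items()}
        if best_acc is None or dev_acc >= best_acc + config.min_improve:
            best_acc = max(dev_acc, best_acc or dev_acc)
            wait = 0
        else:
            wait += 1
            if wait >= config.patience_epochs:
                logger.info("early stop at epoch %d (no dev-accuracy gain "
                            ">= %g in %d epochs)", epoch, config.min_improve,
                            config.patience_epochs)
                break
    # restore the best checkpoint into the live model
    for name, arr in best_arrays.items():
        model.leaves[name].value[...] = arr
    return best_arrays, history


def grid_search(
    param_grid: dict[str, Sequence],
    evaluate: Callable[[dict], float],
) -> tuple[dict, float]:
    """Exhaustive search over the cartesian grid, maximizing ``evaluate``
    (dev MAP).  Ties break toward the first configuration in lexicographic
    grid order (the order of ``param_grid`` values)."""
    if not param_grid:
        raise ValueError("empty grid")
    names = list(param_grid)
    best_config: dict | None = None
    best_score = -np.inf
    for combo in itertools.product(*(param_grid[n] for n in names)):
        config = dict(zip(names, combo))
        score = evaluate(config)
        if score > best_score:
            best_score = score
            best_config = config
    assert best_config is not None
    return best_config, best_score
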