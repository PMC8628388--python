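"""End-to-end workflow glue: dataset preparation and model training runs.

This module wires the pieces together the way the CLI (and the acceptance
script) use them: split the triples 7:1.5:1.5 stratified by relation, build
fixed corrupted negatives per split, extract random-walk path evidence over
the graph (each query's own direct edge excluded from its paths), and
train/evaluate any model of the ladder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kg_core import KnowledgeGraph, SplitSpec, Triple, split_dataset
from .path_sampler import QueryInstance, build_instances
from .text_encoder import make_encoder
from .training import (CorruptionStats, LabeledSets, TrainConfig,
                       make_negatives, train_model)
from .evaluation import evaluate_instances
from .models import make_model
from .verbalizer import DEFAULT_TEMPLATES, TemplateSet

logger = logging.getLogger(__name__)

__all__ = ["SamplerConfig", "PreparedData", "prepare_dataset", "run_training"]


@dataclass
class SamplerConfig:
    """Path-extraction settings (walk count, bounds, truncation)."""

    max_len: int = 7
    n_walks: int = 200
    max_paths: int = 622


@dataclass
class PreparedData:
    """Instance sets per split plus the preparation manifest."""

    train: LabeledSets
    dev: LabeledSets
    test: LabeledSets
    manifest: dict = field(default_factory=dict)
    train_graph: KnowledgeGraph | None = None
    #: the (possibly subsampled) positive triples per split
    triple_splits: dict[str, list[Triple]] = field(default_factory=dict)

    def split(self, name: str) -> LabeledSets:
        return {"train": self.train, "dev": self.dev, "test": self.test}[name]


def prepare_dataset(
    kg: KnowledgeGraph,
    split_spec: SplitSpec | None = None,
    sampler: SamplerConfig | None = None,
    neg_ratio: float = 0.75,
    eval_neg_ratio: float = 8.0,
    same_relation_prob: float = 0.7,
    seed: int = 0,
    max_pos_per_split: int | dict[str, int] | None = None,
    max_pos_per_relation: int | dict[str, int] | None = None,
) -> PreparedData:
    """Split, corrupt, and extract paths; returns labeled instance sets.

    Negatives are fixed at preparation time (filtered against the *full*
    triple set); path evidence comes from random walks over the whole graph
    — the dataset is built by walks first, then split — with every query's
    own direct edge excluded from its paths (label-leakage guard).  Pairs
    with no discovered paths are dropped and counted in the manifest.

    ``neg_ratio`` applies to the training split (≈0.75 negatives per
    positive); dev/test use ``eval_neg_ratio`` (≈8 negatives per positive),
    matching the negative-heavy ranking pools of the evaluation protocol.
    """
    split_spec = split_spec or SplitSpec(seed=seed)
    sampler = sampler or SamplerConfig()
    splits = dict(zip(("train", "dev", "test"), split_dataset(kg, split_spec)))
    raw_split_sizes = {k: len(v) for k, v in splits.items()}
    train_graph = kg.subgraph(splits["train"])
    rng = np.random.default_rng(seed)
    def _cap_for(spec, name):
        return spec.get(name) if isinstance(spec, dict) else spec

    if max_pos_per_split is not None:
        # deterministic per-split subsample: bounds desk-scale problem size;
        # a dict gives each split its own cap (e.g. a low-data train split)
        for name, triples in splits.items():
            cap = _cap_for(max_pos_per_split, name)
            if cap is not None and len(triples) > cap:
                sub_rng = np.random.default_rng(seed + 1)
                idx = sub_rng.choice(len(triples), size=cap, replace=False)
                splits[name] = [triples[i] for i in sorted(idx)]
    if max_pos_per_relation is not None:
        # per-relation cap: balances relations whose triple counts differ by
        # orders of magnitude, so macro-averaged metrics are not dominated
        # by a handful of sparsely represented relations
        for name, triples in splits.items():
            cap = _cap_for(max_pos_per_relation, name)
            if cap is None:
                continue
            sub_rng = np.random.default_rng(seed + 2)
            by_rel: dict[str, list[Triple]] = {}
            for t in triples:
                by_rel.setdefault(t.relation, []).append(t)
            kept: list[Triple] = []
            for rel in sorted(by_rel):
                ts = by_rel[rel]
                if len(ts) > cap:
                    idx = sub_rng.choice(len(ts), size=cap, replace=False)
                    ts = [ts[i] for i in sorted(idx)]
                kept.extend(ts)
            splits[name] = kept
    stats = CorruptionStats()
    sets: dict[str, LabeledSets] = {}
    manifest: dict = {
        "n_triples": kg.n_triples,
        "n_entities": kg.n_entities,
        "n_relations": len(kg.relation_ids()),
        "split_sizes": raw_split_sizes,
        "max_pos_per_split": max_pos_per_split,
        "sampler": {"max_len": sampler.max_len, "n_walks": sampler.n_walks,
                    "max_paths": sampler.max_paths},
        "neg_ratio": neg_ratio,
        "eval_neg_ratio": eval_neg_ratio,
        "same_relation_prob": same_relation_prob,
        "seed": seed,
        "counts": {},
    }
    for name, positives in splits.items():
        ratio = neg_ratio if name == "train" else eval_neg_ratio
        negatives = make_negatives(kg, positives, rng, ratio,
                                   same_relation_prob, stats)
        pos_instances = build_instances(
            kg, positives, max_len=sampler.max_len,
            n_walks=sampler.n_walks, max_paths=sampler.max_paths,
            seed=seed, label=1,
        )
        neg_instances = build_instances(
            kg, negatives, max_len=sampler.max_len,
            n_walks=sampler.n_walks, max_paths=sampler.max_paths,
            seed=seed, label=0,
        )
        sets[name] = LabeledSets(pos_instances, neg_instances)
        manifest["counts"][name] = {
            "positive_triples": len(positives),
            "negative_triples": len(negatives),
            "positive_instances": len(pos_instances),
            "negative_instances": len(neg_instances),
            "dropped_zero_path_pairs": (len(positives) - len(pos_instances))
            + (len(negatives) - len(neg_instances)),
        }
        logger.info("%s: %d+/%d- instances (%d zero-path pairs dropped)",
                    name, len(pos_instances), len(neg_instances),
                    manifest["counts"][name]["dropped_zero_path_pairs"])
    manifest["corruption_same_pool_fraction"] = stats.same_pool_fraction
    if sets["train"].positives:
        avg_paths = float(np.mean([len(i.paths) for i in sets["train"].all]))
        manifest["avg_paths_per_instance"] = avg_paths
    return PreparedData(train=sets["train"], dev=sets["dev"],
                        test=sets["test"], manifest=manifest,
                        train_graph=train_graph, triple_splits=splits)


def run_training(
    prepared: PreparedData,
    kg: KnowledgeGraph,
    model_name: str = "att-types",
    encoder_config: dict | None = None,
    train_config: TrainConfig | None = None,
    templates: TemplateSet = DEFAULT_TEMPLATES,
    d: int = 50,
    k: int = 50,
):
    """Train one model of the ladder; returns (model, history, test report)."""
    train_config = train_config or TrainConfig()
    encoder = make_encoder(encoder_config or {"kind": "stub", "H": 32})
    model = make_model(
        model_name, kg, encoder=encoder, templates=templates,
        seed=train_config.seed, train_instances=prepared.train.all,
        d=d, k=k, H=encoder.H,
    )
    _, history = train_model(prepared.train, prepared.dev, model, train_config)
    report = evaluate_instances(model, prepared.test.all)
    return model, history, report
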