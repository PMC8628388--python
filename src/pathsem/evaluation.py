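"""Ranking protocol: average precision per query relation, MAP, reports.

For each query relation, all test instances of that relation (positives and
the dataset's fixed negatives) are ranked together by model score; average
precision (AP) is the mean, over the positives, of precision at each
positive's rank.  MAP is the unweighted (macro) mean of AP over the relation
set, so relations with few test pairs weigh the same as frequent ones.
Ties are broken by stable instance-id order — AP is tie-sensitive and the
ordering must be deterministic.

Attention case reports list a pair's verbalized path statements sorted by
their attention weight, the model's own account of which evidence drove a
prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kg_core import KnowledgeGraph
from .path_sampler import QueryInstance
from .verbalizer import DEFAULT_TEMPLATES, TemplateSet, path_statement

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "average_precision",
    "mean_average_precision",
    "build_ranked_lists",
    "evaluate_instances",
    "evaluate_model",
    "write_report",
    "attention_report",
    "attention_report_markdown",
    "permutation_null_map",
]


@dataclass
class RankedList:
    """(instance id, score, label) rows for one relation, best score first."""

    relation: str
    items: list[tuple[str, float, int]]

    @classmethod
    def from_scored(cls, relation: str,
                    scored: list[tuple[str, float, int]]) -> "RankedList":
        items = sorted(scored, key=lambda row: (-row[1], row[0]))
        return cls(relation=relation, items=items)

    @property
    def n_positive(self) -> int:
        return sum(label for _, _, label in self.items)


def average_precision(ranked: RankedList) -> float:
    """Mean over positives of precision at each positive's rank."""
    if ranked.n_positive == 0:
        raise ValueError(f"no positives in ranked list for {ranked.relation!r}")
    hits = 0
    precisions = []
    for rank, (_, _, label) in enumerate(ranked.items, start=1):
        if label == 1:
            hits += 1
            precisions.append(hits / rank)
    return float(np.mean(precisions))


def mean_average_precision(per_relation: dict[str, float]) -> float:
    """Unweighted mean of AP over the query-relation set."""
    if not per_relation:
        raise ValueError("MAP over an empty relation map")
    return float(np.mean(list(per_relation.values())))


def build_ranked_lists(
    instances: list[QueryInstance], scores: list[float]
) -> dict[str, RankedList]:
    """Group scored instances per relation into deterministic ranked lists."""
    if len(instances) != len(scores):
        raise ValueError("instances and scores length mismatch")
    grouped: dict[str, list[tuple[str, float, int]]] = {}
    for inst, score in zip(instances, scores):
        grouped.setdefault(inst.relation, []).append(
            (inst.instance_id, float(score), inst.label)
        )
    return {rel: RankedList.from_scored(rel, rows)
            for rel, rows in grouped.items()}


def evaluate_instances(model, instances: list[QueryInstance]) -> dict:
    """Score instances with a model and compute per-relation AP and MAP.

    Relations with no positives are excluded (logged).  Returns
    ``{"per_relation": {rel: AP}, "map": MAP, "counts": {...}}``.
    """
    scores = [model.score(inst) for inst in instances]
    ranked = build_ranked_lists(instances, scores)
    per_relation: dict[str, float] = {}
    counts: dict[str, dict[str, int]] = {}
    for rel in sorted(ranked):
        rl = ranked[rel]
        n_pos = rl.n_positive
        counts[rel] = {"positives": n_pos, "negatives": len(rl.items) - n_pos}
        if n_pos == 0:
            logger.info("relation %r has no test positives; skipped", rel)
            continue
        per_relation[rel] = average_precision(rl)
    result_map = mean_average_precision(per_relation) if per_relation else 0.0
    return {"per_relation": per_relation, "map": result_map, "counts": counts}


def evaluate_model(model, test) -> dict:
    """Evaluate on a :class:`~pathsem.training.LabeledSets` split."""
    return evaluate_instances(model, test.all)


def write_report(report: dict, json_path, csv_path=None,
                 model_name: str = "model") -> None:
    """Serialize a report as JSON and, optionally, a per-relation CSV
    (relation, model, %MAP rows, plus an overall-MAP row)."""
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, ensure_ascii=False)
    if csv_path is not None:
        rows = [
            {"relation": rel, "model": model_name, "pct_map": 100.0 * ap}
            for rel, ap in sorted(report["per_relation"].items())
        ]
        rows.append({"relation": "__overall__", "model": model_name,
                     "pct_map": 100.0 * report["map"]})
        pd.DataFrame(rows).to_csv(csv_path, index=False)


def attention_report(model, instance: QueryInstance, kg: KnowledgeGraph,
                     templates: TemplateSet = DEFAULT_TEMPLATES
                     ) -> list[tuple[str, float]]:
    """Path statements of one pair sorted by descending attention weight."""
    alpha = model.attention(instance)  # raises for non-attention models
    statements = [path_statement(p, kg, templates, fallback_phrase=True)
                  for p in instance.paths]
    order = np.argsort(-alpha, kind="stable")
    return [(statements[i], float(alpha[i])) for i in order]


def attention_report_markdown(model, instance: QueryInstance,
                              kg: KnowledgeGraph,
                              templates: TemplateSet = DEFAULT_TEMPLATES) -> str:
    rows = attention_report(model, instance, kg, templates)
    head = (f"**Query** {instance.relation}({instance.source}, "
            f"{instance.target})?\n\n| weight | path statement |\n|---|---|\n")
    body = "".join(f"| {w:.4f} | {text} |\n" for text, w in rows)
    return head + body


def permutation_null_map(instances: list[QueryInstance], rng,
                         n_permutations: int = 500) -> np.ndarray:
    """Null MAP distribution: scores replaced by random noise, labels fixed.

    Returns the sampled MAP values; compare an observed MAP against e.g.
    their 99th percentile.
    """
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        scores = rng.random(len(instances)).tolist()
        ranked = build_ranked_lists(instances, scores)
        aps = {rel: average_precision(rl) for rel, rl in ranked.items()
               if rl.n_positive > 0}
        null[i] = mean_average_precision(aps)
    return null
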