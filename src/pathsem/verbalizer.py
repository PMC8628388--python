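"""Template-based verbalization of entities and paths into statements.

An entity verbalizes as its name followed by its type labels
(``"Jujube Bark, drug, traditional Chinese medicine."``); a path verbalizes
as one clause per hop, each clause produced from the hop relation's phrase
template with the ``{h}``/``{t}`` slots filled by entity display names, e.g.

    The related symptom of anomalous pulmonaryvenous drainage is respiratory
    distress, and the related department of respiratory distress is
    respiratory medicine.

Templates are data, not code: the shipped defaults are English, and any
language (including the original Chinese) can be supplied via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml

from .kg_core import Entity, KnowledgeGraph, default_phrase
from .path_sampler import Path

__all__ = [
    "TemplateSet",
    "DEFAULT_TEMPLATES",
    "CHINESE_TEMPLATES",
    "entity_statement",
    "path_statement",
    "load_templates",
    "save_templates",
]


@dataclass(frozen=True)
class TemplateSet:
    """Surface-form configuration for statements.

    ``entity_template`` must contain ``{name}``; ``{types}`` expands to the
    joined type list (empty string when the entity has no types) and
    ``{description}`` to an optional free-text description.  Clauses of a
    path statement are joined by ``clause_joiner`` and the statement ends
    with ``terminal``; ``capitalize_first`` upper-cases the first character
    of the first clause (for languages with letter case).
    """

    entity_template: str = "{name}{types}"
    type_joiner: str = ", "
    clause_joiner: str = ", and "
    terminal: str = "."
    capitalize_first: bool = True

    def __post_init__(self) -> None:
        if "{name}" not in self.entity_template:
            raise ValueError("entity_template must contain {name}")
        if self.clause_joiner is None or self.terminal is None:
            raise ValueError("clause_joiner and terminal must be non-null")


DEFAULT_TEMPLATES = TemplateSet()

#: Surface forms suitable for Chinese statements (no clause capitalization;
#: relation phrases carry the full clause structure).
CHINESE_TEMPLATES = TemplateSet(
    entity_template="{name}{types}",
    type_joiner=", ",
    clause_joiner=", ",
    terminal=".",
    capitalize_first=False,
)


def entity_statement(entity: Entity, templates: TemplateSet = DEFAULT_TEMPLATES,
                     description: str = "") -> str:
    """Render an entity as a textual statement (name + type labels)."""
    if not entity.name:
        raise ValueError(f"entity {entity.id!r} has an empty name")
    types = ""
    if entity.types:
        types = templates.type_joiner + templates.type_joiner.join(entity.types)
    body = templates.entity_template.format(
        name=entity.name, types=types, description=description
    )
    return body + templates.terminal


def _clause(kg: KnowledgeGraph, relation_id: str, head_id: str, tail_id: str,
            fallback: bool) -> str:
    if relation_id in kg.relations:
        phrase = kg.relations[relation_id].phrase
    elif fallback:
        phrase = default_phrase(relation_id)
    else:
        raise KeyError(f"relation {relation_id!r} has no phrase template")
    head = kg.entity(head_id).name
    tail = kg.entity(tail_id).name
    return phrase.replace("{h}", head).replace("{t}", tail)


def path_statement(
    path: Path,
    kg: KnowledgeGraph,
    templates: TemplateSet = DEFAULT_TEMPLATES,
    fallback_phrase: bool = False,
) -> str:
    """Render a path as one clause per hop, joined and terminated.

    Raises ``KeyError`` for a relation without a phrase template unless
    ``fallback_phrase`` enables the ``"{h} <id> {t}"`` fallback.
    """
    clauses = []
    head = path.source
    for relation_id, tail in path.steps:
        clauses.append(_clause(kg, relation_id, head, tail, fallback_phrase))
        head = tail
    text = templates.clause_joiner.join(clauses)
    if templates.capitalize_first and text:
        text = text[0].upper() + text[1:]
    return text + templates.terminal


def load_templates(path) -> TemplateSet:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return TemplateSet(**data)


def save_templates(templates: TemplateSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(templates), fh, allow_unicode=True)
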