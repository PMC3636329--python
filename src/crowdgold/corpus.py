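"""Corpus preparation: tokenization, unit splitting, gold designation, balancing.

Documents (clinical-trial-announcement-like plain text with blank-line
paragraph boundaries) are cut into paragraph "units" of at least
``min_tokens_per_unit`` tokens by greedily merging consecutive short
paragraphs.  A seeded fraction of units is designated as hidden gold units
for worker trust accounting, and the proportion of units with no medication
mentions ("empty units") can be rebalanced to a target rate.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence

import numpy as np

from .model import AnnotationError, Entity, Link, Unit

__all__ = [
    "PrepConfig",
    "Document",
    "PreparationError",
    "ConfigurationError",
    "tokenize",
    "split_units",
    "select_gold_units",
    "balance_empty_units",
]

_PUNCT = set(string.punctuation)
_PARA_SEP = re.compile(r"\n[ \t]*\n+")


class PreparationError(ValueError):
    """Raised when a document cannot be split without damaging annotations."""


class ConfigurationError(ValueError):
    """Raised for unachievable preparation settings."""


@dataclass
class PrepConfig:
    """Unit-building settings; the defaults are the production campaign's."""

    min_tokens_per_unit: int = 50
    gold_fraction: float = 0.20
    empty_unit_rate: float = 0.30
    judgments_per_unit: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gold_fraction < 1):
            raise ConfigurationError("gold_fraction must lie in (0, 1)")
        if not (0 <= self.empty_unit_rate < 1):
            raise ConfigurationError("empty_unit_rate must lie in [0, 1)")
        if self.min_tokens_per_unit < 1:
            raise ConfigurationError("min_tokens_per_unit must be >= 1")


@dataclass
class Document:
    """Plain-text document with optional document-level gold annotations.

    ``entities is None`` means no expert annotation exists; an empty set
    means the document was annotated and contains nothing.
    """

    doc_id: str
    text: str
    entities: Optional[FrozenSet[Entity]] = None
    links: Optional[FrozenSet[Link]] = None


def tokenize(text: str) -> List[str]:
    """Deterministic whitespace tokenizer with punctuation peeling.

    Whitespace-delimited chunks are tokens, except that leading and trailing
    punctuation characters are split off as their own tokens; internal
    punctuation (``250/50``, ``4.5``) stays attached.
    """
    tokens: List[str] = []
    for chunk in text.split():
        lead: List[str] = []
        while len(chunk) > 1 and chunk[0] in _PUNCT:
            lead.append(chunk[0])
            chunk = chunk[1:]
        trail: List[str] = []
        while len(chunk) > 1 and chunk[-1] in _PUNCT:
            trail.append(chunk[-1])
            chunk = chunk[:-1]
        tokens.extend(lead)
        tokens.append(chunk)
        tokens.extend(reversed(trail))
    return tokens


def _paragraph_offsets(text: str) -> List[tuple]:
    """(start, end) of each non-blank paragraph in *text*."""
    paragraphs = []
    pos = 0
    for m in _PARA_SEP.finditer(text):
        if text[pos : m.start()].strip():
            paragraphs.append((pos, m.start()))
        pos = m.end()
    if text[pos:].strip():
        paragraphs.append((pos, len(text.rstrip())))
    return paragraphs


def split_units(document: Document, config: PrepConfig) -> List[Unit]:
    """Cut *document* into units of at least ``min_tokens_per_unit`` tokens.

    Consecutive paragraphs are merged greedily until the token floor is met;
    the document's final unit may fall short.  Units never cross document
    boundaries.  Gold entities and links are re-offset into unit-local
    coordinates; an annotation straddling a unit boundary raises
    :class:`PreparationError` rather than being silently truncated.
    """
    if not document.text.strip():
        raise PreparationError(f"document {document.doc_id} has no text")
    paragraphs = _paragraph_offsets(document.text)

    # greedy forward merge of paragraph index ranges
    groups: List[tuple] = []
    start_idx = 0
    count = 0
    for i, (ps, pe) in enumerate(paragraphs):
        count += len(tokenize(document.text[ps:pe]))
        if count >= config.min_tokens_per_unit:
            groups.append((start_idx, i))
            start_idx, count = i + 1, 0
    if start_idx < len(paragraphs):  # short remainder stays its own unit
        groups.append((start_idx, len(paragraphs) - 1))

    units: List[Unit] = []
    annotated = document.entities is not None
    for k, (a, b) in enumerate(groups):
        u_start, u_end = paragraphs[a][0], paragraphs[b][1]
        unit_id = f"{document.doc_id}:u{k}"
        text = document.text[u_start:u_end]
        units.append(
            Unit(
                unit_id=unit_id,
                doc_id=document.doc_id,
                text=text,
                token_count=len(tokenize(text)),
                gold_entities=frozenset() if annotated else None,
                gold_links=frozenset() if annotated else None,
            )
        )

    if annotated:
        bounds = [(paragraphs[a][0], paragraphs[b][1]) for a, b in groups]
        ent_map = {}
        per_unit_entities: List[set] = [set() for _ in units]
        per_unit_links: List[set] = [set() for _ in units]
        for ent in document.entities:
            placed = False
            for idx, (us, ue) in enumerate(bounds):
                if ent.start >= us and ent.end <= ue:
                    local = ent.shifted(-us, units[idx].unit_id)
                    per_unit_entities[idx].add(local)
                    ent_map[ent] = (idx, local)
                    placed = True
                    break
            if not placed:
                raise PreparationError(
                    f"entity {ent.label}@{ent.start}-{ent.end} in {document.doc_id} "
                    "spans a unit boundary"
                )
        for link in document.links or frozenset():
            mi, med = ent_map[link.medication]
            ai, attr = ent_map[link.attribute]
            if mi != ai:
                raise PreparationError(
                    f"link in {document.doc_id} spans a unit boundary"
                )
            per_unit_links[mi].add(Link(units[mi].unit_id, med, attr))
        for idx, unit in enumerate(units):
            unit.gold_entities = frozenset(per_unit_entities[idx])
            unit.gold_links = frozenset(per_unit_links[idx])
    return units


def select_gold_units(units: Sequence[Unit], config: PrepConfig) -> List[Unit]:
    """Flag a seeded uniform sample of ``gold_fraction * N`` units as gold.

    The count is rounded half-to-even.  Only units that carry gold
    annotations are eligible.  Mutates and returns the unit list.
    """
    n = len(units)
    n_gold = round(config.gold_fraction * n)
    if n_gold < 1:
        raise ConfigurationError(
            f"gold_fraction {config.gold_fraction} of {n} units selects none"
        )
    eligible = [i for i, u in enumerate(units) if u.gold_entities is not None]
    if len(eligible) < n_gold:
        raise ConfigurationError(
            f"only {len(eligible)} annotated units available for {n_gold} gold slots"
        )
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(len(eligible), size=n_gold, replace=False)
    for u in units:
        u.is_gold = False
    for j in chosen:
        units[eligible[int(j)]].is_gold = True
    return list(units)


def balance_empty_units(units: Sequence[Unit], config: PrepConfig) -> List[Unit]:
    """Subsample empty units so their share equals ``empty_unit_rate``.

    Non-empty units are always kept.  Surplus empty units are removed by a
    seeded uniform draw; if the pool is already at or below the target rate
    but cannot reach it, a :class:`ConfigurationError` reports the achievable
    rate.  Output preserves the input order.
    """
    for u in units:
        if u.gold_entities is None:
            raise AnnotationError(f"unit {u.unit_id} has no emptiness information")
    empty_idx = [i for i, u in enumerate(units) if u.is_empty]
    n_nonempty = len(units) - len(empty_idx)
    r = config.empty_unit_rate
    if r == 0:
        return [u for u in units if not u.is_empty]
    if n_nonempty == 0:
        raise ConfigurationError("no non-empty units; target rate unachievable")
    target = round(r / (1.0 - r) * n_nonempty)
    if len(empty_idx) < target:
        achievable = len(empty_idx) / (len(empty_idx) + n_nonempty)
        raise ConfigurationError(
            f"need {target} empty units, have {len(empty_idx)} "
            f"(achievable rate {achievable:.3f})"
        )
    rng = np.random.default_rng(config.seed)
    keep = set(
        empty_idx[int(j)]
        for j in rng.choice(len(empty_idx), size=target, replace=False)
    )
    return [u for i, u in enumerate(units) if not u.is_empty or i in keep]
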