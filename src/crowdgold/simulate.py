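"""Synthetic corpora and parameterized crowd behaviour.

The generator emulates the shape of a clinical-trial-announcement (CTA)
annotation campaign: documents averaging ~212 tokens, split into paragraph
units of >= 50 tokens, with medication-name and medication-type mentions plus
nine attribute categories, roughly 30% of units empty, and 5 judgments per
unit from workers of heterogeneous ability.  Worker error behaviour covers
the failure modes of span annotation interfaces: missed entities, spurious
entities, one-token boundary shifts, medication name/type label confusion,
and mis-attached attribute links.

Everything is driven by one integer seed; substreams are derived per purpose
(corpus, assignment, per-worker) so runs are bit-reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .corpus import Document, PrepConfig, split_units
from .model import (
    ATTRIBUTE_LABELS,
    MEDICATION_LABELS,
    MEDICATION_NAME,
    MEDICATION_TYPE,
    Entity,
    Judgment,
    Link,
    Span,
    Unit,
    unit_exact_match,
)
from .qc import BLOCKED, IN_TRAINING, TRUSTED, WARNED, TurkerState, record_gold_result, training_gate

__all__ = [
    "SimConfig",
    "TurkerProfile",
    "CampaignError",
    "generate_gold_corpus",
    "generate_units",
    "simulate_judgment",
    "simulate_crowd",
    "simulate_correction_round",
    "distinct_variants",
    "make_profiles",
]


class CampaignError(RuntimeError):
    """A simulated campaign could not be completed (worker pool exhausted)."""


# ---------------------------------------------------------------------------
# Lexicon: a bundled synthetic drug/type/attribute vocabulary.  Single-token
# surfaces dominate so that boundary-shift noise stays well defined.
# ---------------------------------------------------------------------------

DRUG_NAMES = [
    "ibuprofen", "vancomycin", "ganciclovir", "metformin", "lisinopril",
    "atorvastatin", "omeprazole", "warfarin", "prednisone", "amoxicillin",
    "fluoxetine", "albuterol", "methotrexate", "gabapentin", "sertraline",
    "amlodipine", "azithromycin", "ondansetron", "tacrolimus", "rituximab",
]

DRUG_TYPES = [
    "antibiotics", "chemotherapy", "anticoagulants", "corticosteroids",
    "antidepressants", "benzodiazepines", "statins", "immunosuppressants",
    "medication", "antihypertensives", "analgesics", "anticonvulsants",
    "study drug", "other drugs",
]

ATTRIBUTE_LEXICON: Dict[str, List[str]] = {
    "STRENGTH": ["250/50", "5mg", "10 mg", "500 mg", "2.5 mg", "40 mg"],
    "DOSAGE": ["high dose", "low dose", "stable dose", "1", "2"],
    "FORM": ["tablet", "capsule", "diskus", "injection", "chewable", "puff", "infusion"],
    "FREQUENCY": ["daily", "twice daily", "once a day", "weekly", "every 8 hours"],
    "DURATION": ["for 2 weeks", "for 6 months", "for 14 days"],
    "ROUTE": ["oral", "intravenous", "topical", "subcutaneous"],
    "DATE": ["January 2011", "March 2010", "June 2012"],
    "STATUS_CHANGE": ["discontinued", "started", "hold", "increased", "decreased"],
    "MODIFIER": ["conditional", "stable", "conventional", "current", "prior"],
}

# attribute category sampling weights emulating a realistic skew toward
# modifiers and routes, with dates rare
ATTRIBUTE_WEIGHTS: Dict[str, int] = {
    "DATE": 16,
    "DOSAGE": 645,
    "DURATION": 644,
    "FORM": 482,
    "FREQUENCY": 381,
    "ROUTE": 894,
    "STATUS_CHANGE": 598,
    "STRENGTH": 409,
    "MODIFIER": 5827,
}

FILLER = (
    "patients must be aged between 18 and 65 years with a documented history "
    "of the condition prior to enrollment and willing to comply with all "
    "protocol procedures including scheduled visits laboratory assessments "
    "and screening evaluations subjects who have received any investigational "
    "agent within 30 days are not eligible informed consent must be obtained "
    "before any study specific procedure clinically significant renal or "
    "hepatic dysfunction is exclusionary as are values outside the normal "
    "reference range at screening"
).split()


@dataclass
class SimConfig:
    """Corpus-shape settings; defaults emulate the CTA campaign conditions."""

    n_docs: int = 100
    mean_tokens_per_doc: float = 212.0
    sd_tokens_per_doc: float = 30.0
    min_unit_tokens: int = 50
    empty_unit_rate: float = 0.30
    medication_name_weight: float = 9968.0   # name:type mention ratio
    medication_type_weight: float = 11789.0
    max_meds_per_paragraph: int = 2
    max_attrs_per_med: int = 3
    judgments_per_unit: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.mean_tokens_per_doc < self.min_unit_tokens:
            raise ValueError("document shape cannot accommodate the unit floor")


@dataclass
class TurkerProfile:
    """Error-behaviour parameters of one simulated worker.

    p_miss: probability each gold entity is omitted.
    p_spurious: expected count of fabricated entities per unit (Poisson).
    p_boundary: probability a kept entity's span is shifted by one token.
    p_confuse: probability of a medication name<->type label swap.
    p_link_error: probability an attribute is attached to the wrong medication.
    activity: relative propensity to take tasks (heavier => more jobs).
    """

    turker_id: str
    p_miss: float = 0.0
    p_spurious: float = 0.0
    p_boundary: float = 0.0
    p_confuse: float = 0.0
    p_link_error: float = 0.0
    activity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_boundary", "p_confuse", "p_link_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_spurious < 0 or self.activity <= 0:
            raise ValueError("p_spurious must be >= 0 and activity > 0")


def make_profiles(
    n: int,
    *,
    p_miss: float = 0.15,
    p_spurious: float = 0.1,
    p_boundary: float = 0.05,
    p_confuse: float = 0.05,
    p_link_error: float = 0.05,
    heavy_tailed_activity: bool = True,
    seed: int = 0,
) -> List[TurkerProfile]:
    """A pool of n workers with shared error rates and Zipf-like activity."""
    return [
        TurkerProfile(
            turker_id=f"t{i:03d}",
            p_miss=p_miss,
            p_spurious=p_spurious,
            p_boundary=p_boundary,
            p_confuse=p_confuse,
            p_link_error=p_link_error,
            activity=1.0 / (i + 1) if heavy_tailed_activity else 1.0,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Gold corpus generation
# ---------------------------------------------------------------------------


class _ParagraphDraft:
    """Token buffer with token-range entity/link bookkeeping."""

    def __init__(self) -> None:
        self.tokens: List[str] = []
        self.entities: List[Tuple[str, int, int]] = []  # (label, tok_start, tok_end)
        self.links: List[Tuple[int, int]] = []          # entity-index pairs

    def add_filler(self, rng: np.random.Generator, n: int) -> None:
        for _ in range(n):
            self.tokens.append(FILLER[int(rng.integers(len(FILLER)))])

    def add_entity(self, label: str, surface: str) -> int:
        parts = surface.split()
        start = len(self.tokens)
        self.tokens.extend(parts)
        self.entities.append((label, start, start + len(parts)))
        return len(self.entities) - 1

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


def _render_paragraph(
    draft: _ParagraphDraft, doc_id: str, char_offset: int
) -> Tuple[str, List[Entity], List[Link]]:
    """Join tokens with single spaces and convert token ranges to char spans."""
    starts: List[int] = []
    pos = 0
    for tok in draft.tokens:
        starts.append(pos)
        pos += len(tok) + 1
    text = " ".join(draft.tokens)
    entities: List[Entity] = []
    for label, a, b in draft.entities:
        s = starts[a] + char_offset
        e = starts[b - 1] + len(draft.tokens[b - 1]) + char_offset
        entities.append(Entity(doc_id, label, (Span(s, e),)))
    links = [
        Link(doc_id, entities[mi], entities[ai]) for mi, ai in draft.links
    ]
    return text, entities, links


def _medication_phrase(draft: _ParagraphDraft, rng: np.random.Generator, cfg: SimConfig) -> None:
    p_name = cfg.medication_name_weight / (
        cfg.medication_name_weight + cfg.medication_type_weight
    )
    draft.add_filler(rng, int(rng.integers(2, 5)))
    if rng.random() < p_name:
        med_idx = draft.add_entity(MEDICATION_NAME, DRUG_NAMES[int(rng.integers(len(DRUG_NAMES)))])
    else:
        med_idx = draft.add_entity(MEDICATION_TYPE, DRUG_TYPES[int(rng.integers(len(DRUG_TYPES)))])
    cats = list(ATTRIBUTE_WEIGHTS)
    w = np.array([ATTRIBUTE_WEIGHTS[c] for c in cats], dtype=float)
    w /= w.sum()
    n_attrs = int(rng.integers(0, cfg.max_attrs_per_med + 1))
    chosen = rng.choice(len(cats), size=min(n_attrs, len(cats)), replace=False, p=w)
    for ci in chosen:
        label = cats[int(ci)]
        surface = ATTRIBUTE_LEXICON[label][int(rng.integers(len(ATTRIBUTE_LEXICON[label])))]
        attr_idx = draft.add_entity(label, surface)
        draft.links.append((med_idx, attr_idx))
    draft.add_filler(rng, int(rng.integers(1, 4)))
    draft.tokens.append(".")


def _make_paragraph(rng: np.random.Generator, cfg: SimConfig, empty: bool) -> _ParagraphDraft:
    target = int(rng.integers(cfg.min_unit_tokens, cfg.min_unit_tokens + 15))
    draft = _ParagraphDraft()
    if not empty:
        for _ in range(int(rng.integers(1, cfg.max_meds_per_paragraph + 1))):
            _medication_phrase(draft, rng, cfg)
    if draft.n_tokens < target:
        draft.add_filler(rng, target - draft.n_tokens)
        draft.tokens.append(".")
    return draft


def generate_gold_corpus(config: SimConfig) -> List[Document]:
    """Seeded synthetic CTA-like documents with gold entities and links.

    Every paragraph is at least ``min_unit_tokens`` tokens, so downstream
    unit splitting maps paragraphs to units one-to-one; about
    ``empty_unit_rate`` of paragraphs carry no medication mention.  Every
    entity span extracts exactly its surface form from the document text.
    """
    rng = np.random.default_rng([config.seed, 0])
    docs: List[Document] = []
    for d in range(config.n_docs):
        doc_id = f"doc{d:04d}"
        target = max(
            config.min_unit_tokens,
            int(rng.normal(config.mean_tokens_per_doc, config.sd_tokens_per_doc)),
        )
        paragraphs: List[str] = []
        entities: List[Entity] = []
        links: List[Link] = []
        tok_count = 0
        offset = 0
        while tok_count < target:
            empty = bool(rng.random() < config.empty_unit_rate)
            draft = _make_paragraph(rng, config, empty)
            text, ents, lks = _render_paragraph(draft, doc_id, offset)
            paragraphs.append(text)
            entities.extend(ents)
            links.extend(lks)
            tok_count += draft.n_tokens
            offset += len(text) + 2  # "\n\n" separator
        docs.append(
            Document(
                doc_id=doc_id,
                text="\n\n".join(paragraphs),
                entities=frozenset(entities),
                links=frozenset(links),
            )
        )
    return docs


def generate_units(config: SimConfig) -> Tuple[List[Document], List[Unit]]:
    """Generate documents and split them into units in one call."""
    docs = generate_gold_corpus(config)
    prep = PrepConfig(min_tokens_per_unit=config.min_unit_tokens, seed=config.seed)
    units: List[Unit] = []
    for doc in docs:
        units.extend(split_units(doc, prep))
    return docs, units


# ---------------------------------------------------------------------------
# Worker behaviour
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\S+")


def _shift_boundary(entity: Entity, text: str, rng: np.random.Generator) -> Entity:
    """Move one edge of the entity's last span by one whitespace token."""
    toks = [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    span = entity.spans[-1]
    ops = []
    nxt = [t for t in toks if t[0] >= span.end]
    prv = [t for t in toks if t[1] <= span.start]
    covered = [t for t in toks if t[0] >= span.start and t[1] <= span.end]
    if nxt:
        ops.append(("extend_right", nxt[0][1]))
    if len(covered) >= 2:
        ops.append(("shrink_right", covered[-2][1]))
    if prv and len(entity.spans) == 1:
        ops.append(("extend_left", prv[-1][0]))
    if not ops:
        return entity
    op, pos = ops[int(rng.integers(len(ops)))]
    spans = list(entity.spans)
    if op == "extend_left":
        spans[0] = Span(pos, spans[0].end)
    else:
        spans[-1] = Span(spans[-1].start, pos)
    return Entity(entity.unit_id, entity.label, tuple(spans))


def _confuse_label(entity: Entity) -> Entity:
    if entity.label not in MEDICATION_LABELS:
        return entity
    other = MEDICATION_TYPE if entity.label == MEDICATION_NAME else MEDICATION_NAME
    return Entity(entity.unit_id, other, entity.spans)


def _spurious_entities(
    unit: Unit, existing: set, count: int, rng: np.random.Generator
) -> List[Entity]:
    toks = [(m.start(), m.end()) for m in _TOKEN_RE.finditer(unit.text)]
    taken = [s for e in existing for s in e.spans]
    out: List[Entity] = []
    for _ in range(count):
        for _attempt in range(10):
            a, b = toks[int(rng.integers(len(toks)))]
            cand_span = Span(a, b)
            if any(cand_span.overlaps(s) for s in taken):
                continue
            label = MEDICATION_NAME if rng.random() < 0.5 else MEDICATION_TYPE
            ent = Entity(unit.unit_id, label, (cand_span,))
            if ent in existing or ent in out:
                continue
            out.append(ent)
            taken.append(cand_span)
            break
    return out


def simulate_judgment(
    profile: TurkerProfile,
    unit: Unit,
    rng: np.random.Generator,
    task_kind: str = "annotate",
    judgment_id: Optional[str] = None,
) -> Judgment:
    """One worker's noisy response to one unit.

    Entity tasks: each gold entity is dropped with p_miss; survivors are
    boundary-shifted with p_boundary and label-confused with p_confuse;
    Poisson(p_spurious) fabricated entities are added at free token slots.
    Link tasks: each gold link is dropped with p_miss or rewired to another
    medication in the unit with p_link_error.
    """
    if unit.gold_entities is None:
        raise ValueError(f"unit {unit.unit_id} has no gold annotations to corrupt")
    jid = judgment_id or f"{unit.unit_id}#{profile.turker_id}"
    if task_kind == "link":
        gold_links = unit.gold_links or frozenset()
        meds = sorted(
            {l.medication for l in gold_links},
            key=lambda e: (e.start, e.end, e.label),
        )
        links = set()
        for link in sorted(gold_links, key=lambda l: (l.attribute.start, l.medication.start)):
            if rng.random() < profile.p_miss:
                continue
            med = link.medication
            if len(meds) > 1 and rng.random() < profile.p_link_error:
                others = [m for m in meds if m != med]
                med = others[int(rng.integers(len(others)))]
            links.add(Link(unit.unit_id, med, link.attribute))
        return Judgment(jid, profile.turker_id, unit.unit_id, "link", links=frozenset(links))

    entities = set()
    for ent in sorted(unit.gold_entities, key=lambda e: (e.start, e.end, e.label)):
        if rng.random() < profile.p_miss:
            continue
        if rng.random() < profile.p_boundary:
            ent = _shift_boundary(ent, unit.text, rng)
        if rng.random() < profile.p_confuse:
            ent = _confuse_label(ent)
        entities.add(ent)
    n_spur = int(rng.poisson(profile.p_spurious))
    if n_spur:
        entities.update(_spurious_entities(unit, entities | set(unit.gold_entities), n_spur, rng))
    return Judgment(jid, profile.turker_id, unit.unit_id, task_kind, entities=frozenset(entities))


# ---------------------------------------------------------------------------
# Campaign simulation
# ---------------------------------------------------------------------------


def _active(profiles: Sequence[TurkerProfile], states: Mapping[str, TurkerState]) -> List[TurkerProfile]:
    return [p for p in profiles if states[p.turker_id].status in (TRUSTED, WARNED)]


def _pick_workers(
    pool: Sequence[TurkerProfile], k: int, rng: np.random.Generator
) -> List[TurkerProfile]:
    w = np.array([p.activity for p in pool], dtype=float)
    w /= w.sum()
    idx = rng.choice(len(pool), size=k, replace=False, p=w)
    return [pool[int(i)] for i in idx]


def simulate_crowd(
    units: Sequence[Unit],
    profiles: Sequence[TurkerProfile],
    judgments_per_unit: int = 5,
    seed: int = 0,
    task_kind: str = "annotate",
    max_training_examples: int = 12,
) -> Tuple[List[Judgment], Dict[str, TurkerState]]:
    """Run a full campaign: training gate, assignment, gold-unit monitoring.

    Each unit receives ``judgments_per_unit`` judgments from distinct workers
    sampled proportionally to activity.  If the stream contains gold units,
    workers first face the training gate (simulated on gold units) and are
    then continuously scored; workers blocked mid-campaign stop receiving
    tasks and their slots on under-filled units are re-assigned.  With no
    gold units in the stream, quality control is inert and every worker is
    admitted.

    Returns the complete judgment stream (including later-blocked workers'
    output — filter with :func:`crowdgold.qc.filter_trusted`) and the final
    worker states.
    """
    if len(profiles) < judgments_per_unit:
        raise CampaignError("fewer workers than judgments requested per unit")
    assign_rng = np.random.default_rng([seed, 1])
    worker_rng = {
        p.turker_id: np.random.default_rng([seed, 2, i]) for i, p in enumerate(profiles)
    }
    states = {p.turker_id: TurkerState(p.turker_id) for p in profiles}
    gold_units = [u for u in units if u.is_gold]
    qc_active = bool(gold_units)

    if qc_active:
        for p in profiles:
            st = states[p.turker_id]
            for _ in range(max_training_examples):
                gu = gold_units[int(worker_rng[p.turker_id].integers(len(gold_units)))]
                j = simulate_judgment(p, gu, worker_rng[p.turker_id], task_kind)
                training_gate(st, [unit_exact_match(j, gu)])
                if st.status == TRUSTED:
                    break
    else:
        for st in states.values():
            st.status = TRUSTED

    judgments: List[Judgment] = []
    by_unit: Dict[str, List[Judgment]] = {u.unit_id: [] for u in units}
    unit_by_id = {u.unit_id: u for u in units}
    serial = 0

    def _assign(unit: Unit, workers: Sequence[TurkerProfile]) -> None:
        nonlocal serial
        for p in workers:
            rng = worker_rng[p.turker_id]
            j = simulate_judgment(
                p, unit, rng, task_kind, judgment_id=f"j{serial:06d}"
            )
            serial += 1
            judgments.append(j)
            by_unit[unit.unit_id].append(j)
            states[p.turker_id].judgments_submitted += 1
            if unit.is_gold:
                record_gold_result(states[p.turker_id], unit_exact_match(j, unit))

    for idx in assign_rng.permutation(len(units)):
        unit = units[int(idx)]
        pool = _active(profiles, states)
        if len(pool) < judgments_per_unit:
            raise CampaignError(
                f"only {len(pool)} eligible workers remain; campaign incomplete"
            )
        _assign(unit, _pick_workers(pool, judgments_per_unit, assign_rng))

    # re-assign slots lost to workers blocked after the fact
    for _round in range(10):
        refill_needed = False
        for uid, js in by_unit.items():
            alive = [j for j in js if states[j.turker_id].status != BLOCKED]
            need = judgments_per_unit - len(alive)
            if need <= 0:
                continue
            seen = {j.turker_id for j in js}
            pool = [p for p in _active(profiles, states) if p.turker_id not in seen]
            if len(pool) < need:
                raise CampaignError(
                    f"unit {uid} cannot be re-filled; worker pool exhausted"
                )
            _assign(unit_by_id[uid], _pick_workers(pool, need, assign_rng))
            refill_needed = True
        if not refill_needed:
            break
    return judgments, states


def simulate_correction_round(
    tasks: Sequence,
    gold: Mapping[str, frozenset],
    fix_prob: float = 0.8,
    p_new_error: float = 0.0,
    n_workers: int = 30,
    seed: int = 0,
) -> None:
    """Populate correction tasks with judgments from error-fixing workers.

    Each correction worker starts from the pre-annotated set: every missing
    gold entity is added with probability ``fix_prob`` and every spurious
    one removed with probability ``fix_prob``; with probability
    ``p_new_error`` per correction, one previously-correct entity is
    deleted (a careless correction).  Mutates the tasks in place.
    """
    rng = np.random.default_rng([seed, 3])
    serial = 0
    for t in tasks:
        gold_set = set(gold[t.unit_id])
        pre = set(t.preannotated)
        missing = sorted(gold_set - pre, key=lambda e: (e.start, e.end, e.label))
        spurious = sorted(pre - gold_set, key=lambda e: (e.start, e.end, e.label))
        for r in range(t.n_corrections):
            result = set(pre)
            for ent in missing:
                if rng.random() < fix_prob:
                    result.add(ent)
            for ent in spurious:
                if rng.random() < fix_prob:
                    result.discard(ent)
            if p_new_error and rng.random() < p_new_error:
                keep = sorted(result & gold_set, key=lambda e: (e.start, e.end, e.label))
                if keep:
                    result.discard(keep[int(rng.integers(len(keep)))])
            worker = f"c{int(rng.integers(n_workers)):03d}"
            t.corrections.append(
                Judgment(
                    f"corr{serial:06d}",
                    worker,
                    t.unit_id,
                    "correct",
                    entities=frozenset(result),
                )
            )
            serial += 1


def distinct_variants(unit: Unit, n: int) -> List[frozenset]:
    """Up to *n* guaranteed-distinct entity-set payloads for *unit*.

    Variant 0 is the gold set; further variants drop one gold entity at a
    time, then add one single-token spurious entity at a time.  Used to
    construct judgment pools with an exact number of unique payloads.
    """
    gold = sorted(unit.gold_entities or (), key=lambda e: (e.start, e.end, e.label))
    variants: List[frozenset] = [frozenset(gold)]
    for ent in gold:
        if len(variants) >= n:
            return variants[:n]
        variants.append(frozenset(set(gold) - {ent}))
    taken = [s for e in gold for s in e.spans]
    for m in _TOKEN_RE.finditer(unit.text):
        if len(variants) >= n:
            break
        sp = Span(m.start(), m.end())
        if any(sp.overlaps(t) for t in taken):
            continue
        variants.append(frozenset(set(gold) | {Entity(unit.unit_id, MEDICATION_NAME, (sp,))}))
    if len(variants) < n:
        raise ValueError(f"unit {unit.unit_id} too small for {n} distinct payloads")
    return variants[:n]
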