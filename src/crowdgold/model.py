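"""Core data types for crowdsourced clinical-text annotation.

The atomic object is an :class:`Entity`: a labelled, possibly discontinuous
character-span annotation inside one annotation unit (a paragraph-sized piece
of a clinical trial announcement).  Entities carry medication labels
(specific drug names vs. drug classes / generic medication references) or one
of nine attribute labels (strength, dosage, form, ...).  A :class:`Link` ties
an attribute to the medication it modifies.  A :class:`Judgment` is one crowd
worker's complete response to one unit — an entity set for annotation and
correction tasks, a link set for the linking task.

All comparison in this package is *exact*: two entities match only if unit,
label and the full span set agree character-for-character.  There is no
partial-overlap credit; the quality-control gating and the evaluation both
rely on this identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Tuple

__all__ = [
    "MEDICATION_NAME",
    "MEDICATION_TYPE",
    "MEDICATION_LABELS",
    "ATTRIBUTE_LABELS",
    "ALL_LABELS",
    "Span",
    "Entity",
    "Link",
    "Unit",
    "Judgment",
    "EvalResult",
    "match_entities",
    "match_links",
    "prf",
    "f_from_pr",
    "unit_exact_match",
]

MEDICATION_NAME = "MEDICATION_NAME"
MEDICATION_TYPE = "MEDICATION_TYPE"

MEDICATION_LABELS = frozenset({MEDICATION_NAME, MEDICATION_TYPE})

ATTRIBUTE_LABELS = frozenset(
    {
        "DATE",
        "STRENGTH",
        "DOSAGE",
        "FORM",
        "FREQUENCY",
        "DURATION",
        "ROUTE",
        "STATUS_CHANGE",
        "MODIFIER",
    }
)

ALL_LABELS = MEDICATION_LABELS | ATTRIBUTE_LABELS

TASK_KINDS = frozenset({"annotate", "correct", "link"})


class AnnotationError(ValueError):
    """Invalid annotation input (bad offsets, unknown labels, wrong unit)."""


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval ``[start, end)``, 0-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


def _as_span(s) -> Span:
    if isinstance(s, Span):
        return s
    return Span(int(s[0]), int(s[1]))


@dataclass(frozen=True)
class Entity:
    """A labelled annotation over one or more disjoint spans of a unit.

    Identity is the triple ``(unit_id, label, span set)``; the order in which
    discontinuous segments are supplied does not matter — spans are stored
    sorted by start offset.
    """

    unit_id: str
    label: str
    spans: Tuple[Span, ...]

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise AnnotationError(f"unknown label {self.label!r}")
        spans = tuple(sorted(_as_span(s) for s in self.spans))
        if not spans:
            raise AnnotationError("entity needs at least one span")
        for a, b in zip(spans, spans[1:]):
            if a.end > b.start:
                raise AnnotationError(f"overlapping spans {a} and {b}")
        object.__setattr__(self, "spans", spans)

    @property
    def start(self) -> int:
        return self.spans[0].start

    @property
    def end(self) -> int:
        return self.spans[-1].end

    def text(self, unit_text: str, sep: str = " ") -> str:
        """Surface form: covered segments joined by *sep*."""
        return sep.join(unit_text[s.start : s.end] for s in self.spans)

    def shifted(self, offset: int, unit_id: Optional[str] = None) -> "Entity":
        """Entity with all spans translated by *offset* (re-homing into a unit)."""
        return Entity(
            unit_id if unit_id is not None else self.unit_id,
            self.label,
            tuple(Span(s.start + offset, s.end + offset) for s in self.spans),
        )


@dataclass(frozen=True)
class Link:
    """Directed association between a medication entity and one attribute."""

    unit_id: str
    medication: Entity
    attribute: Entity

    def __post_init__(self) -> None:
        if self.medication.label not in MEDICATION_LABELS:
            raise AnnotationError(
                f"link head must be a medication, got {self.medication.label}"
            )
        if self.attribute.label not in ATTRIBUTE_LABELS:
            raise AnnotationError(
                f"link tail must be an attribute, got {self.attribute.label}"
            )
        if not (self.unit_id == self.medication.unit_id == self.attribute.unit_id):
            raise AnnotationError("link endpoints must belong to the same unit")

    def shifted(self, offset: int, unit_id: Optional[str] = None) -> "Link":
        uid = unit_id if unit_id is not None else self.unit_id
        return Link(
            uid,
            self.medication.shifted(offset, uid),
            self.attribute.shifted(offset, uid),
        )


@dataclass
class Unit:
    """A paragraph-sized annotation task with optional expert ("gold") answers.

    ``gold_entities is None`` means the unit has never been expert-annotated;
    an *empty* frozenset means it was annotated and contains no medication
    mentions (an "empty unit").
    """

    unit_id: str
    doc_id: str
    text: str
    token_count: int
    is_gold: bool = False
    gold_entities: Optional[FrozenSet[Entity]] = None
    gold_links: Optional[FrozenSet[Link]] = None

    def __post_init__(self) -> None:
        if self.token_count < 1:
            raise AnnotationError("unit must contain at least one token")
        if self.gold_entities is not None:
            self.gold_entities = frozenset(self.gold_entities)
            for e in self.gold_entities:
                if e.end > len(self.text):
                    raise AnnotationError(
                        f"entity span {e.spans} exceeds unit text of length {len(self.text)}"
                    )
        if self.gold_links is not None:
            self.gold_links = frozenset(self.gold_links)
        if self.is_gold and self.gold_entities is None:
            raise AnnotationError("gold unit requires gold annotations")

    @property
    def is_empty(self) -> bool:
        return self.gold_entities is not None and len(self.gold_entities) == 0


@dataclass(frozen=True)
class Judgment:
    """One worker's complete response to one unit.

    Exactly one payload is populated: ``entities`` for annotation/correction
    tasks, ``links`` for the linking task.
    """

    judgment_id: str
    turker_id: str
    unit_id: str
    task_kind: str = "annotate"
    entities: Optional[FrozenSet[Entity]] = None
    links: Optional[FrozenSet[Link]] = None

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise AnnotationError(f"unknown task kind {self.task_kind!r}")
        if self.task_kind == "link":
            if self.links is None or self.entities is not None:
                raise AnnotationError("link judgment must carry links only")
            object.__setattr__(self, "links", frozenset(self.links))
            bad = [l for l in self.links if l.unit_id != self.unit_id]
        else:
            if self.entities is None or self.links is not None:
                raise AnnotationError(
                    f"{self.task_kind} judgment must carry entities only"
                )
            object.__setattr__(self, "entities", frozenset(self.entities))
            bad = [e for e in self.entities if e.unit_id != self.unit_id]
        if bad:
            raise AnnotationError(
                f"judgment {self.judgment_id} references foreign unit(s): {bad[:3]}"
            )

    @property
    def payload(self) -> frozenset:
        """The annotated set, whichever kind this judgment carries."""
        return self.links if self.task_kind == "link" else self.entities


@dataclass
class EvalResult:
    """Micro-averaged exact-match counts with derived precision/recall/F."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise AnnotationError("counts must be non-negative")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f_measure(self) -> float:
        return f_from_pr(self.precision, self.recall)

    def __add__(self, other: "EvalResult") -> "EvalResult":
        return EvalResult(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }


def _match_sets(predicted: Iterable, gold: Iterable) -> EvalResult:
    p, g = frozenset(predicted), frozenset(gold)
    tp = len(p & g)
    return EvalResult(tp=tp, fp=len(p) - tp, fn=len(g) - tp)


def match_entities(predicted: Iterable[Entity], gold: Iterable[Entity]) -> EvalResult:
    """Exact-match entity counts: tp = |P ∩ G|, fp = |P \\ G|, fn = |G \\ P|.

    Any label mismatch or any offset difference is a non-match.
    """
    return _match_sets(predicted, gold)


def match_links(predicted: Iterable[Link], gold: Iterable[Link]) -> EvalResult:
    """Exact-match link counts under link identity (both endpoints exact)."""
    return _match_sets(predicted, gold)


def prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """Precision, recall and F-measure from micro counts.

    Zero-denominator cases are defined as 0, which keeps the arithmetic on
    empty units well-behaved.
    """
    r = EvalResult(tp, fp, fn)
    return r.precision, r.recall, r.f_measure


def f_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean F = 2PR/(P+R), 0 when both are 0."""
    s = precision + recall
    return 2 * precision * recall / s if s else 0.0


def unit_exact_match(judgment: Judgment, unit: Unit) -> bool:
    """Whole-unit exact scoring used for worker trust accounting.

    The judgment counts as correct only if its entire payload equals the
    unit's expert answer set — there is no partial credit: annotating 2 of 3
    gold medications scores the whole unit as incorrect.
    """
    if not unit.is_gold:
        raise AnnotationError(f"unit {unit.unit_id} is not a gold unit")
    if judgment.unit_id != unit.unit_id:
        raise AnnotationError("judgment does not target this unit")
    if judgment.task_kind == "link":
        reference = unit.gold_links if unit.gold_links is not None else frozenset()
        return judgment.links == frozenset(reference)
    return judgment.entities == unit.gold_entities
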