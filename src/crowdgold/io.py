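"""On-disk formats: JSONL units/judgments, brat standoff, CSV judgment reports.

JSONL round-trips are lossless; writers are deterministic given identical
inputs (stable ordering, floats printed to 3 decimals in report tables).
The CSV judgment report mimics the shape of a crowdsourcing-platform export:
one row per judgment with ``unit_id, worker_id, trust, payload_json``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import yaml

from .model import Entity, Judgment, Link, Span, Unit

__all__ = [
    "ParseError",
    "RunConfig",
    "read_units",
    "write_units",
    "read_judgments",
    "write_judgments",
    "read_judgments_csv",
    "write_judgments_csv",
    "entities_to_brat",
    "write_brat",
]


class ParseError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline settings; the defaults are the production campaign's."""

    method: str = "simple"
    thresholds: Tuple[float, ...] = (0.20, 0.40, 0.60, 0.80)
    production_threshold: float = 0.40
    alpha: float = 0.05
    seed: int = 0
    judgments_per_unit: int = 5
    trust_threshold: float = 0.5
    training_required: int = 4
    gold_fraction: float = 0.20
    empty_unit_rate: float = 0.30

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in data:
            data["thresholds"] = tuple(data["thresholds"])
        return cls(**data)


# ---------------------------------------------------------------------------
# JSON encoding of the domain types
# ---------------------------------------------------------------------------


def _entity_to_dict(e: Entity) -> dict:
    return {"unit_id": e.unit_id, "label": e.label, "spans": [[s.start, s.end] for s in e.spans]}


def _entity_from_dict(d: dict) -> Entity:
    return Entity(d["unit_id"], d["label"], tuple(Span(a, b) for a, b in d["spans"]))


def _link_to_dict(l: Link) -> dict:
    return {
        "unit_id": l.unit_id,
        "medication": _entity_to_dict(l.medication),
        "attribute": _entity_to_dict(l.attribute),
    }


def _link_from_dict(d: dict) -> Link:
    return Link(d["unit_id"], _entity_from_dict(d["medication"]), _entity_from_dict(d["attribute"]))


def _sorted_entities(es: Iterable[Entity]) -> List[Entity]:
    return sorted(es, key=lambda e: (e.start, e.end, e.label))


def _unit_to_dict(u: Unit) -> dict:
    return {
        "unit_id": u.unit_id,
        "doc_id": u.doc_id,
        "text": u.text,
        "token_count": u.token_count,
        "is_gold": u.is_gold,
        "gold_entities": None
        if u.gold_entities is None
        else [_entity_to_dict(e) for e in _sorted_entities(u.gold_entities)],
        "gold_links": None
        if u.gold_links is None
        else [
            _link_to_dict(l)
            for l in sorted(
                u.gold_links, key=lambda l: (l.attribute.start, l.medication.start)
            )
        ],
    }


def _unit_from_dict(d: dict) -> Unit:
    return Unit(
        unit_id=d["unit_id"],
        doc_id=d["doc_id"],
        text=d["text"],
        token_count=d["token_count"],
        is_gold=d.get("is_gold", False),
        gold_entities=None
        if d.get("gold_entities") is None
        else frozenset(_entity_from_dict(e) for e in d["gold_entities"]),
        gold_links=None
        if d.get("gold_links") is None
        else frozenset(_link_from_dict(l) for l in d["gold_links"]),
    )


def _judgment_to_dict(j: Judgment) -> dict:
    d = {
        "judgment_id": j.judgment_id,
        "turker_id": j.turker_id,
        "unit_id": j.unit_id,
        "task_kind": j.task_kind,
    }
    if j.task_kind == "link":
        d["links"] = [
            _link_to_dict(l)
            for l in sorted(j.links, key=lambda l: (l.attribute.start, l.medication.start))
        ]
    else:
        d["entities"] = [_entity_to_dict(e) for e in _sorted_entities(j.entities)]
    return d


def _judgment_from_dict(d: dict) -> Judgment:
    kw = {}
    if d["task_kind"] == "link":
        kw["links"] = frozenset(_link_from_dict(l) for l in d["links"])
    else:
        kw["entities"] = frozenset(_entity_from_dict(e) for e in d["entities"])
    return Judgment(d["judgment_id"], d["turker_id"], d["unit_id"], d["task_kind"], **kw)


# ---------------------------------------------------------------------------
# JSONL readers/writers
# ---------------------------------------------------------------------------


def _write_jsonl(path, records: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _read_jsonl(path) -> List[dict]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                out.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSON ({exc})") from exc
    return out


def write_units(path, units: Sequence[Unit]) -> None:
    _write_jsonl(path, (_unit_to_dict(u) for u in units))


def read_units(path) -> List[Unit]:
    units = []
    for lineno, d in enumerate(_read_jsonl(path), 1):
        try:
            units.append(_unit_from_dict(d))
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return units


def write_judgments(path, judgments: Sequence[Judgment]) -> None:
    _write_jsonl(path, (_judgment_to_dict(j) for j in judgments))


def read_judgments(path) -> List[Judgment]:
    js = []
    for lineno, d in enumerate(_read_jsonl(path), 1):
        try:
            js.append(_judgment_from_dict(d))
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return js


# ---------------------------------------------------------------------------
# CSV judgment report (platform-export-like dialect)
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["judgment_id", "unit_id", "worker_id", "trust", "task_kind", "payload_json"]


def write_judgments_csv(
    path, judgments: Sequence[Judgment], trusts: Optional[Mapping[str, float]] = None
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for j in judgments:
            d = _judgment_to_dict(j)
            payload = {"links": d["links"]} if j.task_kind == "link" else {"entities": d["entities"]}
            w.writerow(
                {
                    "judgment_id": j.judgment_id,
                    "unit_id": j.unit_id,
                    "worker_id": j.turker_id,
                    "trust": f"{trusts.get(j.turker_id, 1.0):.3f}" if trusts else "",
                    "task_kind": j.task_kind,
                    "payload_json": json.dumps(payload, sort_keys=True),
                }
            )


def read_judgments_csv(path) -> Tuple[List[Judgment], Dict[str, float]]:
    """Parse a judgment report; returns judgments plus reported worker trusts.

    Duplicate (worker, unit) rows are rejected — a worker judges a unit once.
    """
    judgments: List[Judgment] = []
    trusts: Dict[str, float] = {}
    seen = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "unit_id" not in reader.fieldnames:
            raise ParseError(f"{path}: missing header row")
        for lineno, row in enumerate(reader, 2):
            key = (row["worker_id"], row["unit_id"])
            if key in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate judgment {key}")
            seen.add(key)
            try:
                payload = json.loads(row["payload_json"])
                d = {
                    "judgment_id": row["judgment_id"],
                    "turker_id": row["worker_id"],
                    "unit_id": row["unit_id"],
                    "task_kind": row["task_kind"],
                    **payload,
                }
                judgments.append(_judgment_from_dict(d))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if row.get("trust"):
                trusts[row["worker_id"]] = float(row["trust"])
    return judgments, trusts


# ---------------------------------------------------------------------------
# brat standoff
# ---------------------------------------------------------------------------


def entities_to_brat(
    entities: Sequence[Entity], text: str, links: Sequence[Link] = ()
) -> str:
    """brat .ann serialization; links become LINK relations.

    Discontinuous entities use the semicolon-separated multi-fragment span
    syntax; the text column joins fragments with a space.
    """
    lines = []
    ids: Dict[Entity, str] = {}
    for i, e in enumerate(_sorted_entities(entities), 1):
        tid = f"T{i}"
        ids[e] = tid
        frag = ";".join(f"{s.start} {s.end}" for s in e.spans)
        lines.append(f"{tid}\t{e.label} {frag}\t{e.text(text)}")
    for r, l in enumerate(
        sorted(links, key=lambda l: (l.attribute.start, l.medication.start)), 1
    ):
        lines.append(f"R{r}\tLINK Arg1:{ids[l.medication]} Arg2:{ids[l.attribute]}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_brat(directory, units: Sequence[Unit]) -> None:
    """One .txt/.ann pair per unit under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for u in units:
        stem = u.unit_id.replace(":", "_")
        (directory / f"{stem}.txt").write_text(u.text, encoding="utf-8")
        ann = entities_to_brat(
            sorted(u.gold_entities or (), key=lambda e: (e.start, e.end, e.label)),
            u.text,
            sorted(u.gold_links or (), key=lambda l: (l.attribute.start, l.medication.start)),
        )
        (directory / f"{stem}.ann").write_text(ann, encoding="utf-8")
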