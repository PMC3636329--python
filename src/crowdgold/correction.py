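"""The iterative correction round.

Unique judgments from a finished annotation job are resubmitted as
pre-annotated tasks; fresh workers may add annotations, remove them, or
leave the unit unchanged.  Corrections are merged by pooling *all* correction
judgments per unit and voting exactly as in first-round aggregation.  A
per-source improvement analysis compares each unique judgment's F-measure
against the simple-vote (threshold 0.40) merge of its own corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model import EvalResult, Judgment, _match_sets
from .voting import ExperienceTable, VotingError, vote

__all__ = [
    "CorrectionError",
    "CorrectionTask",
    "dedupe_judgments",
    "build_correction_round",
    "merge_corrections",
    "improvement_analysis",
    "relative_improvement",
    "IMPROVED",
    "WORSE",
    "UNCHANGED",
]

IMPROVED = "improved"
WORSE = "worse"
UNCHANGED = "unchanged"


class CorrectionError(ValueError):
    pass


@dataclass
class CorrectionTask:
    """One unique judgment fanned out for k correction judgments."""

    source_judgment_id: str
    unit_id: str
    preannotated: frozenset
    n_corrections: int = 5
    corrections: List[Judgment] = field(default_factory=list)


def dedupe_judgments(judgments: Sequence[Judgment]) -> List[Judgment]:
    """Collapse per-unit duplicate payloads to one representative.

    Equality is payload identity (offsets + labels), not surface text.
    Output order is stable by first occurrence; idempotent.
    """
    seen: Dict[str, set] = {}
    unique: List[Judgment] = []
    for j in judgments:
        key = j.payload
        bucket = seen.setdefault(j.unit_id, set())
        if key not in bucket:
            bucket.add(key)
            unique.append(j)
    return unique


def build_correction_round(
    unique_judgments: Sequence[Judgment], k: int = 5
) -> List[CorrectionTask]:
    """One task per unique judgment, each requesting *k* corrections."""
    if k < 1:
        raise CorrectionError("k must be >= 1")
    return [
        CorrectionTask(
            source_judgment_id=j.judgment_id,
            unit_id=j.unit_id,
            preannotated=j.payload,
            n_corrections=k,
        )
        for j in unique_judgments
    ]


def merge_corrections(
    tasks: Sequence[CorrectionTask],
    method: str = "simple",
    threshold: float = 0.40,
    *,
    turker_states: Optional[Mapping] = None,
    experience: Optional[ExperienceTable] = None,
) -> Dict[str, frozenset]:
    """Pool all corrections per unit (across source judgments) and vote.

    J for each unit is the pooled correction count — e.g. 3 unique judgments
    with 5 corrections each give J = 15 for that unit.
    """
    pooled: List[Judgment] = [c for t in tasks for c in t.corrections]
    if not pooled:
        raise CorrectionError("no correction judgments to merge")
    if method == "experience" and experience is None:
        experience = ExperienceTable.from_judgments(pooled)
    by_unit: Dict[str, List[Judgment]] = {}
    for j in pooled:
        by_unit.setdefault(j.unit_id, []).append(j)
    merged: Dict[str, frozenset] = {}
    for uid, js in by_unit.items():
        selected, _ = vote(
            js, method, threshold, turker_states=turker_states, experience=experience
        )
        merged[uid] = selected
    return merged


def improvement_analysis(
    tasks: Sequence[CorrectionTask],
    gold: Mapping[str, frozenset],
    threshold: float = 0.40,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Per-source-judgment improvement labels under simple voting.

    For each task, F_original is the pre-annotated payload scored against
    the unit's gold; F_corrected is the simple vote at *threshold* over the
    task's own k corrections, scored against the same gold.  Labels:
    improved / worse / unchanged (exact float comparison).
    """
    rows = []
    counts = {IMPROVED: 0, WORSE: 0, UNCHANGED: 0}
    for t in tasks:
        if not t.corrections:
            raise CorrectionError(
                f"task for judgment {t.source_judgment_id} has no corrections"
            )
        gold_set = gold[t.unit_id]
        f_orig = _match_sets(t.preannotated, gold_set).f_measure
        selected, _ = vote(t.corrections, "simple", threshold)
        f_corr = _match_sets(selected, gold_set).f_measure
        if f_corr > f_orig:
            label = IMPROVED
        elif f_corr < f_orig:
            label = WORSE
        else:
            label = UNCHANGED
        counts[label] += 1
        rows.append(
            {
                "source_judgment_id": t.source_judgment_id,
                "unit_id": t.unit_id,
                "f_original": f_orig,
                "f_corrected": f_corr,
                "label": label,
            }
        )
    return pd.DataFrame(rows), counts


def relative_improvement(baseline_f: float, corrected_f: float) -> float:
    """Percent change (corrected - baseline) / baseline * 100."""
    if baseline_f <= 0:
        raise CorrectionError("relative improvement undefined for baseline F <= 0")
    return (corrected_f - baseline_f) / baseline_f * 100.0
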