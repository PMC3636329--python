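"""Adjudication of multiple crowd judgments per unit by thresholded voting.

Three voting methods are implemented, all operating at the entity (or link)
level with micro averaging.  With ``e`` votes for a candidate out of ``J``
judgments on the unit:

* **simple**: score = e / J.  At J = 5 and threshold 0.40 this is the
  "2 or more of 5 votes" production rule.
* **trust**: each vote is weighted by the voter's trust score t_i in [0, 1];
  score = (sum of voters' t_i) / J.
* **experience**: each vote is weighted by w_i = log(1 + u_i) / log(1 + m),
  where u_i is the number of judgments worker i performed and m the maximum
  over workers, so the most prolific worker votes with weight 1; the
  logarithm compresses the heavy-tailed activity distribution.

Dividing by J normalizes every score to [0, 1]; a candidate is selected iff
its score reaches the threshold (ties select).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model import EvalResult, Judgment, _match_sets

__all__ = [
    "VotingError",
    "VoteTally",
    "ExperienceTable",
    "simple_vote",
    "trust_vote",
    "experience_vote",
    "vote",
    "aggregate_corpus",
    "threshold_sweep",
    "METHODS",
]

METHODS = ("simple", "trust", "experience")


class VotingError(ValueError):
    pass


@dataclass
class VoteTally:
    """Score sheet for one candidate entity or link on one unit."""

    candidate: Hashable
    votes: int
    judgment_count: int
    score: float
    selected: bool


@dataclass
class ExperienceTable:
    """Per-worker activity counts u_i and the campaign maximum m."""

    counts: Dict[str, int]

    def __post_init__(self) -> None:
        if self.counts and min(self.counts.values()) < 1:
            raise VotingError("experience counts must be >= 1")

    @classmethod
    def from_judgments(cls, judgments: Iterable[Judgment]) -> "ExperienceTable":
        counts: Dict[str, int] = {}
        for j in judgments:
            counts[j.turker_id] = counts.get(j.turker_id, 0) + 1
        return cls(counts)

    @property
    def m(self) -> int:
        if not self.counts:
            raise VotingError("empty experience table")
        return max(self.counts.values())

    def weight(self, turker_id: str) -> float:
        """log(1+u_i)/log(1+m): 1 for the most prolific worker."""
        try:
            u = self.counts[turker_id]
        except KeyError:
            raise VotingError(f"no experience recorded for worker {turker_id}")
        return math.log1p(u) / math.log1p(self.m)


def _trust_of(states: Mapping, turker_id: str) -> float:
    try:
        entry = states[turker_id]
    except KeyError:
        raise VotingError(f"no trust available for worker {turker_id}")
    t = entry.trust if hasattr(entry, "trust") else float(entry)
    if not (0.0 <= t <= 1.0):
        raise VotingError(f"trust {t} for {turker_id} outside [0, 1]")
    return t


def _tally(
    judgments: Sequence[Judgment],
    threshold: float,
    weight_fn: Callable[[str], float],
) -> Tuple[frozenset, List[VoteTally]]:
    if not judgments:
        raise VotingError("cannot adjudicate a unit with zero judgments")
    if not (0.0 < threshold <= 1.0):
        raise VotingError(f"threshold {threshold} outside (0, 1]")
    unit_ids = {j.unit_id for j in judgments}
    if len(unit_ids) != 1:
        raise VotingError(f"judgments span multiple units: {sorted(unit_ids)}")
    J = len(judgments)
    votes: Dict[Hashable, int] = {}
    weights: Dict[Hashable, float] = {}
    for j in judgments:
        w = weight_fn(j.turker_id)
        for cand in j.payload:
            votes[cand] = votes.get(cand, 0) + 1
            weights[cand] = weights.get(cand, 0.0) + w
    tallies = [
        VoteTally(
            candidate=c,
            votes=votes[c],
            judgment_count=J,
            score=weights[c] / J,
            selected=weights[c] / J >= threshold,
        )
        for c in votes
    ]
    tallies.sort(key=lambda t: (-t.score, repr(t.candidate)))
    selected = frozenset(t.candidate for t in tallies if t.selected)
    return selected, tallies


def simple_vote(
    judgments: Sequence[Judgment], threshold: float = 0.40
) -> Tuple[frozenset, List[VoteTally]]:
    """Unweighted vote: select candidates with e/J >= threshold."""
    return _tally(judgments, threshold, lambda tid: 1.0)


def trust_vote(
    judgments: Sequence[Judgment],
    turker_states: Mapping,
    threshold: float = 0.24,
) -> Tuple[frozenset, List[VoteTally]]:
    """Trust-weighted vote: a worker with trust 0.75 casts a 0.75 vote."""
    return _tally(judgments, threshold, lambda tid: _trust_of(turker_states, tid))


def experience_vote(
    judgments: Sequence[Judgment],
    experience: ExperienceTable,
    threshold: float = 0.24,
) -> Tuple[frozenset, List[VoteTally]]:
    """Experience-weighted vote using log-scaled relative activity."""
    return _tally(judgments, threshold, experience.weight)


def vote(
    judgments: Sequence[Judgment],
    method: str,
    threshold: float,
    *,
    turker_states: Optional[Mapping] = None,
    experience: Optional[ExperienceTable] = None,
) -> Tuple[frozenset, List[VoteTally]]:
    """Dispatch on method name; unknown names are a configuration error."""
    if method == "simple":
        return simple_vote(judgments, threshold)
    if method == "trust":
        if turker_states is None:
            raise VotingError("trust voting requires turker states")
        return trust_vote(judgments, turker_states, threshold)
    if method == "experience":
        if experience is None:
            raise VotingError("experience voting requires an experience table")
        return experience_vote(judgments, experience, threshold)
    raise VotingError(f"unknown voting method {method!r}; expected one of {METHODS}")


def _group_by_unit(judgments: Iterable[Judgment]) -> Dict[str, List[Judgment]]:
    groups: Dict[str, List[Judgment]] = {}
    for j in judgments:
        groups.setdefault(j.unit_id, []).append(j)
    return groups


def aggregate_corpus(
    judgments: Sequence[Judgment],
    method: str,
    threshold: float,
    gold: Optional[Mapping[str, frozenset]] = None,
    *,
    turker_states: Optional[Mapping] = None,
    experience: Optional[ExperienceTable] = None,
) -> Tuple[Dict[str, frozenset], Optional[EvalResult]]:
    """Adjudicate every unit, then score the whole corpus micro-averaged.

    ``gold`` maps unit_id to the expert entity (or link) set; every unit in
    ``gold`` contributes to the pooled counts, with units lacking judgments
    adjudicated empty.  J is the number of judgments actually collected for
    each unit, so under-subscribed units still aggregate.
    """
    if method == "experience" and experience is None:
        experience = ExperienceTable.from_judgments(judgments)
    groups = _group_by_unit(judgments)
    if gold is not None:
        unknown = set(groups) - set(gold)
        if unknown:
            raise VotingError(f"judgments reference units absent from gold: {sorted(unknown)[:5]}")
    adjudicated: Dict[str, frozenset] = {}
    for uid, js in groups.items():
        selected, _ = vote(
            js, method, threshold, turker_states=turker_states, experience=experience
        )
        adjudicated[uid] = selected
    if gold is None:
        return adjudicated, None
    total = EvalResult()
    for uid, gold_set in gold.items():
        total = total + _match_sets(adjudicated.get(uid, frozenset()), gold_set)
    return adjudicated, total


def threshold_sweep(
    judgments: Sequence[Judgment],
    method: str,
    thresholds: Sequence[float],
    gold: Mapping[str, frozenset],
    *,
    turker_states: Optional[Mapping] = None,
    experience: Optional[ExperienceTable] = None,
) -> pd.DataFrame:
    """One P/R/F row per threshold, ascending — the shape of a results table."""
    if not thresholds:
        raise VotingError("threshold sweep needs at least one threshold")
    if method == "experience" and experience is None:
        experience = ExperienceTable.from_judgments(judgments)
    rows = []
    for th in sorted(thresholds):
        _, result = aggregate_corpus(
            judgments,
            method,
            th,
            gold,
            turker_states=turker_states,
            experience=experience,
        )
        rows.append(
            {
                "threshold": th,
                "precision": result.precision,
                "recall": result.recall,
                "f_measure": result.f_measure,
            }
        )
    return pd.DataFrame(rows)
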