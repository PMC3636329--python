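"""Worker admission and continuous trust accounting.

Crowd workers ("turkers") pass a training gate (4 exactly-correct training
examples), then are monitored on hidden gold units interleaved in their task
stream.  Trust is the fraction of gold units answered with a unit-level
exact match.  A trusted worker whose trust slips below 50% is warned; if
after the next two gold tests trust has not recovered to >= 50% the worker
is blocked and their entire output is excluded.  Blocking is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import pandas as pd

from .model import Judgment

__all__ = [
    "IN_TRAINING",
    "TRUSTED",
    "WARNED",
    "BLOCKED",
    "TRUST_THRESHOLD",
    "TRAINING_REQUIRED",
    "PROBATION_GOLD_TESTS",
    "QCError",
    "TurkerState",
    "training_gate",
    "record_gold_result",
    "filter_trusted",
    "qc_report",
]

IN_TRAINING = "in_training"
TRUSTED = "trusted"
WARNED = "warned"
BLOCKED = "blocked"

TRUST_THRESHOLD = 0.5      # unit-level: at least 2 of 4 gold units exact
TRAINING_REQUIRED = 4      # correct training examples to enter production
PROBATION_GOLD_TESTS = 2   # gold tests granted after a warning


class QCError(ValueError):
    """Invalid quality-control transition or unknown worker."""


@dataclass
class TurkerState:
    """Trust accounting for one worker.

    ``trust`` is always the running fraction of exactly-matched gold units.
    Status moves only along in_training -> trusted -> warned -> {trusted,
    blocked}; blocked is absorbing.
    """

    turker_id: str
    status: str = IN_TRAINING
    gold_results: List[bool] = field(default_factory=list)
    training_correct: int = 0
    judgments_submitted: int = 0
    probation_remaining: int = 0
    quiz_passed: bool = True  # the sign-up quiz, modelled as a flag only

    @property
    def trust(self) -> float:
        if not self.gold_results:
            return 1.0 if self.status in (TRUSTED, WARNED) else 0.0
        return sum(self.gold_results) / len(self.gold_results)

    @property
    def gold_seen(self) -> int:
        return len(self.gold_results)

    @property
    def gold_correct(self) -> int:
        return sum(self.gold_results)


def training_gate(state: TurkerState, training_outcomes: Iterable[bool]) -> TurkerState:
    """Feed training-example outcomes; promote after 4 correct ones.

    Outcomes beyond the promotion point are ignored.  Workers that never
    accumulate 4 correct examples remain ``in_training`` and receive no
    production tasks.
    """
    if state.status != IN_TRAINING:
        raise QCError(f"{state.turker_id} is not in training (status={state.status})")
    for ok in training_outcomes:
        state.training_correct += bool(ok)
        if state.training_correct >= TRAINING_REQUIRED:
            state.status = TRUSTED
            break
    return state


def record_gold_result(state: TurkerState, matched: bool) -> TurkerState:
    """Record one gold-unit outcome and run the warn/block transitions.

    Trusted worker dropping below 50% trust -> warned, with a two-gold-test
    probation.  During probation, recovering to >= 50% restores trusted;
    exhausting the probation still below 50% blocks the worker for good.
    """
    if state.status not in (TRUSTED, WARNED):
        raise QCError(
            f"cannot score gold unit for {state.turker_id} (status={state.status})"
        )
    state.gold_results.append(bool(matched))
    if state.status == TRUSTED:
        if state.trust < TRUST_THRESHOLD:
            state.status = WARNED
            state.probation_remaining = PROBATION_GOLD_TESTS
    else:  # warned: on probation
        state.probation_remaining -= 1
        if state.trust >= TRUST_THRESHOLD:
            state.status = TRUSTED
            state.probation_remaining = 0
        elif state.probation_remaining <= 0:
            state.status = BLOCKED
    return state


def filter_trusted(
    judgments: Sequence[Judgment], states: Mapping[str, TurkerState]
) -> List[Judgment]:
    """Drop the entire output of blocked workers; keep trusted/warned output."""
    out = []
    for j in judgments:
        try:
            state = states[j.turker_id]
        except KeyError:
            raise QCError(f"judgment {j.judgment_id} from unknown worker {j.turker_id}")
        if state.status != BLOCKED:
            out.append(j)
    return out


def qc_report(
    states: Mapping[str, TurkerState], judgments: Sequence[Judgment] = ()
) -> pd.DataFrame:
    """Per-worker summary table (gold seen/correct, trust, status, retention)."""
    per_worker: Dict[str, int] = {}
    for j in judgments:
        per_worker[j.turker_id] = per_worker.get(j.turker_id, 0) + 1
    rows = []
    for tid in sorted(states):
        s = states[tid]
        n = per_worker.get(tid, s.judgments_submitted)
        rows.append(
            {
                "turker_id": tid,
                "gold_seen": s.gold_seen,
                "gold_correct": s.gold_correct,
                "trust": round(s.trust, 3),
                "status": s.status,
                "judgments_submitted": n,
                "judgments_retained": 0 if s.status == BLOCKED else n,
            }
        )
    return pd.DataFrame(rows)
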