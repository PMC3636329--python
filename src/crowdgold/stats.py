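"""Pooling chi-square test of crowd-vs-expert annotation equivalence.

The question: does folding the expert corpus into the crowd's voted results
change the correct/incorrect composition?  The null hypothesis is that the
expert output does not change the quality profile of the crowd's
annotations.  The 2x2 table contrasts the crowd's outcome counts with the
pooled (crowd + expert) counts; a Pearson chi-square on this table with
1 df yields the decision at alpha (default 0.05).  If p >= alpha there is
no evidence of a difference between crowd and expert annotation quality.

By construction the pooled row contains the crowd counts again; this is the
literal "pool, then test against the original" design and makes the test
conservative.  A plain crowd-vs-expert homogeneity table is available with
``pooled=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "OutcomeCounts",
    "ChiSquareResult",
    "pooling_chi_square",
    "hypothesis_report",
]

NO_DIFFERENCE = "no significant difference"
SIGNIFICANT = "significant difference"


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeCounts:
    """Unique entities annotated correctly / incorrectly against a reference."""

    correct: int
    incorrect: int

    def __post_init__(self) -> None:
        if self.correct < 0 or self.incorrect < 0:
            raise StatsError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.correct + self.incorrect


@dataclass
class ChiSquareResult:
    chi2: float
    p_value: float
    alpha: float
    decision: str
    table: np.ndarray


def pooling_chi_square(
    crowd: OutcomeCounts,
    expert: OutcomeCounts,
    alpha: float = 0.05,
    *,
    pooled: bool = True,
    continuity: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square (1 df) between crowd counts and pooled counts.

    ``pooled=True`` (default) uses rows [crowd, crowd + expert]; with
    ``pooled=False`` the rows are [crowd, expert] (ordinary homogeneity
    test).  No Yates continuity correction unless ``continuity=True``.
    """
    if crowd.total == 0 or expert.total == 0:
        raise StatsError("each group needs at least one counted entity")
    if pooled:
        table = np.array(
            [
                [crowd.correct, crowd.incorrect],
                [crowd.correct + expert.correct, crowd.incorrect + expert.incorrect],
            ],
            dtype=float,
        )
    else:
        table = np.array(
            [[crowd.correct, crowd.incorrect], [expert.correct, expert.incorrect]],
            dtype=float,
        )
    # degenerate column margin (e.g. nobody incorrect): proportions are
    # identical by construction, chi-square carries no information
    if np.any(table.sum(axis=0) == 0):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=continuity)
    decision = NO_DIFFERENCE if p >= alpha else SIGNIFICANT
    return ChiSquareResult(chi2=float(chi2), p_value=float(p), alpha=alpha, decision=decision, table=table)


def hypothesis_report(
    results: Mapping[str, Tuple[OutcomeCounts, OutcomeCounts]],
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Tabulate the pooling chi-square per task (names, types, linking...)."""
    rows = []
    for task, (crowd, expert) in results.items():
        r = pooling_chi_square(crowd, expert, alpha=alpha, **kwargs)
        rows.append(
            {
                "task": task,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "alpha": alpha,
                "decision": r.decision,
            }
        )
    return pd.DataFrame(rows, columns=["task", "chi2", "p_value", "alpha", "decision"])
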