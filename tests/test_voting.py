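"""Voting methods: thresholds, weights, reductions and monotonicity."""

import itertools
import math

import numpy as np
import pytest

from crowdgold.model import Entity, Span
from crowdgold.voting import (
    ExperienceTable,
    VotingError,
    aggregate_corpus,
    experience_vote,
    simple_vote,
    threshold_sweep,
    trust_vote,
    vote,
)
from conftest import ent, judgment


def unit_judgments(vote_pattern, candidate=None, unit_id="u"):
    """One candidate entity voted for according to a boolean pattern."""
    candidate = candidate or ent(unit_id, "MEDICATION_NAME", (0, 4))
    return [
        judgment(f"j{i}", f"t{i}", unit_id, {candidate} if v else set())
        for i, v in enumerate(vote_pattern)
    ]


class TestSimpleVote:
    def test_two_of_five_selected_at_040(self):
        sel, tallies = simple_vote(unit_judgments([1, 1, 0, 0, 0]), 0.40)
        assert len(sel) == 1
        assert tallies[0].score == pytest.approx(0.4) and tallies[0].selected

    def test_one_of_five_rejected(self):
        sel, tallies = simple_vote(unit_judgments([1, 0, 0, 0, 0]), 0.40)
        assert not sel and tallies[0].score == pytest.approx(0.2)

    def test_unanimous_selected_at_any_threshold(self):
        for th in (0.2, 0.5, 1.0):
            sel, _ = simple_vote(unit_judgments([1] * 5), th)
            assert len(sel) == 1

    def test_exhaustive_patterns_match_brute_force(self):
        """All 2^5 vote patterns: selection iff >= 2 raw votes at th 0.40."""
        for pattern in itertools.product([0, 1], repeat=5):
            sel, _ = simple_vote(unit_judgments(pattern), 0.40)
            assert bool(sel) == (sum(pattern) >= 2)

    def test_zero_judgments_is_an_error(self):
        with pytest.raises(VotingError):
            simple_vote([], 0.4)


class TestTrustVote:
    def test_single_075_vote_scores_015(self):
        js = unit_judgments([1, 0, 0, 0, 0])
        trusts = {f"t{i}": 0.75 for i in range(5)}
        sel, tallies = trust_vote(js, trusts, threshold=0.24)
        assert tallies[0].score == pytest.approx(0.15)
        assert not sel

    def test_mixed_weights(self):
        js = unit_judgments([1, 1, 0, 0])
        sel, tallies = trust_vote(js, {"t0": 1.0, "t1": 0.5, "t2": 0.9, "t3": 0.9}, 0.24)
        assert tallies[0].score == pytest.approx(0.375)
        assert sel

    def test_missing_trust_is_an_error(self):
        with pytest.raises(VotingError):
            trust_vote(unit_judgments([1, 1]), {"t0": 1.0}, 0.24)


class TestExperienceVote:
    def test_most_prolific_weight_is_one(self):
        t = ExperienceTable({"a": 163, "b": 10})
        assert t.weight("a") == pytest.approx(1.0)
        assert t.weight("b") == pytest.approx(math.log(11) / math.log(164))

    def test_log_scaled_vote(self):
        js = unit_judgments([1, 0, 0, 0, 0])
        table = ExperienceTable({f"t{i}": 163 if i else 10 for i in range(5)})
        _, tallies = experience_vote(js, table, 0.24)
        assert tallies[0].score == pytest.approx(math.log(11) / math.log(164) / 5)

    def test_zero_experience_rejected(self):
        with pytest.raises(VotingError):
            ExperienceTable({"a": 0})


def random_unit_judgments(rng, unit_id, n_judges=5, n_candidates=4):
    cands = [ent(unit_id, "MEDICATION_NAME", (i * 10, i * 10 + 5)) for i in range(n_candidates)]
    out = []
    for j in range(n_judges):
        picked = {c for c in cands if rng.random() < 0.5}
        out.append(judgment(f"{unit_id}-j{j}", f"t{j}", unit_id, picked))
    return out


class TestReductionsAndMonotonicity:
    def test_all_trust_one_reduces_to_simple(self):
        rng = np.random.default_rng(0)
        trusts = {f"t{j}": 1.0 for j in range(5)}
        for k in range(200):
            js = random_unit_judgments(rng, f"u{k}")
            s, _ = simple_vote(js, 0.4)
            t, _ = trust_vote(js, trusts, 0.4)
            assert s == t

    def test_equal_experience_reduces_to_simple(self):
        rng = np.random.default_rng(1)
        table = ExperienceTable({f"t{j}": 7 for j in range(5)})
        for k in range(200):
            js = random_unit_judgments(rng, f"u{k}")
            s, _ = simple_vote(js, 0.4)
            e, _ = experience_vote(js, table, 0.4)
            assert s == e

    def test_weighted_scores_never_exceed_simple(self):
        rng = np.random.default_rng(2)
        trusts = {f"t{j}": rng.uniform(0.3, 1.0) for j in range(5)}
        table = ExperienceTable({f"t{j}": int(rng.integers(1, 50)) for j in range(5)})
        for k in range(50):
            js = random_unit_judgments(rng, f"u{k}")
            _, simple_t = simple_vote(js, 0.4)
            simple_scores = {t.candidate: t.score for t in simple_t}
            for _, tallies in (trust_vote(js, trusts, 0.4), experience_vote(js, table, 0.4)):
                for t in tallies:
                    assert t.score <= simple_scores[t.candidate] + 1e-12

    def test_raising_threshold_never_adds_candidates(self):
        rng = np.random.default_rng(3)
        for k in range(50):
            js = random_unit_judgments(rng, f"u{k}")
            prev = None
            for th in (0.2, 0.4, 0.6, 0.8, 1.0):
                sel, _ = simple_vote(js, th)
                if prev is not None:
                    assert sel <= prev
                prev = sel


class TestAggregateCorpus:
    def test_error_free_crowd_is_perfect(self):
        gold = {}
        js = []
        for k in range(10):
            cand = ent(f"u{k}", "MEDICATION_NAME", (0, 5))
            gold[f"u{k}"] = frozenset({cand})
            js += unit_judgments([1] * 5, cand, f"u{k}")
        for th in (0.2, 0.6, 1.0):
            _, res = aggregate_corpus(js, "simple", th, gold)
            assert res.f_measure == 1.0

    def test_unknown_method_is_a_configuration_error(self):
        with pytest.raises(VotingError, match="unknown voting method"):
            vote(unit_judgments([1]), "median", 0.4)

    def test_units_without_judgments_count_as_misses(self):
        cand = ent("u0", "MEDICATION_NAME", (0, 5))
        gold = {"u0": frozenset({cand}), "u1": frozenset({ent("u1", "MEDICATION_NAME", (0, 5))})}
        _, res = aggregate_corpus(unit_judgments([1] * 5, cand, "u0"), "simple", 0.4, gold)
        assert (res.tp, res.fp, res.fn) == (1, 0, 1)

    def test_sweep_single_threshold_matches_aggregate(self):
        cand = ent("u0", "MEDICATION_NAME", (0, 5))
        gold = {"u0": frozenset({cand})}
        js = unit_judgments([1, 1, 0, 0, 0], cand, "u0")
        table = threshold_sweep(js, "simple", [0.4], gold)
        _, res = aggregate_corpus(js, "simple", 0.4, gold)
        assert len(table) == 1
        assert table.iloc[0].f_measure == pytest.approx(res.f_measure)

    def test_sweep_requires_thresholds(self):
        with pytest.raises(VotingError):
            threshold_sweep([], "simple", [], {})
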