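"""Synthetic corpus and crowd-behaviour generator."""

import numpy as np
import pytest

from crowdgold.corpus import PrepConfig, select_gold_units
from crowdgold.model import MEDICATION_LABELS, match_entities
from crowdgold.qc import BLOCKED, IN_TRAINING
from crowdgold.simulate import (
    CampaignError,
    SimConfig,
    TurkerProfile,
    distinct_variants,
    generate_gold_corpus,
    generate_units,
    make_profiles,
    simulate_crowd,
    simulate_judgment,
)


class TestGenerateGoldCorpus:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_docs=5, seed=42)
        a, b = generate_gold_corpus(cfg), generate_gold_corpus(cfg)
        assert [d.text for d in a] == [d.text for d in b]
        assert [d.entities for d in a] == [d.entities for d in b]

    def test_spans_extract_surfaces_and_links_are_local(self):
        _, units = generate_units(SimConfig(n_docs=10, seed=1))
        for u in units:
            for e in u.gold_entities:
                surface = e.text(u.text)
                assert surface == u.text[e.start : e.end]
                assert surface.strip() == surface
            for l in u.gold_links:
                assert l.medication in u.gold_entities
                assert l.attribute in u.gold_entities

    def test_unit_floor_and_empty_rate(self):
        _, units = generate_units(SimConfig(n_docs=60, seed=2))
        assert all(u.token_count >= 50 for u in units)
        rate = sum(u.is_empty for u in units) / len(units)
        assert 0.2 < rate < 0.4

    def test_name_type_ratio_tracks_configured_densities(self):
        # large corpus so sampling noise sits well inside the 10% band
        _, units = generate_units(SimConfig(n_docs=400, seed=11))
        n_name = sum(1 for u in units for e in u.gold_entities if e.label == "MEDICATION_NAME")
        n_type = sum(1 for u in units for e in u.gold_entities if e.label == "MEDICATION_TYPE")
        target = 9968 / 11789
        assert abs(n_name / n_type - target) / target < 0.10

    def test_attributes_link_to_exactly_one_medication(self):
        _, units = generate_units(SimConfig(n_docs=10, seed=3))
        for u in units:
            attr_targets = {}
            for l in u.gold_links:
                attr_targets.setdefault(l.attribute, set()).add(l.medication)
            for med_set in attr_targets.values():
                assert len(med_set) == 1


class TestSimulateJudgment:
    @pytest.fixture
    def unit(self):
        _, units = generate_units(SimConfig(n_docs=5, seed=4))
        return next(u for u in units if len(u.gold_entities) >= 2)

    def test_error_free_worker_reproduces_gold(self, unit):
        p = TurkerProfile("perfect")
        j = simulate_judgment(p, unit, np.random.default_rng(0))
        assert j.entities == unit.gold_entities

    def test_total_miss_gives_empty_judgment(self, unit):
        p = TurkerProfile("absent", p_miss=1.0)
        j = simulate_judgment(p, unit, np.random.default_rng(0))
        assert j.entities == frozenset()

    def test_boundary_shift_moves_one_token(self, unit):
        p = TurkerProfile("shifty", p_boundary=1.0)
        j = simulate_judgment(p, unit, np.random.default_rng(0))
        assert j.entities != unit.gold_entities
        for e in j.entities:
            assert 0 <= e.start < e.end <= len(unit.text)

    def test_confusion_swaps_medication_labels_only(self, unit):
        p = TurkerProfile("confused", p_confuse=1.0)
        j = simulate_judgment(p, unit, np.random.default_rng(0))
        gold_by_span = {e.spans: e.label for e in unit.gold_entities}
        for e in j.entities:
            orig = gold_by_span[e.spans]
            if orig in MEDICATION_LABELS:
                assert e.label in MEDICATION_LABELS and e.label != orig
            else:
                assert e.label == orig

    def test_miss_rate_concentrates_on_per_worker_recall(self):
        _, units = generate_units(SimConfig(n_docs=150, seed=5))
        p = TurkerProfile("lossy", p_miss=0.2)
        rng = np.random.default_rng(6)
        total = None
        for u in units:
            j = simulate_judgment(p, u, rng)
            r = match_entities(j.entities, u.gold_entities)
            total = r if total is None else total + r
        n = total.tp + total.fn
        assert n > 1500
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(total.recall - 0.8) < 3 * se
        assert total.precision == 1.0


class TestSimulateCrowd:
    def test_perfect_workers_unanimous(self):
        _, units = generate_units(SimConfig(n_docs=5, seed=7))
        profiles = make_profiles(5, p_miss=0, p_spurious=0, p_boundary=0,
                                 p_confuse=0, heavy_tailed_activity=False)
        js, states = simulate_crowd(units, profiles, 5, seed=7)
        by_unit = {}
        for j in js:
            by_unit.setdefault(j.unit_id, []).append(j)
        for u in units:
            payloads = {j.entities for j in by_unit[u.unit_id]}
            assert len(by_unit[u.unit_id]) == 5 and payloads == {u.gold_entities}

    def test_heavy_tailed_activity_concentrates_jobs(self):
        _, units = generate_units(SimConfig(n_docs=40, seed=8))
        profiles = make_profiles(25, p_miss=0.05, heavy_tailed_activity=True)
        js, states = simulate_crowd(units, profiles, 5, seed=8)
        counts = sorted((s.judgments_submitted for s in states.values()), reverse=True)
        assert sum(counts[:5]) / sum(counts) > 0.40

    def test_unreliable_worker_gets_blocked(self):
        _, units = generate_units(SimConfig(n_docs=40, seed=9))
        select_gold_units(units, PrepConfig(seed=9))
        profiles = make_profiles(15, p_miss=0.02, p_spurious=0.01,
                                 heavy_tailed_activity=False)
        profiles.append(TurkerProfile("sloppy", p_miss=0.9, activity=3.0))
        js, states = simulate_crowd(units, profiles, 5, seed=9)
        assert states["sloppy"].status in (BLOCKED, IN_TRAINING)
        # a worker this bad never survives into the trusted pool
        if states["sloppy"].status == BLOCKED:
            assert states["sloppy"].trust < 0.5

    def test_too_small_pool_is_a_campaign_error(self):
        _, units = generate_units(SimConfig(n_docs=2, seed=10))
        with pytest.raises(CampaignError):
            simulate_crowd(units, make_profiles(3), 5, seed=0)


class TestDistinctVariants:
    def test_requested_count_and_distinctness(self):
        _, units = generate_units(SimConfig(n_docs=5, seed=12))
        unit = max(units, key=lambda u: len(u.gold_entities))
        variants = distinct_variants(unit, 5)
        assert len(variants) == 5 == len(set(variants))
        assert variants[0] == unit.gold_entities
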