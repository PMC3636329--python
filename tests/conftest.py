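import pytest

from crowdgold.model import Entity, Judgment, Link, Span, Unit


def ent(unit_id, label, *spans):
    """Entity from (start, end) pairs."""
    return Entity(unit_id, label, tuple(Span(a, b) for a, b in spans))


def judgment(jid, turker, unit_id, entities, task_kind="annotate"):
    return Judgment(jid, turker, unit_id, task_kind, entities=frozenset(entities))


def link_judgment(jid, turker, unit_id, links):
    return Judgment(jid, turker, unit_id, "link", links=frozenset(links))


@pytest.fixture
def toy_unit():
    """A 3-medication unit with gold annotations ('u1')."""
    text = "patients receiving ibuprofen or vancomycin or metformin daily"
    gold = frozenset(
        {
            ent("u1", "MEDICATION_NAME", (text.index("ibuprofen"), text.index("ibuprofen") + 9)),
            ent("u1", "MEDICATION_NAME", (text.index("vancomycin"), text.index("vancomycin") + 10)),
            ent("u1", "MEDICATION_NAME", (text.index("metformin"), text.index("metformin") + 9)),
        }
    )
    return Unit(
        unit_id="u1",
        doc_id="d1",
        text=text,
        token_count=8,
        is_gold=True,
        gold_entities=gold,
        gold_links=frozenset(),
    )


@pytest.fixture
def linked_sentence():
    """Two medications with nine linked attributes in one sentence.

    'Advair 250/50 diskus 1 puff and Singulair 5mg chewable 1 tablet once a day'
    """
    text = "Advair 250/50 diskus 1 puff and Singulair 5mg chewable 1 tablet once a day"

    def span_of(surface, from_pos=0):
        i = text.index(surface, from_pos)
        return i, i + len(surface)

    uid = "fig1"
    one_a = text.index(" 1 ") + 1
    s_start = text.index("Singulair")
    one_s = text.index(" 1 ", s_start) + 1
    advair = ent(uid, "MEDICATION_NAME", span_of("Advair"))
    singulair = ent(uid, "MEDICATION_NAME", span_of("Singulair"))
    attrs_advair = [
        ent(uid, "STRENGTH", span_of("250/50")),
        ent(uid, "FORM", span_of("diskus")),
        ent(uid, "DOSAGE", (one_a, one_a + 1)),
        ent(uid, "FORM", span_of("puff")),
    ]
    attrs_singulair = [
        ent(uid, "STRENGTH", span_of("5mg")),
        ent(uid, "FORM", span_of("chewable")),
        ent(uid, "DOSAGE", (one_s, one_s + 1)),
        ent(uid, "FORM", span_of("tablet")),
        ent(uid, "FREQUENCY", span_of("once a day")),
    ]
    links = frozenset(
        {Link(uid, advair, a) for a in attrs_advair}
        | {Link(uid, singulair, a) for a in attrs_singulair}
    )
    entities = frozenset([advair, singulair] + attrs_advair + attrs_singulair)
    unit = Unit(
        unit_id=uid,
        doc_id="figdoc",
        text=text,
        token_count=14,
        is_gold=True,
        gold_entities=entities,
        gold_links=links,
    )
    return unit, advair, singulair, attrs_advair, attrs_singulair
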