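import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrtriples.lexicon import Category, LexiconSet, Provenance
from emrtriples.tagger import FilterConfig, TaggedSpan, filter_events, tag_terms

_PROP_LEXMAP = {
    Category.SYMPTOM: {"甲乙", "乙丙", "丙"},
    Category.DISEASE: {"甲乙丙", "丁戊"},
    Category.DRUG: {"戊"},
}
_PROP_LEX = LexiconSet()
for _cat, _terms in _PROP_LEXMAP.items():
    for _t in _terms:
        _PROP_LEX.add_term(_t, _cat)


def oracle_tag(s: str, lexmap: dict[Category, set[str]]):
    """Brute force: enumerate all substrings longest-first, left to right,
    with boundary-character blocking."""
    tagged: set[int] = set()
    out = []
    for length in range(len(s), 0, -1):
        for start in range(0, len(s) - length + 1):
            end = start + length
            if start in tagged or (end - 1) in tagged:
                continue
            sub = s[start:end]
            hits = [c for c, terms in sorted(lexmap.items()) if sub in terms]
            if hits:
                out.extend((start, end, c) for c in hits)
                tagged.update(range(start, end))
    return sorted(out, key=lambda x: (x[0], x[2].value))


def _as_keys(spans):
    return [(sp.start, sp.end, sp.category) for sp in spans]


def test_empty_string_yields_nothing(toy_lexica):
    assert tag_terms("", toy_lexica) == []


def test_longest_match_blocks_shorter_terms():
    lex = LexiconSet()
    for t in ["咳嗽", "咳痰", "咳"]:
        lex.add_term(t, Category.SYMPTOM)
    spans = tag_terms("咳嗽咳痰", lex)
    assert _as_keys(spans) == [
        (0, 2, Category.SYMPTOM),
        (2, 4, Category.SYMPTOM),
    ]
    assert all(sp.surface != "咳" for sp in spans)


def test_multi_category_term_emits_one_span_per_category():
    lex = LexiconSet()
    lex.add_term("腹", Category.BODY_PART)
    lex.add_term("腹", Category.SYMPTOM)
    spans = tag_terms("腹", lex)
    assert {sp.category for sp in spans} == {Category.BODY_PART, Category.SYMPTOM}
    assert all((sp.start, sp.end) == (0, 1) for sp in spans)


def test_spans_never_overlap_and_surface_consistent(toy_lexica):
    rng = random.Random(5)
    alphabet = "咳嗽痰恶寒头孢呋腹口腔黏膜出血肺功能，。"
    for _ in range(200):
        s = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 25)))
        spans = tag_terms(s, toy_lexica)
        for sp in spans:
            assert s[sp.start : sp.end] == sp.surface
        for a, b in zip(spans, spans[1:]):
            if a.category is not b.category or (a.start, a.end) != (b.start, b.end):
                assert a.end <= b.start or (a.start, a.end) == (b.start, b.end)


def test_matches_brute_force_oracle_on_random_strings():
    rng = random.Random(99)
    alphabet = "甲乙丙丁戊己庚辛壬癸子丑寅卯辰巳午未申酉"
    lexmap: dict[Category, set[str]] = {c: set() for c in Category}
    lex = LexiconSet()
    cats = list(Category)
    for k in range(50):
        term = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 4)))
        cat = cats[k % len(cats)]
        lexmap[cat].add(term)
        lex.add_term(term, cat, Provenance.CORE)
    for _ in range(300):
        s = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 30)))
        assert _as_keys(tag_terms(s, lex)) == oracle_tag(s, lexmap)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.text(alphabet="甲乙丙丁戊，。", max_size=24))
def test_tagging_invariants_hold_on_arbitrary_text(s):
    spans = tag_terms(s, _PROP_LEX)
    keys = _as_keys(spans)
    assert keys == oracle_tag(s, {c: _PROP_LEXMAP.get(c, set()) for c in Category})
    assert sum(sp.end - sp.start for sp in spans if sp.category is not None) >= 0
    covered: set[int] = set()
    for sp in spans:
        chars = set(range(sp.start, sp.end))
        overlap = covered & chars
        # overlaps only between co-located multi-category spans
        for other in spans:
            if other is not sp and set(range(other.start, other.end)) & chars:
                assert (other.start, other.end) == (sp.start, sp.end)
        covered |= chars


def test_negated_symptom_is_not_an_event(toy_lexica):
    doc = "无恶寒"
    spans = filter_events(doc, tag_terms(doc, toy_lexica))
    (span,) = [s for s in spans if s.surface == "恶寒"]
    assert span.is_event is False


def test_future_procedure_is_not_an_event(toy_lexica):
    doc = "拟行前列腺电切术"
    spans = filter_events(doc, tag_terms(doc, toy_lexica))
    (span,) = [s for s in spans if s.surface == "前列腺电切术"]
    assert span.is_event is False


def test_unmarked_symptom_is_an_event(toy_lexica):
    doc = "咳嗽3天"
    spans = filter_events(doc, tag_terms(doc, toy_lexica))
    (span,) = [s for s in spans if s.surface == "咳嗽"]
    assert span.is_event is True


def test_negation_scope_is_clause_local(toy_lexica):
    # the negation in the first clause must not demote the second clause
    doc = "无恶寒，咳嗽3天"
    spans = filter_events(doc, tag_terms(doc, toy_lexica))
    by_surface = {s.surface: s for s in spans}
    assert by_surface["恶寒"].is_event is False
    assert by_surface["咳嗽"].is_event is True


def test_disease_and_drug_always_events_body_part_never(toy_lexica):
    doc = "无上呼吸道感染，无头孢呋，口腔"
    spans = filter_events(doc, tag_terms(doc, toy_lexica))
    by_surface = {s.surface: s for s in spans}
    assert by_surface["上呼吸道感染"].is_event is True
    assert by_surface["头孢呋"].is_event is True
    assert by_surface["口腔"].is_event is False


def test_filter_config_rejects_empty_markers():
    with pytest.raises(ValueError):
        FilterConfig(negation_prefixes=frozenset({""}))
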