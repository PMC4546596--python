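import random

import pytest

from emrtriples.bootstrap import (
    BootstrapConfig,
    CandidatePattern,
    CandidateTerm,
    apply_pattern,
    bootstrap,
    generate_candidate_patterns,
    grid_search_thresholds,
    score_patterns,
    select_patterns,
    select_terms,
)
from emrtriples.lexicon import Category, LexiconSet, Provenance
from emrtriples.synthetic import SynthConfig, generate_corpus, make_toy_lexica
from emrtriples.tagger import TaggedSpan

NINE_PATTERNS = {
    ("予", "抗"), ("予", "抗感"), ("予", "抗感染"),
    ("给予", "抗"), ("给予", "抗感"), ("给予", "抗感染"),
    (",给予", "抗"), (",给予", "抗感"), (",给予", "抗感染"),
}


def test_worked_example_emits_the_nine_patterns():
    doc = ",给予头孢呋抗感染"
    span = TaggedSpan("头孢呋", Category.DRUG, 3, 6)
    pats = generate_candidate_patterns(doc, span)
    assert len(pats) == 9
    assert {(p.left, p.right) for p in pats} == NINE_PATTERNS
    assert all(p.slot_category is Category.DRUG for p in pats)


def test_boundary_truncation_dedupes():
    # span at position 0 with one character of right context
    doc = "头孢呋抗"
    span = TaggedSpan("头孢呋", Category.DRUG, 0, 3)
    pats = generate_candidate_patterns(doc, span)
    assert len(pats) == 1
    assert (pats[0].left, pats[0].right) == ("", "抗")


def test_full_context_always_gives_nine_distinct_patterns():
    rng = random.Random(3)
    alphabet = "甲乙丙丁戊己庚辛壬"
    for _ in range(20):
        left = "".join(rng.sample(alphabet, 3))
        right = "".join(rng.sample(alphabet, 3))
        doc = left + "灵" + right
        pats = generate_candidate_patterns(doc, TaggedSpan("灵", Category.DRUG, 3, 4))
        expect = {(left[3 - l:], right[:r]) for l in (1, 2, 3) for r in (1, 2, 3)}
        assert {(p.left, p.right) for p in pats} == expect


def test_out_of_bounds_span_raises():
    with pytest.raises(ValueError):
        generate_candidate_patterns("短", TaggedSpan("长长", Category.DRUG, 0, 2))


def test_apply_pattern_single_match():
    pat = CandidatePattern("予", Category.DRUG, "抗")
    assert apply_pattern(pat, ["给予阿莫西林抗感染"]) == {"阿莫西林"}


def test_apply_pattern_absent_left_is_empty():
    pat = CandidatePattern("氨", Category.DRUG, "抗")
    assert apply_pattern(pat, ["给予阿莫西林抗感染"]) == set()


def test_apply_pattern_rejects_fillers_spanning_clause_punctuation():
    pat = CandidatePattern("予", Category.DRUG, "抗")
    assert apply_pattern(pat, ["予A，B抗"]) == set()


def test_apply_pattern_respects_max_term_len():
    pat = CandidatePattern("予", Category.DRUG, "抗")
    doc = "予" + "甲" * 11 + "抗"
    assert apply_pattern(pat, [doc], BootstrapConfig(max_term_len=10)) == set()
    assert apply_pattern(pat, [doc], BootstrapConfig(max_term_len=11)) == {"甲" * 11}


def oracle_apply(pattern: CandidatePattern, corpus, max_term_len=10):
    """Brute force over all (anchor position, filler length) pairs with
    shortest-match-per-anchor semantics."""
    bad = set("。，、；：!！?？")
    out = set()
    for doc in corpus:
        for i in range(len(doc) + 1):
            if pattern.left and doc[max(0, i - len(pattern.left)) : i] != pattern.left:
                continue
            if not pattern.left and i >= len(doc):
                continue
            if not pattern.right:
                continue
            for L in range(1, len(doc) - i + 1):
                if doc[i + L : i + L + len(pattern.right)] == pattern.right:
                    filler = doc[i : i + L]
                    if L <= max_term_len and not (set(filler) & bad):
                        out.add(filler)
                    break
    return out


def test_apply_pattern_agrees_with_brute_force_oracle():
    rng = random.Random(17)
    alphabet = "甲乙丙，。予抗"
    for _ in range(300):
        doc = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 40)))
        left = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 2)))
        right = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 2)))
        pat = CandidatePattern(left, Category.DRUG, right)
        assert apply_pattern(pat, [doc]) == oracle_apply(pat, [doc])


def test_score_patterns_hand_count():
    # one pattern extracting fillers {A, B, C} with {A, B} in the lexicon
    lex = LexiconSet()
    lex.add_term("呋素", Category.DRUG)
    lex.add_term("洛素", Category.DRUG)
    corpus = ["予呋素抗。予洛素抗。予坦素抗。"]
    pat = CandidatePattern("予", Category.DRUG, "抗")
    (scored,) = score_patterns([pat], corpus, lex)
    assert scored.ps == 2
    assert scored.pp == pytest.approx(2 / 3)


def test_score_patterns_undefined_pp_when_nothing_extracted():
    lex = LexiconSet()
    pat = CandidatePattern("前", Category.DRUG, "后")
    (scored,) = score_patterns([pat], [], lex)
    assert scored.ps == 0 and scored.pp is None


def test_score_patterns_all_known_gives_pp_one():
    lex = LexiconSet()
    lex.add_term("呋素", Category.DRUG)
    (scored,) = score_patterns(
        [CandidatePattern("予", Category.DRUG, "抗")], ["予呋素抗"], lex
    )
    assert scored.pp == 1.0


def test_select_patterns_strict_inequalities():
    cfg = BootstrapConfig(pst=7, ppt=0.7)
    at_threshold = CandidatePattern("a", Category.DRUG, "b", ps=7, pp=0.7)
    above = CandidatePattern("c", Category.DRUG, "d", ps=8, pp=0.75)
    undefined = CandidatePattern("e", Category.DRUG, "f", ps=0, pp=None)
    assert select_patterns([at_threshold, above, undefined], cfg) == [above]
    assert select_patterns([], cfg) == []


def test_select_terms_strict_inequality():
    cfg = BootstrapConfig(tft=1)
    one = CandidateTerm("甲素", 1, Category.DRUG)
    two = CandidateTerm("乙素", 2, Category.DRUG)
    zero = CandidateTerm("丙素", 0, Category.DRUG)
    assert select_terms([one, two, zero], cfg) == [two]


def test_bootstrap_no_category_terms_means_no_growth(toy_lexica):
    corpus = ["今日无特殊。", "继续观察。"]
    enriched, history = bootstrap(corpus, toy_lexica, Category.DRUG, BootstrapConfig())
    assert enriched.entries[Category.DRUG] == toy_lexica.entries[Category.DRUG]
    assert sum(h.n_terms_added for h in history) == 0


def test_bootstrap_is_deterministic_and_monotone():
    cfg = SynthConfig(seed=23, n_docs=120)
    lex, planted = make_toy_lexica(cfg)
    corpus = [d.text for d in generate_corpus(cfg, lex, planted)]
    bc = BootstrapConfig(pst=3, ppt=0.5, tft=1)
    e1, h1 = bootstrap(corpus, lex, Category.DRUG, bc)
    e2, h2 = bootstrap(corpus, lex, Category.DRUG, bc)
    assert e1.entries[Category.DRUG] == e2.entries[Category.DRUG]
    assert [h.n_terms_added for h in h1] == [h.n_terms_added for h in h2]
    # lexicon only grows, and every accretion is tagged with its origin
    assert e1.entries[Category.DRUG] >= lex.entries[Category.DRUG]
    for term in e1.entries[Category.DRUG] - lex.entries[Category.DRUG]:
        assert e1.provenance[(term, Category.DRUG)] is Provenance.PATTERN_ITERATION


def test_planted_term_recall_non_increasing_in_thresholds():
    cfg = SynthConfig(seed=31, n_docs=150)
    lex, planted = make_toy_lexica(cfg)
    corpus = [d.text for d in generate_corpus(cfg, lex, planted)]
    plant = set(planted[Category.DRUG])

    def recall(pst, ppt):
        enriched, _ = bootstrap(
            corpus, lex, Category.DRUG, BootstrapConfig(pst=pst, ppt=ppt, tft=1)
        )
        got = enriched.entries[Category.DRUG] - lex.entries[Category.DRUG]
        return len(got & plant) / len(plant)

    r_by_pst = [recall(pst, 0.5) for pst in (3, 20, 200)]
    assert sorted(r_by_pst, reverse=True) == r_by_pst
    r_by_ppt = [recall(3, ppt) for ppt in (0.3, 0.7, 0.999)]
    assert sorted(r_by_ppt, reverse=True) == r_by_ppt


def _tiny_grid_setup():
    lex = LexiconSet()
    for t in ["呋素", "洛素", "坦素", "平素"]:
        lex.add_term(t, Category.DRUG)
    corpus = ["予呋素抗。予洛素抗。予坦素抗。予平素抗。予新素抗。予新素服。"]
    gold = [
        [
            TaggedSpan("呋素", Category.DRUG, 1, 3),
            TaggedSpan("洛素", Category.DRUG, 6, 8),
        ]
    ]
    docs = ["予呋素抗。予洛素抗。"]
    return lex, corpus, gold, docs


def test_grid_search_single_point_returns_it():
    lex, corpus, gold, docs = _tiny_grid_setup()
    pst, ppt, table = grid_search_thresholds(
        corpus, lex, Category.DRUG, gold, docs, pst_grid=[4], ppt_grid=[0.6]
    )
    assert (pst, ppt) == (4, 0.6)
    assert len(table) == 1


def test_grid_search_default_grid_has_104_points():
    lex, corpus, gold, docs = _tiny_grid_setup()
    _, _, table = grid_search_thresholds(corpus, lex, Category.DRUG, gold, docs)
    assert len(table) == 8 * 13


def test_grid_search_ties_break_to_higher_ppt():
    lex, corpus, gold, docs = _tiny_grid_setup()
    # with an extreme pst no grid point ever enriches: all F1 equal
    pst, ppt, table = grid_search_thresholds(
        corpus, lex, Category.DRUG, gold, docs,
        pst_grid=[50, 60], ppt_grid=[0.4, 0.8],
    )
    f1s = {f1 for _, _, f1 in table}
    assert len(f1s) == 1
    assert (pst, ppt) == (60, 0.8)


def test_grid_search_empty_gold_raises():
    lex, corpus, _, docs = _tiny_grid_setup()
    with pytest.raises(ValueError):
        grid_search_thresholds(corpus, lex, Category.DRUG, [], docs)
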