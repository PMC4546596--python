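import math
import random

import numpy as np
import pytest

from emrtriples.lexicon import Category
from emrtriples.linker import (
    CachedFrequencyProvider,
    CandidateDescription,
    CorpusFrequencyProvider,
    baseline_adjacent,
    extract_candidates,
    featurize,
    filter_candidates,
    link,
    ngd,
    train_linker,
)
from emrtriples.tagger import TaggedSpan
from emrtriples.temporal import TemporalTerm


def _span(term, cat, start, is_event=True):
    return TaggedSpan(term, cat, start, start + len(term), is_event)


def _cand(s, start):
    return CandidateDescription(s, start, start + len(s), any(c.isdigit() for c in s))


# ------------------------------------------------------------- candidates


def test_uncovered_clauses_become_candidates():
    cands = extract_candidates("色黄，质粘", [], [])
    assert [(c.surface, c.start, c.end) for c in cands] == [
        ("色黄", 0, 2),
        ("质粘", 3, 5),
    ]


def test_fully_covered_statement_has_no_candidates():
    stmt = "3天前咳嗽"
    spans = [_span("咳嗽", Category.SYMPTOM, 3)]
    times = [TemporalTerm("3天前", 0, 3, "relative_duration")]
    assert extract_candidates(stmt, spans, times) == []


def test_digit_candidate_flagged():
    stmt = "FEV1/FVC小于70%"
    (cand,) = extract_candidates(stmt, [], [])
    assert cand.contains_digit is True
    assert cand.surface == "FEV1/FVC小于70%"


def test_filter_drops_candidates_overlapping_non_events():
    stmt = "无恶寒明显"
    spans = [_span("恶寒", Category.SYMPTOM, 1, is_event=False)]
    cands = [_cand("恶寒明显", 1)]
    assert filter_candidates(cands, spans) == []


def test_filter_drops_stoplisted_and_keeps_others():
    cands = [_cand("于我院住院治疗", 0), _cand("色黄", 8)]
    kept = filter_candidates(cands, [])
    assert [c.surface for c in kept] == ["色黄"]


def test_growing_stoplist_never_grows_output():
    cands = [_cand("色黄", 0), _cand("质粘", 3)]
    small = filter_candidates(cands, [], stoplist=frozenset())
    big = filter_candidates(cands, [], stoplist=frozenset({"色黄"}))
    assert set(c.surface for c in big) <= set(c.surface for c in small)


# -------------------------------------------------------------------- NGD


class _TableFP:
    def __init__(self, fx, fy, fxy, M):
        self._fx, self._fy, self._fxy, self.M = fx, fy, fxy, M

    def f(self, t):
        return self._fx if t == "x" else self._fy

    def f2(self, a, b):
        return self._fxy


def test_ngd_hand_computed_case():
    # f(x)=4, f(y)=2, f(x,y)=1, M=16 → (log4 - log1) / (log16 - log2) = 2/3
    assert ngd("x", "y", _TableFP(4, 2, 1, 16)) == pytest.approx(2 / 3, abs=1e-9)


def test_ngd_identical_terms_is_zero():
    assert ngd("x", "x", _TableFP(5, 5, 5, 100)) == 0.0


def test_ngd_zero_joint_frequency_hits_cap():
    assert ngd("x", "y", _TableFP(5, 5, 0, 100)) == 10.0
    assert ngd("x", "y", _TableFP(0, 5, 0, 100), cap=3.0) == 3.0


def test_ngd_requires_two_documents():
    with pytest.raises(ValueError):
        ngd("x", "y", _TableFP(1, 1, 1, 1))


def test_ngd_symmetric_on_random_triples():
    rng = random.Random(8)
    docs = []
    vocab = [chr(0x4E00 + i) for i in range(30)]
    for _ in range(200):
        docs.append("".join(rng.sample(vocab, rng.randint(1, 8))))
    fp = CorpusFrequencyProvider(docs)
    for _ in range(1000):
        x, y = rng.choice(vocab), rng.choice(vocab)
        assert ngd(x, y, fp) == pytest.approx(ngd(y, x, fp))


def test_ngd_non_increasing_in_joint_frequency():
    values = [ngd("x", "y", _TableFP(8, 6, fxy, 64)) for fxy in (1, 2, 4, 6)]
    assert sorted(values, reverse=True) == values


def test_corpus_frequency_provider_counts_documents():
    fp = CorpusFrequencyProvider(["甲乙", "甲丙", "丁"])
    assert fp.M == 3
    assert fp.f("甲") == 2
    assert fp.f2("甲", "乙") == 1
    assert fp.f2("乙", "丙") == 0


def test_cached_provider_is_symmetric():
    fp = CachedFrequencyProvider({"a": 4, "b": 2}, {("a", "b"): 1}, M=16)
    assert fp.f2("b", "a") == 1
    assert ngd("a", "b", fp) == pytest.approx(2 / 3)


# --------------------------------------------------------------- features


def test_between_counts_in_constructed_statement():
    stmt = "咳痰，色黄，质粘"
    event = _span("咳痰", Category.SYMPTOM, 0)
    c1, c2 = _cand("色黄", 3), _cand("质粘", 6)
    fp = CorpusFrequencyProvider([stmt, stmt])
    f = featurize(stmt, event, c2, [event], [c1, c2], fp)
    assert f.n_descs_between == 1
    assert f.n_commas_between == 2
    assert f.n_terms_between == 0
    assert f.term_type is Category.SYMPTOM


def test_adjacent_pair_has_empty_between():
    stmt = "咳痰色黄"
    event = _span("咳痰", Category.SYMPTOM, 0)
    cand = _cand("色黄", 2)
    fp = CorpusFrequencyProvider([stmt, stmt])
    f = featurize(stmt, event, cand, [event], [cand], fp)
    assert (f.n_terms_between, f.n_descs_between, f.n_commas_between) == (0, 0, 0)


def test_context_windows_padded_at_boundaries():
    stmt = "咳痰，色黄"
    event = _span("咳痰", Category.SYMPTOM, 0)
    cand = _cand("色黄", 3)
    fp = CorpusFrequencyProvider([stmt, stmt])
    f = featurize(stmt, event, cand, [event], [cand], fp)
    assert len(f.ctx_term_left) == 3 and f.ctx_term_left.startswith("§")
    assert f.ctx_term_right == "，色黄"


def test_cross_statement_pair_is_an_error():
    stmt = "咳痰"
    event = _span("咳痰", Category.SYMPTOM, 0)
    cand = _cand("色黄", 10)
    fp = CorpusFrequencyProvider([stmt, stmt])
    with pytest.raises(ValueError):
        featurize(stmt, event, cand, [event], [cand], fp)


# ------------------------------------------------------------- classifier


def _separable_pairs(n=40, seed=0):
    """NGD alone separates: positives near 0, negatives near the cap."""
    rng = random.Random(seed)
    fp = CorpusFrequencyProvider(["甲", "乙"])
    pairs = []
    stmt = "咳痰，色黄"
    event = _span("咳痰", Category.SYMPTOM, 0)
    cand = _cand("色黄", 3)
    base = featurize(stmt, event, cand, [event], [cand], fp)
    import dataclasses

    for i in range(n):
        label = i % 2 == 0
        f = dataclasses.replace(base, ngd=rng.uniform(0, 1) if label else rng.uniform(5, 9))
        pairs.append((f, label))
    return pairs


def test_separable_training_reaches_perfect_fit():
    pairs = _separable_pairs()
    model = train_linker(pairs, seed=1)
    preds = model.predict([f for f, _ in pairs])
    assert all(p == l for p, (_, l) in zip(preds, pairs))


def test_single_class_training_raises():
    pairs = [(f, True) for f, _ in _separable_pairs(10)]
    with pytest.raises(ValueError):
        train_linker(pairs, seed=0)


def test_retraining_with_same_seed_is_deterministic():
    pairs = _separable_pairs(60, seed=3)
    m1 = train_linker(pairs, seed=7)
    m2 = train_linker(pairs, seed=7)
    feats = [f for f, _ in pairs]
    assert np.array_equal(m1.predict(feats), m2.predict(feats))


def test_link_allows_many_to_many():
    stmt = "咳痰、发热，色黄"
    e1 = _span("咳痰", Category.SYMPTOM, 0)
    e2 = _span("发热", Category.SYMPTOM, 3)
    cand = _cand("色黄", 6)
    fp = CorpusFrequencyProvider([stmt, stmt])

    class _YesModel:
        def predict(self, feats):
            return np.ones(len(feats), dtype=bool)

    out = link(_YesModel(), stmt, [e1, e2], [cand], [e1, e2], fp)
    assert len(out) == 2
    assert link(_YesModel(), stmt, [e1, e2], [], [e1, e2], fp) == []


def test_baseline_links_nearest_following_candidate():
    e1 = _span("咳痰", Category.SYMPTOM, 0)
    e2 = _span("发热", Category.SYMPTOM, 3)
    cand = _cand("色黄", 6)
    out = baseline_adjacent([e1, e2], [cand])
    assert [(e.surface, c.surface) for e, c in out] == [("咳痰", "色黄"), ("发热", "色黄")]
    # no following candidate → no pair
    assert baseline_adjacent([e2], [_cand("色黄", 0)]) == []
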