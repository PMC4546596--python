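"""Seeded synthetic clinical-narrative generator with gold annotations.

Real Chinese inpatient narratives cannot be redistributed, so every stage
of the framework is exercised on generated documents that imitate the
*structural* properties the methods depend on: short period-delimited
statements, comma-dense clauses, temporal phrases heading statements,
lexicon terms in stereotyped contexts (予…抗感染, 诊断为…), negated and
future mentions, and description clauses whose vocabulary co-occurs with
specific event terms so that corpus co-occurrence (hence NGD) is
informative.

Pseudo-terms are synthesized from small per-category Chinese character
inventories chosen to read plausibly (symptoms end in 痛/肿/痒/胀, drugs
end in 素/平/林/星, procedures in 术). The inventories are pairwise
disjoint, and disjoint from all template, temporal and description
characters; together with fixed per-category term lengths this guarantees
that longest-match tagging of a generated document reproduces the gold
spans exactly — there is simply no unintended string collision to find.
That property is what makes the generator usable as a gold standard; it is
also what real corpora do NOT guarantee, so green tests here bound
engineering correctness, not clinical performance.

A configurable number of drug terms are "planted": used in documents but
withheld from the core lexica, each in at least two distinct context
templates, so the pattern-iteration bootstrap has something to recover.
All randomness flows from ``SynthConfig.seed``.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .lexicon import Category, LexiconSet, Provenance
from .linker import CandidateDescription, DEFAULT_STOPLIST, Triple
from .tagger import TaggedSpan
from .temporal import TemporalTerm

__all__ = [
    "SynthConfig",
    "GoldDocument",
    "make_toy_lexica",
    "generate_corpus",
    "StatementView",
    "statement_views",
    "RECOMMENDED_STOPLIST",
]

# ---------------------------------------------------------------- inventories
# per-category character pools; pairwise disjoint and disjoint from the
# template / temporal / description characters below
_STEMS = {
    Category.DISEASE: "风湿瘟疫痹疠痼瘀",
    Category.SYMPTOM: "咳喘呕眩悸闷",
    Category.DRUG: "莫西沙卡洛他汀尼培酮",
    Category.BODY_PART: "肝肺肾脾胃肠胆脑",
    Category.PROCEDURE: "切割缝扎造瘘引流",
    Category.CLINICAL_TEST: "超磁核电镜谱",
}
_SUFFIXES = {
    Category.DISEASE: "炎症疡癣",
    Category.SYMPTOM: "痛肿痒胀",
    Category.DRUG: "素平林星",
    Category.BODY_PART: "",
    Category.PROCEDURE: "术",
    Category.CLINICAL_TEST: "检",
}

#: description clause character inventory, keyed by the event category the
#: clause may describe; each describable term owns two dedicated phrases
#: built from this inventory, so corpus co-occurrence (and hence NGD)
#: carries a real association signal
_DESC_CHARS = {
    Category.SYMPTOM: "量色质频沉隐浊润燥涩",
    Category.CLINICAL_TEST: "示影波纹升降",
}

#: temporal phrases drawn by the generator (all covered by the grammar)
_DURATIONS = (
    "3天前", "5天前", "10天前", "2周前", "约1周前", "1月前", "约3月前",
    "半月前", "2年前", "4小时前",
)
_DAY_REFS = ("昨天下午", "今天上午", "今天凌晨", "昨天")
_IDIOMS = ("今晨", "昨晚", "今晚", "昨夜")

#: drug context templates (left, right): the shared contexts the
#: pattern-iteration bootstrap harvests
_DRUG_CONTEXTS = (("给予", "抗感染"), ("予", "口服"), ("服", "后缓解"))

_NEGATIONS = ("无", "否认", "未见")
_FUTURES = ("拟行", "建议行")

#: connector vocabulary of the generator's own templates; the analogue, for
#: this corpus, of the "common EMR words" stoplist rule
RECOMMENDED_STOPLIST = frozenset(DEFAULT_STOPLIST) | {
    "给予", "予", "抗感染", "口服", "服", "缓解", "诊断", "查",
    "无", "否认", "未见", "拒绝", "拟", "建议", "行",
}


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_docs: int = 100
    vocab_sizes: dict[Category, int] = field(
        default_factory=lambda: {
            Category.DISEASE: 24,
            Category.SYMPTOM: 20,
            Category.DRUG: 45,
            Category.BODY_PART: 8,
            Category.PROCEDURE: 12,
            Category.CLINICAL_TEST: 10,
        }
    )
    n_planted_unknown_terms: int = 20  # drug terms withheld from the core lexica
    p_time: float = 0.8
    p_negation: float = 0.05
    p_future: float = 0.05
    p_description: float = 0.55
    p_multi_time: float = 0.15
    p_second_symptom: float = 0.5
    p_planted_drug: float = 0.35
    min_statements: int = 3
    max_statements: int = 6
    template_weights: dict[str, float] = field(
        default_factory=lambda: {
            "symptom": 0.40,
            "drug": 0.30,
            "test": 0.15,
            "disease": 0.15,
        }
    )

    def __post_init__(self) -> None:
        for p in (
            self.p_time, self.p_negation, self.p_future,
            self.p_description, self.p_multi_time,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")


@dataclass
class GoldDocument:
    """A generated document and its by-construction gold annotations.

    All offsets are document-level. ``statements`` are (offset, text)
    pairs excluding the closing period. ``gold_links`` pairs event spans
    with their description candidates; ``gold_candidates`` lists every
    description clause emitted (the post-filter candidate view).
    """

    doc_id: str
    text: str
    statements: list[tuple[int, str]] = field(default_factory=list)
    gold_spans: list[TaggedSpan] = field(default_factory=list)
    gold_times: list[TemporalTerm] = field(default_factory=list)
    gold_candidates: list[CandidateDescription] = field(default_factory=list)
    gold_links: list[tuple[TaggedSpan, CandidateDescription]] = field(
        default_factory=list
    )
    gold_triples: list[Triple] = field(default_factory=list)


@dataclass
class StatementView:
    """One statement of a gold document in statement-local coordinates,
    ready for linker feature extraction: every (event, candidate) pair in
    the statement plus the set of gold links among them."""

    doc_id: str
    statement: str
    spans: list[TaggedSpan]
    events: list[TaggedSpan]
    candidates: list[CandidateDescription]
    gold_pairs: set[tuple[tuple[int, int], tuple[int, int]]]  # event/cand intervals


def statement_views(docs: list[GoldDocument]) -> list[StatementView]:
    """Per-statement local views over gold documents (only statements with
    at least one event and one candidate can contribute linker pairs, but
    all statements are returned)."""
    views: list[StatementView] = []
    for doc in docs:
        for off, stmt in doc.statements:
            end = off + len(stmt)
            loc_spans = [
                TaggedSpan(s.surface, s.category, s.start - off, s.end - off, s.is_event)
                for s in doc.gold_spans
                if off <= s.start and s.end <= end
            ]
            loc_cands = [
                CandidateDescription(c.surface, c.start - off, c.end - off, c.contains_digit)
                for c in doc.gold_candidates
                if off <= c.start and c.end <= end
            ]
            gold = {
                ((e.start - off, e.end - off), (c.start - off, c.end - off))
                for e, c in doc.gold_links
                if off <= e.start and e.end <= end
            }
            views.append(
                StatementView(
                    doc.doc_id,
                    stmt,
                    loc_spans,
                    [s for s in loc_spans if s.is_event],
                    loc_cands,
                    gold,
                )
            )
    return views


def _term_universe(rng: random.Random, category: Category) -> list[str]:
    stems, suffixes = _STEMS[category], _SUFFIXES[category]
    if category is Category.SYMPTOM:
        combos = [a + z for a in stems for z in suffixes]
    elif suffixes:
        combos = [a + b + z for a, b in itertools.permutations(stems, 2) for z in suffixes]
    else:
        combos = [a + b for a, b in itertools.permutations(stems, 2)]
    rng.shuffle(combos)
    return combos


def make_toy_lexica(
    cfg: SynthConfig,
) -> tuple[LexiconSet, dict[Category, list[str]]]:
    """Build the core lexica and the withheld (planted) term lists.

    Planted terms are disjoint from core terms and, like all generated
    terms, pairwise disjoint across categories. Deterministic under
    ``cfg.seed``.
    """
    rng = random.Random(cfg.seed)
    lex = LexiconSet()
    planted: dict[Category, list[str]] = {c: [] for c in Category}
    for category in Category:
        universe = _term_universe(rng, category)
        want = cfg.vocab_sizes.get(category, 10)
        n_plant = cfg.n_planted_unknown_terms if category is Category.DRUG else 0
        if want + n_plant > len(universe):
            raise ValueError(f"vocab size too large for {category.value} inventory")
        for term in universe[:want]:
            lex.add_term(term, category, Provenance.CORE)
        planted[category] = universe[want : want + n_plant]
    return lex, planted


class _DocBuilder:
    """Accumulates one document's text and gold while tracking offsets and
    the carried-forward temporal term (scoping rule 3)."""

    def __init__(self, doc_id: str, carried: TemporalTerm | None):
        self.gold = GoldDocument(doc_id=doc_id, text="")
        self.carried = carried
        self._pos = 0

    def _emit(self, chunk: str) -> int:
        start = self._pos
        self.gold.text += chunk
        self._pos += len(chunk)
        return start

    def add_statement(
        self,
        parts: list[tuple[str, str, object]],
    ) -> None:
        """parts: (kind, text, payload) with kind in {plain, time, span,
        desc}; payload is (category, is_event) for spans, an owner marker
        for descs, a kind string for times."""
        stmt_start = self._pos
        times: list[TemporalTerm] = []
        spans: list[TaggedSpan] = []
        descs: list[tuple[CandidateDescription, int]] = []  # (cand, owner idx)
        for kind, text, payload in parts:
            start = self._emit(text)
            if kind == "time":
                times.append(TemporalTerm(text, start, start + len(text), str(payload)))
            elif kind == "span":
                category, is_event = payload  # type: ignore[misc]
                spans.append(TaggedSpan(text, category, start, start + len(text), is_event))
            elif kind == "desc":
                descs.append(
                    (
                        CandidateDescription(
                            text, start, start + len(text),
                            any(ch.isdigit() for ch in text),
                        ),
                        int(payload),  # type: ignore[arg-type]
                    )
                )
        self._emit("。")
        stmt_text = self.gold.text[stmt_start : self._pos - 1]
        self.gold.statements.append((stmt_start, stmt_text))
        self.gold.gold_times.extend(times)
        self.gold.gold_spans.extend(spans)
        links: dict[int, CandidateDescription] = {}
        for cand, owner in descs:
            self.gold.gold_candidates.append(cand)
            if 0 <= owner < len(spans):
                self.gold.gold_links.append((spans[owner], cand))
                links[owner] = cand
        # time assignment per the scoping rules
        for i, span in enumerate(spans):
            if not span.is_event:
                continue
            if not times:
                t = self.carried
            elif len(times) == 1:
                t = times[0]
            else:
                t = times[0]
                for cand_t in times:
                    if cand_t.start <= span.start:
                        t = cand_t
            self.gold.gold_triples.append(Triple(t, span, links.get(i)))
        if times:
            self.carried = times[-1]


def generate_corpus(
    cfg: SynthConfig,
    lexica: LexiconSet,
    planted: dict[Category, list[str]],
) -> list[GoldDocument]:
    """Generate ``cfg.n_docs`` documents with full gold structure.

    Each planted drug is scheduled into at least two *distinct* context
    templates (given enough drug statements), so it is recoverable by
    pattern iteration; core drugs are scheduled across every template so
    patterns stay precise.
    """
    rng = random.Random(cfg.seed + 1)
    core = {c: sorted(lexica.entries[c]) for c in Category}
    planted_drugs = list(planted.get(Category.DRUG, []))

    # scheduling queue of (drug, context index): planted drugs in >=2
    # distinct contexts, core drugs in every context
    queue: list[tuple[str, int]] = []
    for d in planted_drugs:
        ctx = rng.sample(range(len(_DRUG_CONTEXTS)), 2)
        queue.extend((d, c) for c in ctx)
    for d in core[Category.DRUG]:
        queue.extend((d, c) for c in range(len(_DRUG_CONTEXTS)))
    rng.shuffle(queue)

    desc_map = _desc_assignment(core)
    kinds, weights = zip(*sorted(cfg.template_weights.items()))
    docs: list[GoldDocument] = []
    for di in range(cfg.n_docs):
        builder = _DocBuilder(f"doc{di:04d}", carried=None)
        n_stmt = rng.randint(cfg.min_statements, cfg.max_statements)
        for _ in range(n_stmt):
            r = rng.random()
            if r < cfg.p_negation:
                _negation_statement(builder, rng, core)
                continue
            if r < cfg.p_negation + cfg.p_future:
                _future_statement(builder, rng, core)
                continue
            kind = rng.choices(kinds, weights=weights)[0]
            if kind == "symptom":
                _symptom_statement(builder, rng, cfg, core, desc_map)
            elif kind == "drug":
                _drug_statement(builder, rng, cfg, core, planted_drugs, queue)
            elif kind == "test":
                _test_statement(builder, rng, cfg, core, desc_map)
            else:
                _disease_statement(builder, rng, cfg, core)
        docs.append(builder.gold)
    return docs


def _draw_time(rng: random.Random) -> tuple[str, str]:
    r = rng.random()
    if r < 0.6:
        return rng.choice(_DURATIONS), "relative_duration"
    if r < 0.85:
        return rng.choice(_DAY_REFS), "day_reference"
    return rng.choice(_IDIOMS), "idiom"


def _maybe_time(
    parts: list, rng: random.Random, cfg: SynthConfig
) -> bool:
    if rng.random() < cfg.p_time:
        surface, kind = _draw_time(rng)
        parts.append(("time", surface, kind))
        return True
    return False


def _symptom_statement(builder, rng, cfg, core, desc_map) -> None:
    parts: list = []
    symptoms = core[Category.SYMPTOM]
    if rng.random() < cfg.p_multi_time:
        # two times, two events: scoping rule 2
        t1, k1 = _draw_time(rng)
        t2, k2 = _draw_time(rng)
        s1, s2 = rng.sample(symptoms, 2)
        parts = [
            ("time", t1, k1),
            ("span", s1, (Category.SYMPTOM, True)),
            ("plain", "，", None),
            ("time", t2, k2),
            ("span", s2, (Category.SYMPTOM, True)),
        ]
        builder.add_statement(parts)
        return
    _maybe_time(parts, rng, cfg)
    n_sym = 2 if rng.random() < cfg.p_second_symptom else 1
    chosen = rng.sample(symptoms, n_sym)
    for i, s in enumerate(chosen):
        if i:
            parts.append(("plain", "、", None))
        parts.append(("span", s, (Category.SYMPTOM, True)))
    if rng.random() < cfg.p_description:
        owner = rng.randrange(n_sym)
        desc = rng.choice(desc_map[chosen[owner]])
        parts.append(("plain", "，", None))
        parts.append(("desc", desc, owner))
    builder.add_statement(parts)


def _desc_assignment(core: dict[Category, list[str]]) -> dict[str, tuple[str, str]]:
    """Two dedicated description phrases per describable term.

    Symptom phrases are character pairs from the symptom description
    inventory; clinical-test phrases pair a qualitative finding with a
    numeric reading (示/值 + digits) so the digit feature varies.
    Deterministic in the sorted term lists.
    """
    out: dict[str, tuple[str, str]] = {}
    sym_chars = _DESC_CHARS[Category.SYMPTOM]
    sym_pairs = [a + b for a, b in itertools.permutations(sym_chars, 2)]
    n = len(sym_pairs)
    for i, term in enumerate(core[Category.SYMPTOM]):
        out[term] = (sym_pairs[(2 * i) % n], sym_pairs[(2 * i + 1) % n])
    test_chars = _DESC_CHARS[Category.CLINICAL_TEST]
    test_pairs = [a + b for a, b in itertools.permutations(test_chars, 2)]
    for i, term in enumerate(core[Category.CLINICAL_TEST]):
        out[term] = (test_pairs[i % len(test_pairs)], f"值{37 + 3 * i}")
    return out


def _drug_statement(builder, rng, cfg, core, planted_drugs, queue) -> None:
    if queue:
        drug, ctx_idx = queue.pop()
    else:
        if planted_drugs and rng.random() < cfg.p_planted_drug:
            drug = rng.choice(planted_drugs)
        else:
            drug = rng.choice(core[Category.DRUG])
        ctx_idx = rng.randrange(len(_DRUG_CONTEXTS))
    left, right = _DRUG_CONTEXTS[ctx_idx]
    parts: list = []
    _maybe_time(parts, rng, cfg)
    parts.append(("plain", left, None))
    parts.append(("span", drug, (Category.DRUG, True)))
    parts.append(("plain", right, None))
    builder.add_statement(parts)


def _test_statement(builder, rng, cfg, core, desc_map) -> None:
    parts: list = []
    _maybe_time(parts, rng, cfg)
    test = rng.choice(core[Category.CLINICAL_TEST])
    parts.append(("plain", "查", None))
    parts.append(("span", test, (Category.CLINICAL_TEST, True)))
    if rng.random() < cfg.p_description:
        desc = rng.choice(desc_map[test])
        parts.append(("plain", "，", None))
        parts.append(("desc", desc, 0))
    builder.add_statement(parts)


def _disease_statement(builder, rng, cfg, core) -> None:
    parts: list = []
    _maybe_time(parts, rng, cfg)
    disease = rng.choice(core[Category.DISEASE])
    parts.append(("plain", "诊断为", None))
    parts.append(("span", disease, (Category.DISEASE, True)))
    builder.add_statement(parts)


def _negation_statement(builder, rng, core) -> None:
    neg = rng.choice(_NEGATIONS)
    sym = rng.choice(core[Category.SYMPTOM])
    builder.add_statement(
        [("plain", neg, None), ("span", sym, (Category.SYMPTOM, False))]
    )


def _future_statement(builder, rng, core) -> None:
    fut = rng.choice(_FUTURES)
    proc = rng.choice(core[Category.PROCEDURE])
    builder.add_statement(
        [("plain", fut, None), ("span", proc, (Category.PROCEDURE, False))]
    )
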